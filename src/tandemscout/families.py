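"""Greedy seed-and-remove extraction of tandem-repeat families.

The core procedure: rank tandem contigs by recruited reads, take the top
contig's consensus monomer as the seed, absorb every contig with local
homology to the seed (ungapped seeded alignment, E-value threshold 0.1),
record the family, remove its members from the pool, repeat.  Each family's
genomic composition is then re-estimated by recruiting the full read set
against a reference built from the seed monomer plus all member contigs.

E-values use ungapped Karlin-Altschul statistics with the homology search's
own +1/-2 weights: E = K * m * n * exp(-lambda * S) with m the query length
and n the total database length.  The seed monomer is doubled before
searching so rotated copies in other contigs are found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp, log as ln
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._kmers import canonical_monomer, encode, kmer_codes, reverse_complement
from .assemble import Contig
from .params import HomologyParams
from .recruit import RecruitmentResult, rank_contigs, recruit_reads
from .seq_io import SequenceRecord
from .tandem import TandemAnnotation, representative_annotation

log = logging.getLogger("tandemscout")


@dataclass
class RepeatFamily:
    """A seed monomer plus all homologous contigs."""

    rank: int
    seed_contig_id: str
    seed_monomer: str  # canonical (rotation/strand-normalised)
    members: Set[str]
    recruited_reads: int
    genomic_fraction: float
    seed_monomer_raw: str = ""  # consensus as called, for reference building
    member_seqs: Dict[str, str] = field(default_factory=dict)


def _best_ungapped_score(query: str, subject: str, params: HomologyParams) -> int:
    """Best seeded ungapped local alignment score (X-drop extension).

    Seeds are exact shared words of ``params.word_size``; both subject
    strands are searched.  Deterministic.
    """
    w = params.word_size
    if len(query) < w or len(subject) < w:
        return 0
    qcodes, qvalid = kmer_codes(encode(query), w)
    qdict: Dict[int, List[int]] = {}
    for i in np.nonzero(qvalid)[0]:
        qdict.setdefault(int(qcodes[i]), []).append(int(i))
    best = 0
    for strand_seq in (subject, reverse_complement(subject)):
        scodes, svalid = kmer_codes(encode(strand_seq), w)
        qarr = encode(query)
        sarr = encode(strand_seq)
        covered: Dict[int, int] = {}  # diagonal -> rightmost subject pos covered
        for j in np.nonzero(svalid)[0]:
            hits = qdict.get(int(scodes[j]))
            if not hits:
                continue
            j = int(j)
            for i in hits:
                diag = j - i
                if covered.get(diag, -1) >= j:
                    continue
                score = w * params.match
                # extend right
                run = score
                qi, sj = i + w, j + w
                right_end = j + w
                right_gain = 0
                while qi < len(qarr) and sj < len(sarr):
                    run += params.match if qarr[qi] == sarr[sj] else params.mismatch
                    if run - score - right_gain > 0:
                        right_gain = run - score
                        right_end = sj + 1
                    if run < score + right_gain - params.xdrop:
                        break
                    qi += 1
                    sj += 1
                # extend left
                run = 0
                left_gain = 0
                qi, sj = i - 1, j - 1
                while qi >= 0 and sj >= 0:
                    run += params.match if qarr[qi] == sarr[sj] else params.mismatch
                    if run > left_gain:
                        left_gain = run
                    if run < left_gain - params.xdrop:
                        break
                    qi -= 1
                    sj -= 1
                total = score + right_gain + left_gain
                covered[diag] = right_end
                if total > best:
                    best = total
    return best


def evalue(score: int, query_len: int, db_len: int, params: HomologyParams) -> float:
    """Karlin-Altschul E-value of an ungapped segment score."""
    return params.karlin_k * query_len * db_len * exp(-params.karlin_lambda * score)


def min_significant_score(query_len: int, db_len: int, params: HomologyParams) -> int:
    """Smallest integer score with E <= evalue_max."""
    lam = params.karlin_lambda
    s = ln(params.karlin_k * query_len * db_len / params.evalue_max) / lam
    return max(1, int(np.ceil(s)))


def find_homologs(
    seed_monomer: str,
    contigs: Sequence[Contig],
    params: HomologyParams | None = None,
) -> Set[str]:
    """Ids of contigs with seeded local homology to the (doubled) seed monomer
    at E <= ``evalue_max``."""
    params = params or HomologyParams()
    if not seed_monomer:
        raise ValueError("empty seed monomer")
    query = seed_monomer * 2  # expose rotated copies
    db_len = sum(len(c.seq) for c in contigs)
    if db_len == 0:
        return set()
    smin = min_significant_score(len(query), db_len, params)
    out: Set[str] = set()
    for c in contigs:
        if _best_ungapped_score(query, c.seq, params) >= smin:
            out.add(c.id)
    return out


def extract_top_families(
    tandem_contigs: Sequence[Tuple[Contig, Sequence[TandemAnnotation]]],
    recruitment: RecruitmentResult,
    n_families: int = 4,
    params: HomologyParams | None = None,
    min_monomer_length: int = 30,
) -> List[RepeatFamily]:
    """Iteratively extract up to ``n_families`` disjoint repeat families.

    Stops early (logged, not an error) when the pool empties or no contig
    with a monomer of at least ``min_monomer_length`` bases remains to seed
    the next family.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    params = params or HomologyParams()
    pool: Dict[str, Tuple[Contig, Sequence[TandemAnnotation]]] = {
        c.id: (c, anns) for c, anns in tandem_contigs
    }
    anns_by_id = {cid: list(anns) for cid, (_, anns) in pool.items()}
    families: List[RepeatFamily] = []
    for rank in range(1, n_families + 1):
        if not pool:
            log.info("family extraction: pool empty after %d families", len(families))
            break
        ranked = rank_contigs(
            recruitment, anns_by_id, min_monomer_length, restrict=sorted(pool)
        )
        top = ranked[0]
        top_ann = representative_annotation(anns_by_id[top])
        if len(top_ann.consensus) < min_monomer_length:
            log.info("family extraction: no eligible seed left at rank %d", rank)
            break
        seed = top_ann.consensus
        members = find_homologs(seed, [c for c, _ in pool.values()], params) | {top}
        members &= set(pool)
        recruited = sum(
            1 for hits in recruitment.read_hits if hits.keys() & members
        )
        fam = RepeatFamily(
            rank=rank,
            seed_contig_id=top,
            seed_monomer=canonical_monomer(seed),
            members=members,
            recruited_reads=recruited,
            genomic_fraction=recruited / max(recruitment.total_reads, 1),
            seed_monomer_raw=seed,
            member_seqs={cid: pool[cid][0].seq for cid in sorted(members)},
        )
        families.append(fam)
        for cid in members:
            pool.pop(cid, None)
    log.info("extracted %d families", len(families))
    return families


def family_composition(
    family: RepeatFamily,
    reads: Sequence[SequenceRecord],
    seed_k: int = 15,
    min_identity: float = 0.85,
    index=None,
) -> float:
    """Fraction of all reads recruiting to the family reference.

    The reference is the seed monomer (doubled, since the monomer is a
    cyclic unit) plus every member contig; a read recruited by two families
    is counted by both, since families are disjoint over contigs, not reads.
    Updates ``family.recruited_reads`` and ``family.genomic_fraction``.
    """
    if not family.members:
        raise ValueError("family has no members")
    reference = [Contig("seed_monomer", family.seed_monomer_raw * 2)]
    for cid, seq in sorted(family.member_seqs.items()):
        reference.append(Contig(cid, seq))
    if not reads:
        family.recruited_reads = 0
        family.genomic_fraction = 0.0
        return 0.0
    result = recruit_reads(reads, reference, seed_k, min_identity, index=index)
    frac = result.total_tandem_reads / result.total_reads
    family.recruited_reads = result.total_tandem_reads
    family.genomic_fraction = frac
    return frac


def classify_top_repeat(
    family: RepeatFamily,
    known_repeats: Sequence[Tuple[str, str]],
    params: HomologyParams | None = None,
) -> Optional[Tuple[str, float, int]]:
    """Best-matching known repeat (name, E-value, monomer length difference)
    for the family seed, or None when nothing reaches E <= evalue_max."""
    params = params or HomologyParams()
    if not known_repeats:
        return None
    query = family.seed_monomer * 2
    best: Optional[Tuple[str, float, int]] = None
    for name, monomer in known_repeats:
        subject = monomer * 2
        s = _best_ungapped_score(query, subject, params)
        e = evalue(s, len(query), len(subject), params)
        if e <= params.evalue_max and (best is None or e < best[1]):
            best = (name, e, abs(len(monomer) - len(family.seed_monomer)))
    return best
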