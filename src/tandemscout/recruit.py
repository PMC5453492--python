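"""Multi-mapping-aware recruitment of shotgun reads to tandem contigs.

A read hits a contig when a shared seed k-mer (either strand) extends to a
local alignment covering at least 80% of the read at identity at or above
``min_identity``; edge-overhanging reads are scored on the overlapping part
only.  A read counts once per contig it hits (all-hits counting) but only
once toward the total of recruited reads, matching a 'proportion of all
reads mapping to any tandem contig' summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Dict, List, Sequence

import edlib
import numpy as np

from ._kmers import canonical_codes, encode, kmer_codes, reverse_complement
from .assemble import Contig
from .seq_io import SequenceRecord
from .tandem import TandemAnnotation, representative_annotation

log = logging.getLogger("tandemscout")

READ_COVERAGE_FRACTION = 0.8  # minimum fraction of a read an alignment must cover


@dataclass
class RecruitmentResult:
    """Per-contig read counts plus per-read hit sets."""

    counts: Dict[str, int]
    read_hits: List[Dict[str, float]]  # per read: contig id -> best identity
    total_reads: int
    total_tandem_reads: int
    contig_lengths: Dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        total = max(self.total_reads, 1)
        rows = [
            {"contig_id": cid, "reads": n, "fraction": n / total}
            for cid, n in sorted(self.counts.items(), key=lambda t: (-t[1], t[0]))
        ]
        return pd.DataFrame(rows, columns=["contig_id", "reads", "fraction"])


def _read_hits_one(
    read_seq: str, contig_seq: str, min_identity: float
) -> float | None:
    """Best identity of a qualifying alignment of read vs contig, else None."""
    L = len(read_seq)
    part_len = max(1, ceil(READ_COVERAGE_FRACTION * L))
    parts = [read_seq]
    if part_len < L:
        parts += [read_seq[:part_len], read_seq[L - part_len :]]
    best = None
    for part in parts:
        maxd = floor((1.0 - min_identity) * len(part))
        for query in (part, reverse_complement(part)):
            d = edlib.align(query, contig_seq, mode="HW", task="distance", k=maxd)[
                "editDistance"
            ]
            if d >= 0:
                ident = 1.0 - d / len(part)
                if best is None or ident > best:
                    best = ident
    return best


class ReadKmerIndex:
    """Canonical seed k-mers of a read set, computed once and reusable across
    recruitment passes (per-contig ranking, then per-family composition)."""

    def __init__(self, reads: Sequence[SequenceRecord], seed_k: int):
        self.seed_k = seed_k
        self.n_reads = len(reads)
        joined = "N".join(r.seq for r in reads)
        codes, valid = kmer_codes(encode(joined), seed_k)
        can, _ = canonical_codes(codes, seed_k)
        valid_idx = np.nonzero(valid)[0]
        valid_can = can[valid_idx]
        starts = np.empty(len(reads), dtype=np.int64)
        off = 0
        for i, r in enumerate(reads):
            starts[i] = off
            off += len(r.seq) + 1
        # read owning each valid window (separator windows are never valid)
        window_read = np.searchsorted(starts, valid_idx, side="right") - 1
        order = np.argsort(valid_can, kind="stable")
        self.sorted_can = valid_can[order]
        self.sorted_read = window_read[order]

    def reads_sharing(self, contig_codes: np.ndarray) -> np.ndarray:
        """Indices of reads sharing any canonical seed k-mer with the contig."""
        if len(self.sorted_can) == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self.sorted_can, contig_codes, side="left")
        hi = np.searchsorted(self.sorted_can, contig_codes, side="right")
        chunks = [self.sorted_read[l:h] for l, h in zip(lo, hi) if h > l]
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(chunks))


def contig_seed_codes(seq: str, seed_k: int) -> np.ndarray:
    codes, valid = kmer_codes(encode(seq), seed_k)
    can, _ = canonical_codes(codes[valid], seed_k)
    return np.unique(can)


def recruit_reads(
    reads: Sequence[SequenceRecord],
    contigs: Sequence[Contig],
    seed_k: int = 15,
    min_identity: float = 0.85,
    index: ReadKmerIndex | None = None,
) -> RecruitmentResult:
    """Map reads against contigs; multi-map aware, deterministic.

    Empty ``reads`` gives zero counts (not an error); empty ``contigs`` is a
    contract violation.  Pass a prebuilt :class:`ReadKmerIndex` to amortise
    the read k-mer scan over several recruitment passes.
    """
    if not contigs:
        raise ValueError("contigs must be non-empty")
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0.5, 1]")

    counts = {c.id: 0 for c in contigs}
    contig_lengths = {c.id: len(c.seq) for c in contigs}
    read_hits: List[Dict[str, float]] = [dict() for _ in reads]
    if not reads:
        return RecruitmentResult(counts, read_hits, 0, 0, contig_lengths)

    if index is None or index.seed_k != seed_k or index.n_reads != len(reads):
        index = ReadKmerIndex(reads, seed_k)

    candidates: Dict[int, List[int]] = {}  # read index -> contig indices
    for ci, c in enumerate(contigs):
        ccodes = contig_seed_codes(c.seq, seed_k)
        for ri in index.reads_sharing(ccodes):
            candidates.setdefault(int(ri), []).append(ci)

    hit_read_total = 0
    for ri in sorted(candidates):
        r = reads[ri]
        got = False
        for ci in candidates[ri]:
            c = contigs[ci]
            ident = _read_hits_one(r.seq, c.seq, min_identity)
            if ident is not None:
                counts[c.id] += 1
                read_hits[ri][c.id] = ident
                got = True
        if got:
            hit_read_total += 1

    result = RecruitmentResult(
        counts=counts,
        read_hits=read_hits,
        total_reads=len(reads),
        total_tandem_reads=hit_read_total,
        contig_lengths=contig_lengths,
    )
    log.info(
        "recruitment: %d/%d reads hit %d contigs",
        hit_read_total,
        len(reads),
        len(contigs),
    )
    return result


def rank_contigs(
    result: RecruitmentResult,
    annotations: Dict[str, Sequence[TandemAnnotation]],
    min_monomer_length: int = 30,
    restrict: Sequence[str] | None = None,
) -> List[str]:
    """Contig ids in rank order: descending read count, ties to the longer
    contig then lexicographic id.

    Contigs whose representative monomer is shorter than
    ``min_monomer_length`` are ineligible as top-ranked seeds and are
    demoted after all eligible contigs.
    """
    ids = list(result.counts) if restrict is None else list(restrict)
    for cid in ids:
        if cid not in annotations or not annotations[cid]:
            raise ValueError(f"contig {cid} has no tandem annotation")

    def sort_key(cid):
        return (-result.counts[cid], -result.contig_lengths.get(cid, 0), cid)

    eligible = [
        cid
        for cid in ids
        if len(representative_annotation(annotations[cid]).consensus) >= min_monomer_length
    ]
    short = [cid for cid in ids if cid not in set(eligible)]
    return sorted(eligible, key=sort_key) + sorted(short, key=sort_key)


def total_tandem_fraction(result: RecruitmentResult) -> float:
    """Proportion of all reads mapping to any tandem contig."""
    if result.total_reads == 0:
        raise ValueError("no reads")
    return result.total_tandem_reads / result.total_reads
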