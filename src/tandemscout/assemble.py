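"""Repeat-tolerant greedy assembly of low-coverage shotgun reads.

A de Bruijn graph over canonical k-mers stands in for an overlap assembler:
at survey coverage only high-copy repeats accumulate enough k-mer support to
assemble, and those are precisely the contigs the downstream tandem detector
consumes.  Contigs are maximal non-branching paths; a branch is followed only
when one outgoing k-mer dominates the alternatives by a large count ratio,
which lets the high-multiplicity trunk of a satellite array shrug off
low-count variant branches created by diverged monomer copies.

Tandem arrays collapse to cycles in the graph; cycles are unrolled to at
least three monomer copies (more for very short monomers, so the unrolled
contig clears the length filter) so the detector sees multiple copies.

Contigs are emitted strand-canonically (the lexicographic min of the
sequence and its reverse complement) and sorted by length then sequence, so
assembling the reverse-complemented read set yields an identical contig set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import List, Sequence

import numpy as np

from ._kmers import (
    canonical_codes,
    canonical_monomer,
    decode_code,
    encode,
    kmer_codes,
    reverse_complement,
    revcomp_codes,
)
from .seq_io import SequenceRecord

log = logging.getLogger("tandemscout")


@dataclass
class Contig:
    """An assembled sequence plus the approximate number of reads consumed."""

    id: str
    seq: str
    n_reads: int = 0

    def __len__(self) -> int:
        return len(self.seq)


def kmer_noise_threshold(reads: Sequence[SequenceRecord], k: int) -> int:
    """Minimum k-mer multiplicity retained by the assembler.

    Singleton k-mers are treated as sequencing errors (threshold 2).  The
    threshold scales up slowly with the total amount of sequence so that at
    very deep sampling error k-mers, which recur by chance, are still
    suppressed; it is monotone non-decreasing in total read count.
    """
    if not reads:
        raise ValueError("empty read set")
    total_bases = sum(len(r) for r in reads)
    return max(2, 1 + total_bases // 500_000_000)


def _all_kmer_counts(reads, k):
    # one joined pass: 'N' separators poison windows that straddle reads
    joined = "N".join(r.seq for r in reads)
    codes, valid = kmer_codes(encode(joined), k)
    if not len(codes):
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    can, _ = canonical_codes(codes[valid], k)
    return np.unique(can, return_counts=True)


def assemble_contigs(
    reads: Sequence[SequenceRecord],
    k: int = 31,
    min_contig_length: int = 200,
    min_kmer_count: int | None = None,
    dominance_ratio: float = 8.0,
) -> List[Contig]:
    """Assemble reads into contigs of at least ``min_contig_length`` bases.

    ``min_kmer_count`` defaults to :func:`kmer_noise_threshold`.  At a branch
    the walk continues only when the best extension's k-mer count is at least
    ``dominance_ratio`` times the combined count of the alternatives;
    otherwise the path is truncated conservatively.
    """
    if k % 2 == 0 or k < 11:
        raise ValueError("k must be odd and >= 11")
    if reads and k >= min(len(r) for r in reads):
        raise ValueError("k must be smaller than the read length")
    if min_contig_length < k:
        raise ValueError("min_contig_length must be >= k")
    if not reads:
        return []

    if min_kmer_count is None:
        min_kmer_count = kmer_noise_threshold(reads, k)

    codes, counts = _all_kmer_counts(reads, k)
    keep = counts >= min_kmer_count
    kept = codes[keep]
    kcounts = counts[keep]
    M = len(kept)
    log.info(
        "assembly: %d distinct k-mers, %d kept at multiplicity >= %d",
        len(codes),
        M,
        min_kmer_count,
    )
    if M == 0:
        return []

    mask = (1 << (2 * k)) - 1
    rc_kept = revcomp_codes(kept, k)

    # successor arrays per orientation: index, orientation, appended base
    succ_idx = np.full((2, M), -1, dtype=np.int64)
    succ_or = np.zeros((2, M), dtype=np.int8)
    succ_base = np.zeros((2, M), dtype=np.int8)
    for o in (0, 1):
        X = kept if o == 0 else rc_kept
        cand_idx = np.empty((4, M), dtype=np.int64)
        cand_or = np.empty((4, M), dtype=np.int8)
        cand_cnt = np.zeros((4, M), dtype=np.int64)
        for b in range(4):
            Y = ((X << 2) | b) & mask
            Yrc = revcomp_codes(Y, k)
            Ycan = np.minimum(Y, Yrc)
            idx = np.searchsorted(kept, Ycan)
            idx_c = np.clip(idx, 0, M - 1)
            present = kept[idx_c] == Ycan
            cand_idx[b] = np.where(present, idx_c, -1)
            cand_or[b] = (Yrc < Y).astype(np.int8)
            cand_cnt[b] = np.where(present, kcounts[idx_c], 0)
        total = cand_cnt.sum(axis=0)
        best_b = cand_cnt.argmax(axis=0)
        best_cnt = cand_cnt.max(axis=0)
        npresent = (cand_cnt > 0).sum(axis=0)
        others = total - best_cnt
        ok = (npresent == 1) | ((npresent > 1) & (best_cnt >= dominance_ratio * others))
        rows = np.arange(M)
        succ_idx[o] = np.where(ok, cand_idx[best_b, rows], -1)
        succ_or[o] = cand_or[best_b, rows]
        succ_base[o] = best_b.astype(np.int8)

    # an edge (u,o) -> (v,o') is usable only if the reverse walk agrees:
    # succ of (v, 1-o') must be (u, 1-o)
    valid = np.zeros((2, M), dtype=bool)
    for o in (0, 1):
        v = succ_idx[o]
        has = v >= 0
        vc = np.clip(v, 0, M - 1)
        back_o = 1 - succ_or[o]
        back_idx = succ_idx[back_o, vc]
        back_or = succ_or[back_o, vc]
        valid[o] = has & (back_idx == np.arange(M)) & (back_or == 1 - o)

    # plain python lists: the walk below is a tight scalar loop
    valid_l = [valid[0].tolist(), valid[1].tolist()]
    succ_idx_l = [succ_idx[0].tolist(), succ_idx[1].tolist()]
    succ_or_l = [succ_or[0].tolist(), succ_or[1].tolist()]
    succ_base_l = [succ_base[0].tolist(), succ_base[1].tolist()]
    counts_l = kcounts.tolist()
    visited = [False] * M
    raw: List[tuple[str, int]] = []  # (sequence, total k-mer count along path)

    def walk(start: int, o: int):
        bases = [decode_code(int(kept[start] if o == 0 else rc_kept[start]), k)]
        total_cnt = counts_l[start]
        visited[start] = True
        cur, co = start, o
        while valid_l[co][cur]:
            nxt = succ_idx_l[co][cur]
            if visited[nxt]:
                break
            bases.append("ACGT"[succ_base_l[co][cur]])
            total_cnt += counts_l[nxt]
            cur, co = nxt, succ_or_l[co][cur]
            visited[cur] = True
        return "".join(bases), total_cnt

    # linear paths: start at tips (an outgoing edge but no incoming one)
    for o in (0, 1):
        starts = np.nonzero(valid[o] & ~valid[1 - o])[0]
        for s in starts:
            if visited[s]:
                continue
            raw.append(walk(int(s), o))

    # cycles: remaining nodes whose both-side edges are intact (tandem arrays)
    for s in range(M):
        if visited[s] or not valid_l[0][s]:
            continue
        bases: List[str] = []
        total_cnt = counts_l[s]
        visited[s] = True
        cur, co = s, 0
        is_cycle = False
        for _ in range(M + 1):
            if not valid_l[co][cur]:
                break
            nxt = succ_idx_l[co][cur]
            no = succ_or_l[co][cur]
            bases.append("ACGT"[succ_base_l[co][cur]])
            if nxt == s and no == 0:
                is_cycle = True
                break
            if visited[nxt]:
                break
            total_cnt += counts_l[nxt]
            cur, co = nxt, no
            visited[cur] = True
        if is_cycle and bases:
            monomer = canonical_monomer("".join(bases))
            copies = max(3, ceil(min_contig_length / len(monomer)))
            raw.append((monomer * copies, total_cnt))
        else:
            seq = decode_code(int(kept[s]), k) + "".join(bases)
            raw.append((seq, total_cnt))

    mean_read_len = sum(len(r) for r in reads) / len(reads)
    kmers_per_read = max(1.0, mean_read_len - k + 1)
    contigs: List[Contig] = []
    for seq, total_cnt in raw:
        if len(seq) < min_contig_length:
            continue
        canon = min(seq, reverse_complement(seq))
        contigs.append(Contig("", canon, n_reads=int(round(total_cnt / kmers_per_read))))
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    for i, c in enumerate(contigs, start=1):
        c.id = f"contig_{i:05d}"
    log.info("assembled %d contigs >= %d bp from %d reads", len(contigs), min_contig_length, len(reads))
    return contigs


def write_contigs(contigs: Sequence[Contig], path) -> None:
    """Contigs as FASTA, with n_reads recorded in the description line."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} n_reads={c.n_reads}\n")
            for i in range(0, len(c.seq), 70):
                fh.write(c.seq[i : i + 70] + "\n")
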