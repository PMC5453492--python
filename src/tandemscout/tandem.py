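"""Tandem-repeat detection in contigs via wraparound dynamic programming.

The detector works in three steps, mirroring the classic tandem-repeat-finder
design while staying fully deterministic:

1. candidate periods — distances between recurrences of identical probe
   k-mers, kept only when the k-mer support at that lag covers at least a
   ``pm`` fraction of the available positions;
2. consensus calling — per-phase majority vote over the period-phased array,
   refined once through a wraparound alignment of the span against the
   voted consensus;
3. scoring — global alignment of the span against an unbounded cyclic
   concatenation of the consensus monomer (wraparound DP, linear gaps),
   with annotations below ``min_score`` or above ``max_period`` discarded.

A perfect c-copy array of monomer m scores exactly ``2 * c * len(m)`` under
the default +2/-7/-7 weights, so arrays shorter than 25 bases can never
reach the min score of 50.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from math import ceil
from typing import List, Sequence, Tuple

import numpy as np

from ._kmers import canonical_monomer, encode, kmer_codes  # noqa: F401  (canonical_monomer re-exported)
from .assemble import Contig
from .params import ScoringParams

log = logging.getLogger("tandemscout")


@dataclass(frozen=True)
class TandemAnnotation:
    """One detected tandem array on a contig (0-based half-open span)."""

    contig_id: str
    start: int
    end: int
    period: int
    consensus: str
    score: int
    copy_number: float


# ---------------------------------------------------------------------------
# wraparound dynamic programming


def _wdp_matrix(seq_codes: np.ndarray, mon_codes: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Full DP matrix W[i, j]: best score of seq[:i] ending at monomer column j.

    Row 0 is all zeros (the alignment may start at any monomer phase).  The
    horizontal (within-row) gap closure is a running-max prefix scan; one
    extra pass propagates scores that wrap across the monomer boundary,
    which suffices because a full circle of gaps can never gain score.
    """
    n, p = len(seq_codes), len(mon_codes)
    g = params.indel
    W = np.zeros((n + 1, p), dtype=np.int32)
    idx_g = np.arange(p, dtype=np.int32) * g
    for i in range(1, n + 1):
        sub = np.where(mon_codes == seq_codes[i - 1], params.match, params.mismatch)
        prev = W[i - 1]
        base = np.maximum(np.roll(prev, 1) + sub, prev + g)
        row = np.maximum.accumulate(base - idx_g) + idx_g
        row = np.maximum(row, row[p - 1] + idx_g + g)  # wrap once through column p-1
        W[i] = row
    return W


def wraparound_align(
    seq: str, monomer: str, params: ScoringParams | None = None
) -> Tuple[int, List[Tuple[int, int]]]:
    """Score ``seq`` against an unbounded cyclic concatenation of ``monomer``.

    Returns ``(score, pairs)`` where ``pairs`` lists the (sequence position,
    monomer column) of every aligned (match or mismatch) base on the optimal
    path.  The alignment is global in the sequence and free in monomer phase.
    """
    params = params or ScoringParams()
    if not seq or not monomer:
        raise ValueError("empty sequence or monomer")
    if len(monomer) > params.max_period:
        raise ValueError(f"monomer longer than max_period {params.max_period}")
    s = encode(seq).astype(np.int16)
    m = encode(monomer).astype(np.int16)
    n, p = len(s), len(m)
    W = _wdp_matrix(s, m, params)
    g = params.indel
    score = int(W[n].max())

    # traceback: prefer diagonal, then vertical, then horizontal (deterministic)
    pairs: List[Tuple[int, int]] = []
    i, j = n, int(W[n].argmax())
    guard = (n + 1) * (p + 2)
    while i > 0 and guard > 0:
        guard -= 1
        jm1 = (j - 1) % p
        sub = params.match if m[j] == s[i - 1] else params.mismatch
        w = W[i][j]
        if w == W[i - 1][jm1] + sub:
            pairs.append((i - 1, j))
            i, j = i - 1, jm1
        elif w == W[i - 1][j] + g:
            i -= 1
        elif w == W[i][jm1] + g:
            j = jm1
        else:  # pragma: no cover - row 0 is all zeros, so i must reach 0
            break
    pairs.reverse()
    return score, pairs


# ---------------------------------------------------------------------------
# candidate periods


def find_candidate_periods(
    seq: str,
    k: int | None = None,
    max_period: int | None = None,
    pm: float | None = None,
    params: ScoringParams | None = None,
) -> List[Tuple[int, int]]:
    """Candidate (period, support) pairs, sorted by support (descending).

    Support for a lag d is the number of positions i whose probe k-mer
    recurs exactly d bases downstream; a lag is retained only when support
    reaches ``ceil(pm * (len(seq) - d - k))``, i.e. the periodicity spans
    essentially the whole sequence.
    """
    params = params or ScoringParams()
    k = k if k is not None else params.probe_k
    max_period = max_period if max_period is not None else params.max_period
    pm = pm if pm is not None else params.pm
    n = len(seq)
    if n < 2 * k:
        return []
    arr = encode(seq)
    codes, valid = kmer_codes(arr, k)
    pos = np.nonzero(valid)[0]
    codes = codes[pos]
    if len(codes) < 2:
        return []
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], pos[order]
    same = sc[1:] == sc[:-1]
    gaps = (sp[1:] - sp[:-1])[same]
    if len(gaps) == 0:
        return []
    gvals, gcounts = np.unique(gaps, return_counts=True)
    base = gvals[gcounts >= 2]
    if len(base) > 64:  # cap work on low-complexity sequence
        base = base[np.argsort(gcounts[gcounts >= 2])[::-1][:64]]
    cands = set()
    limit = min(max_period, n - k - 1)
    for d in base:
        for mult in range(1, 9):
            dd = int(d) * mult
            if dd > limit:
                break
            cands.add(dd)

    out = []
    a = arr.astype(np.int16)
    bad = arr > 3
    for d in sorted(cands):
        eq = (a[: n - d] == a[d:]) & ~bad[: n - d] & ~bad[d:]
        m = n - d - k
        if m < 1:
            continue
        cs = np.concatenate(([0], np.cumsum(eq)))
        support = int(np.count_nonzero((cs[k:] - cs[:-k]) == k))
        if support >= ceil(pm * m):
            out.append((d, support))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# consensus and detection


def _vote(columns: List[List[str]], fallback: str | None = None) -> str:
    out = []
    for j, col in enumerate(columns):
        if not col:
            out.append(fallback[j] if fallback else "A")
            continue
        counts = Counter(col)
        top = max(counts.values())
        out.append(min(b for b, c in counts.items() if c == top))  # tie -> alphabetical
    return "".join(out)


def consensus_monomer(seq: str, period: int, params: ScoringParams | None = None) -> str:
    """Majority-vote consensus of a period-phased array, refined by one
    wraparound realignment.  Ties break to the alphabetically first base."""
    params = params or ScoringParams()
    if period < 1 or period > len(seq) // 2:
        raise ValueError(f"period {period} not supported for sequence of length {len(seq)}")
    cols: List[List[str]] = [[] for _ in range(period)]
    for i, b in enumerate(seq):
        if b != "N":
            cols[i % period].append(b)
    c0 = _vote(cols)
    # refine once: realign against the voted consensus and re-vote columns
    _, pairs = wraparound_align(seq, c0, params)
    cols2: List[List[str]] = [[] for _ in range(period)]
    for i, j in pairs:
        if seq[i] != "N":
            cols2[j].append(seq[i])
    return _vote(cols2, fallback=c0)


def detect_tandem_repeats(
    contig: Contig, params: ScoringParams | None = None
) -> List[TandemAnnotation]:
    """All tandem annotations on a contig passing the score/period filters.

    Overlapping annotations are resolved to the highest score (ties to the
    smaller period), so a perfect multiple of a primitive period is
    suppressed in favour of the primitive one; results are sorted by start.
    """
    params = params or ScoringParams()
    seq = contig.seq
    n = len(seq)
    cands = find_candidate_periods(seq, params=params)
    anns: List[TandemAnnotation] = []
    a = encode(seq)
    for d, _support in sorted(cands):
        eq = np.nonzero((a[: n - d] == a[d:]) & (a[: n - d] <= 3))[0]
        if len(eq) == 0:
            continue
        s, e = int(eq[0]), int(eq[-1]) + d + 1
        if e - s < 2 * d:
            continue
        span = seq[s:e]
        cons = consensus_monomer(span, d, params)
        score, _ = wraparound_align(span, cons, params)
        if score >= params.min_score and d <= params.max_period:
            anns.append(
                TandemAnnotation(
                    contig_id=contig.id,
                    start=s,
                    end=e,
                    period=d,
                    consensus=cons,
                    score=score,
                    copy_number=(e - s) / d,
                )
            )
    # overlap resolution: greedy by score (ties: smaller period, earlier start)
    anns.sort(key=lambda x: (-x.score, x.period, x.start))
    kept: List[TandemAnnotation] = []
    for ann in anns:
        if all(ann.end <= q.start or ann.start >= q.end for q in kept):
            kept.append(ann)
    kept.sort(key=lambda x: x.start)
    return kept


def representative_annotation(anns: Sequence[TandemAnnotation]) -> TandemAnnotation:
    """The contig's representative repeat: highest score, then smallest period."""
    return min(anns, key=lambda x: (-x.score, x.period, x.start))


def filter_tandem_contigs(
    contigs: Sequence[Contig], params: ScoringParams | None = None
) -> Tuple[List[Tuple[Contig, List[TandemAnnotation]]], List[Contig]]:
    """Partition contigs into (tandem-bearing with annotations, discarded)."""
    params = params or ScoringParams()
    tandem: List[Tuple[Contig, List[TandemAnnotation]]] = []
    discarded: List[Contig] = []
    for c in contigs:
        anns = detect_tandem_repeats(c, params)
        if anns:
            tandem.append((c, anns))
        else:
            discarded.append(c)
    log.info("tandem filter: %d retained, %d discarded", len(tandem), len(discarded))
    return tandem, discarded
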