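"""Summary artifacts: composition tables, genome-size correlation, dot plots.

Tables are the contract; plots are optional image artifacts behind a flag.
Percentages are reported to 2 decimal places in text outputs, full
precision in machine-readable columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._kmers import encode, reverse_complement
from .families import RepeatFamily
from .simulate import SimulationTruth

log = logging.getLogger("tandemscout")


@dataclass
class CompositionReport:
    """Total tandem fraction plus the per-family composition table."""

    total_tandem_fraction: float
    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_tandem_fraction\t{self.total_tandem_fraction:.10g}\n")
            fh.write(
                f"# total_tandem_percent\t{100 * self.total_tandem_fraction:.2f}\n"
            )
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def composition_report(
    families: Sequence[RepeatFamily],
    total_fraction: float,
    truth: Optional[SimulationTruth] = None,
) -> CompositionReport:
    """Tabulate family compositions (fractions and percentages), optionally
    joined against simulation truth on the canonical monomer."""
    rows: List[dict] = []
    truth_by_monomer = (
        {f.monomer: f for f in truth.families} if truth is not None else {}
    )
    for fam in families:
        row = {
            "rank": fam.rank,
            "seed_contig": fam.seed_contig_id,
            "monomer_length": len(fam.seed_monomer),
            "n_members": len(fam.members),
            "reads": fam.recruited_reads,
            "fraction": fam.genomic_fraction,
            "percent": 100.0 * fam.genomic_fraction,
        }
        if truth is not None:
            t = truth_by_monomer.get(fam.seed_monomer)
            row["truth_family"] = t.name if t else ""
            row["truth_fraction"] = t.true_fraction if t else np.nan
        rows.append(row)
    cols = ["rank", "seed_contig", "monomer_length", "n_members", "reads", "fraction", "percent"]
    if truth is not None:
        cols += ["truth_family", "truth_fraction"]
    frame = pd.DataFrame(rows, columns=cols)
    return CompositionReport(total_tandem_fraction=total_fraction, frame=frame)


def genome_size_correlation(
    fractions: Mapping[str, float] | pd.Series,
    sizes: pd.DataFrame,
) -> Tuple[float, float, int]:
    """Pearson correlation between per-taxon tandem fraction and genome size.

    Pairs are matched by taxon name; unmatched taxa are dropped with a
    warning.  Returns (r, two-sided p, n); fewer than 3 pairs is an error.
    """
    if isinstance(fractions, pd.Series):
        fractions = fractions.to_dict()
    size_map = dict(zip(sizes["taxon"], sizes["genome_size_pg"]))
    xs, ys = [], []
    for taxon, frac in fractions.items():
        if taxon in size_map:
            xs.append(size_map[taxon])
            ys.append(frac)
        else:
            log.warning("taxon %r has no genome size entry; dropped", taxon)
    for taxon in size_map:
        if taxon not in fractions:
            log.warning("taxon %r has no tandem fraction; dropped", taxon)
    n = len(xs)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def self_dotplot(seq: str, window: int, min_identity: float) -> np.ndarray:
    """Boolean match matrix: point (i, j) iff the windows at i and j match
    at >= ``min_identity`` on either strand.  Symmetric; the main diagonal
    is always present."""
    if window < 4:
        raise ValueError("window must be >= 4")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    arr = encode(seq)
    W = np.lib.stride_tricks.sliding_window_view(arr, window)
    rc = encode(reverse_complement(seq))
    Wrc = np.lib.stride_tricks.sliding_window_view(rc, window)[::-1]
    N = len(W)
    need = min_identity * window
    out = np.zeros((N, N), dtype=bool)
    chunk = max(1, int(4e7) // (N * window + 1))
    for i0 in range(0, N, chunk):
        i1 = min(N, i0 + chunk)
        fwd = (W[i0:i1, None, :] == W[None, :, :]).sum(axis=2)
        rcm = (W[i0:i1, None, :] == Wrc[None, :, :]).sum(axis=2)
        out[i0:i1] = (fwd >= need) | (rcm >= need)
    np.fill_diagonal(out, True)
    return out


def save_dotplot(matrix: np.ndarray, path, title: str = "") -> None:
    """Render a dot-plot matrix to an image file (optional artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ys, xs = np.nonzero(matrix)
    ax.plot(xs, ys, ",k", markersize=1)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
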