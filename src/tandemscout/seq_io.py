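"""Sequence and table I/O for the pipeline.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the strict
validation the rest of the pipeline relies on: upper-cased sequences over
{A,C,G,T,N}, non-empty ids, and quality strings matching sequence length.
All genomic coordinates produced anywhere in this package are 0-based,
half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("tandemscout")

_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single read or contig: id, sequence, optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: bases outside ACGTN: {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: str) -> List[SequenceRecord]:
    """Parse a FASTA or FASTQ file into validated records, in file order.

    Lowercase bases are upper-cased; bases outside {A,C,G,T,N} are rejected.
    An empty file yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, format), start=1):
                seq = str(rec.seq).upper()
                qual = None
                if format == "fastq":
                    quals = rec.letter_annotations.get("phred_quality")
                    qual = "".join(chr(q + 33) for q in quals) if quals is not None else None
                try:
                    records.append(SequenceRecord(rec.id, seq, qual))
                except ValueError as e:
                    raise ParseError(f"{path}: record {i}: {e}") from e
        except ValueError as e:
            if isinstance(e, ParseError):
                raise
            raise ParseError(f"{path}: record {len(records) + 1}: {e}") from e
    log.info("read %d records from %s", len(records), path)
    return records


def write_sequences(records: Iterable[SequenceRecord], path, format: str) -> None:
    """Write records as FASTA or FASTQ.

    FASTA silently drops quality strings (format semantics).  FASTQ requires
    every record to carry qualities.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    records = list(records)
    with _open_text(path, "wt") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.seq), 70):
                    fh.write(rec.seq[i : i + 70] + "\n")
            else:
                if rec.qual is None:
                    raise ValueError(
                        f"record {rec.id!r} has no qualities; cannot write FASTQ"
                    )
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
    log.info("wrote %d records to %s", len(records), path)


def load_genome_sizes(path) -> pd.DataFrame:
    """Load a tab-separated (taxon, genome size in pg/1C) table.

    Returns a DataFrame with columns ``taxon`` and ``genome_size_pg``.
    Rows must have unique taxa and strictly positive sizes.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least two columns (taxon, size)")
    # tolerate a header row
    first = df.iloc[0, 1]
    try:
        float(first)
        start = 0
    except ValueError:
        start = 1
    rows = []
    for i in range(start, len(df)):
        taxon = str(df.iloc[i, 0]).strip()
        raw = str(df.iloc[i, 1]).strip()
        try:
            size = float(raw)
        except ValueError:
            raise ParseError(f"{path}: row {i + 1}: non-numeric size {raw!r}") from None
        if size <= 0:
            raise ParseError(f"{path}: row {i + 1}: genome size must be > 0, got {size}")
        rows.append((taxon, size))
    out = pd.DataFrame(rows, columns=["taxon", "genome_size_pg"])
    if out["taxon"].duplicated().any():
        dups = out.loc[out["taxon"].duplicated(), "taxon"].tolist()
        raise ParseError(f"{path}: duplicate taxa {dups}")
    log.info("loaded %d genome sizes from %s", len(out), path)
    return out


def packaged_genome_sizes() -> pd.DataFrame:
    """The genome-size table bundled with the package (Andropogoneae panel)."""
    from importlib.resources import files

    return load_genome_sizes(files("tandemscout.data") / "genome_sizes.tsv")
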