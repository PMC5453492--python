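"""Repeat-genome simulation with a machine-readable truth table.

Builds genomes containing (a) tandem arrays of specified monomers, (b)
optional dispersed TE-like repeats, and (c) unique background sequence, then
samples single-end shotgun reads with substitution errors, emulating a
low-coverage short-read survey design (150 bp reads, coverage well below
1X by default).  Every operation is deterministic for a fixed seed.

Truth fractions are computed from planted reference bases, not from sampled
reads: estimation error is the pipeline's to measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._kmers import canonical_monomer, reverse_complement
from .seq_io import SequenceRecord

log = logging.getLogger("tandemscout")

_BASES = np.array(list("ACGT"))


@dataclass
class RepeatFamilySpec:
    """One planted tandem-repeat family.

    Either give an explicit ``monomer`` or a ``monomer_length`` (with ``gc``)
    to auto-generate one.  ``per_copy_mutation_rate`` is substitutions per
    base applied independently to each monomer copy, emulating intra-family
    divergence of a satellite.
    """

    name: str
    monomer: Optional[str] = None
    monomer_length: Optional[int] = None
    gc: float = 0.5
    n_arrays: int = 1
    copies_per_array: int = 10
    per_copy_mutation_rate: float = 0.0

    def __post_init__(self):
        if self.monomer is None and self.monomer_length is None:
            raise ValueError(f"family {self.name}: need monomer or monomer_length")
        length = len(self.monomer) if self.monomer else self.monomer_length
        if not 2 <= length <= 2000:
            raise ValueError(f"family {self.name}: monomer length {length} not in [2, 2000]")
        if self.n_arrays < 1 or self.copies_per_array < 1:
            raise ValueError(f"family {self.name}: n_arrays and copies_per_array must be >= 1")
        if not 0 <= self.per_copy_mutation_rate <= 0.2:
            raise ValueError(f"family {self.name}: per_copy_mutation_rate not in [0, 0.2]")

    @property
    def planted_bases(self) -> int:
        length = len(self.monomer) if self.monomer else self.monomer_length
        return length * self.copies_per_array * self.n_arrays


@dataclass
class GenomeSpec:
    """A synthetic genome: background + planted families + optional TEs."""

    length: int
    gc: float = 0.5
    families: List[RepeatFamilySpec] = field(default_factory=list)
    te_spec: Optional[Tuple[int, int, float]] = None  # (te_length, n_copies, mut_rate)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        planted = sum(f.planted_bases for f in self.families)
        if self.te_spec is not None:
            planted += self.te_spec[0] * self.te_spec[1]
        if planted > self.length:
            raise ValueError(
                f"planted bases ({planted}) exceed genome length ({self.length})"
            )


@dataclass
class FamilyTruth:
    name: str
    monomer: str  # canonical form
    planted_bases: int
    true_fraction: float
    intervals: List[Tuple[int, int]] = field(default_factory=list)  # 0-based half-open


@dataclass
class SimulationTruth:
    """Planted families and their exact genomic fractions — the oracle."""

    genome_length: int
    families: List[FamilyTruth]

    @property
    def total_tandem_fraction(self) -> float:
        return sum(f.true_fraction for f in self.families)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": f.name,
                    "monomer": f.monomer,
                    "planted_bases": f.planted_bases,
                    "true_fraction": f.true_fraction,
                }
                for f in self.families
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _has_subperiod(seq: str) -> bool:
    n = len(seq)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and seq == seq[:d] * (n // d):
            return True
    return False


def generate_monomer(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """A random monomer of exactly ``length`` bases at the given GC.

    Rejection-resamples until the result is not a perfect tandem of a
    shorter period, so a planted array's period is unambiguous.
    """
    if not 2 <= length <= 2000:
        raise ValueError(f"monomer length {length} not in [2, 2000]")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        seq = _random_seq(rng, length, gc)
        if not _has_subperiod(seq):
            return seq
    raise RuntimeError("could not sample a primitive monomer")  # pragma: no cover


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return seq
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    for i in hit:
        arr[i] = rng.choice(lut[arr[i]])
    return arr.tobytes().decode()


def build_genome(spec: GenomeSpec) -> Tuple[str, SimulationTruth]:
    """Assemble the genome: blocks (arrays, TE copies) spliced into background.

    Arrays are head-to-tail copies of the (per-copy mutated) monomer, each
    array on a random strand, placed at non-overlapping loci separated by
    random background gaps.  Returns the sequence and the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: List[Tuple[str, Optional[int]]] = []  # (sequence, family index or None)

    monomers: List[str] = []
    for fi, fam in enumerate(spec.families):
        if fam.monomer is not None:
            monomer = fam.monomer.upper()
        else:
            monomer = generate_monomer(
                fam.monomer_length, fam.gc, seed=int(rng.integers(2**31))
            )
        monomers.append(monomer)
        for _ in range(fam.n_arrays):
            copies = [
                _mutate(rng, monomer, fam.per_copy_mutation_rate)
                for _ in range(fam.copies_per_array)
            ]
            array = "".join(copies)
            if rng.random() < 0.5:
                array = reverse_complement(array)
            blocks.append((array, fi))

    if spec.te_spec is not None:
        te_len, te_n, te_mut = spec.te_spec
        te = _random_seq(rng, te_len, spec.gc)
        for _ in range(te_n):
            copy = _mutate(rng, te, te_mut)
            if rng.random() < 0.5:
                copy = reverse_complement(copy)
            blocks.append((copy, None))

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    planted = sum(len(b) for b, _ in blocks)
    free = spec.length - planted
    # random gap allocation: free background bases split across len(blocks)+1 gaps
    if blocks:
        cuts = np.sort(rng.integers(0, free + 1, size=len(blocks)))
        gaps = np.diff(np.concatenate(([0], cuts, [free])))
    else:
        gaps = np.array([free])

    parts: List[str] = []
    pos = 0
    intervals: dict[int, List[Tuple[int, int]]] = {}
    for i, (block, fi) in enumerate(blocks):
        g = _random_seq(rng, int(gaps[i]), spec.gc)
        parts.append(g)
        pos += len(g)
        parts.append(block)
        if fi is not None:
            intervals.setdefault(fi, []).append((pos, pos + len(block)))
        pos += len(block)
    parts.append(_random_seq(rng, int(gaps[-1]), spec.gc))
    genome = "".join(parts)
    assert len(genome) == spec.length

    fams = []
    for fi, fam in enumerate(spec.families):
        fams.append(
            FamilyTruth(
                name=fam.name,
                monomer=canonical_monomer(monomers[fi]),
                planted_bases=fam.planted_bases,
                true_fraction=fam.planted_bases / spec.length,
                intervals=intervals.get(fi, []),
            )
        )
    truth = SimulationTruth(genome_length=spec.length, families=fams)
    log.info(
        "built %d bp genome: %d families, total tandem fraction %.4f",
        spec.length,
        len(fams),
        truth.total_tandem_fraction,
    )
    return genome, truth


def shotgun_reads(
    genome: str,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> List[SequenceRecord]:
    """Uniform single-end shotgun sampling with i.i.d. substitution errors.

    Emits ``ceil(coverage * genome_length / read_length)`` reads; start
    positions and strands uniform; deterministic for a fixed seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_reads = ceil(coverage * len(genome) / read_length)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    reads: List[SequenceRecord] = []
    qual = "I" * read_length
    for i in range(n_reads):
        s = int(starts[i])
        seq = arr[s : s + read_length].tobytes().decode()
        strand = "+"
        if strands[i]:
            seq = reverse_complement(seq)
            strand = "-"
        if error_rate > 0:
            seq = _mutate(rng, seq, error_rate)
        # id carries provenance (start, strand) for downstream validation
        reads.append(SequenceRecord(f"read_{i:07d}_{s}_{strand}", seq, qual))
    log.info("simulated %d reads of %d bp (coverage %.3gX)", n_reads, read_length, coverage)
    return reads
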