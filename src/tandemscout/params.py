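"""Parameter sets for tandem detection, homology grouping, and the pipeline.

Defaults follow the classic tandem-repeat-finder weighting (match +2,
mismatch/indel -7, min score 50, max period 2000) and a permissive
E <= 0.1 homology threshold for family grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import yaml
from scipy.optimize import brentq


@dataclass(frozen=True)
class ScoringParams:
    """Weights for wraparound tandem alignment and detection thresholds.

    ``pm`` is the target per-base match probability used by the
    period-candidate heuristic; ``pi`` (target indel probability) is carried
    for completeness but unused by the substitution-only scorer.
    """

    match: int = 2
    mismatch: int = -7
    indel: int = -7
    min_score: int = 50
    max_period: int = 2000
    pm: float = 0.80
    pi: float = 0.10
    probe_k: int = 4  # k-mer size of the period-candidate heuristic

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch and self.indel < 0):
            raise ValueError("need match > 0 > mismatch, indel")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")
        if not 2 <= self.max_period <= 2000:
            raise ValueError("max_period must be in [2, 2000]")
        if not 0 < self.pm <= 1:
            raise ValueError("pm must be in (0, 1]")


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int) -> float:
    """Ungapped Karlin-Altschul lambda for equal base frequencies.

    Solves E[exp(lambda * S)] = 1 for a random aligned base pair, where the
    score S is ``match`` with probability 1/4 and ``mismatch`` with 3/4.
    """
    import math

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass(frozen=True)
class HomologyParams:
    """Seeded ungapped local-alignment search used for family grouping.

    The E-value of a segment pair of score S in a search of query length m
    against a database of total length n is ``K * m * n * exp(-lambda * S)``;
    contigs with a hit at E <= ``evalue_max`` join the seed's family.
    ``karlin_k`` is the standard ungapped K for +1/-2 at equal base
    frequencies; lambda is computed from the weights.
    """

    evalue_max: float = 0.1
    word_size: int = 16
    match: int = 1
    mismatch: int = -2
    xdrop: int = 10
    karlin_k: float = 0.621

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")

    @property
    def karlin_lambda(self) -> float:
        return karlin_lambda(self.match, self.mismatch)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with study defaults."""

    # assembly
    assembly_k: int = 31
    min_contig_length: int = 200
    min_kmer_count: int | None = None  # None -> kmer_noise_threshold default
    dominance_ratio: float = 8.0
    # tandem detection
    scoring: ScoringParams = field(default_factory=ScoringParams)
    # recruitment
    seed_k: int = 15
    min_identity: float = 0.85
    # family extraction
    homology: HomologyParams = field(default_factory=HomologyParams)
    n_families: int = 4
    min_monomer_length: int = 30
    # simulation
    read_length: int = 150
    coverage: float = 0.05
    error_rate: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        raw.pop("genome", None)  # genome-spec section, consumed by the CLI
        scoring = ScoringParams(**raw.pop("scoring", {}))
        homology = HomologyParams(**raw.pop("homology", {}))
        return cls(scoring=scoring, homology=homology, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
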