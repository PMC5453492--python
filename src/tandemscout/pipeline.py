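"""End-to-end orchestration: reads -> contigs -> tandem filter -> recruitment
-> family extraction -> composition report.

All stages are deterministic given the input reads and configuration; the
synthetic entry point derives every random stream from one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .assemble import Contig, assemble_contigs, write_contigs
from .families import RepeatFamily, extract_top_families, family_composition
from .params import PipelineConfig
from .recruit import (
    ReadKmerIndex,
    RecruitmentResult,
    recruit_reads,
    total_tandem_fraction,
)
from .report import CompositionReport, composition_report
from .seq_io import SequenceRecord, write_sequences
from .simulate import (
    GenomeSpec,
    RepeatFamilySpec,
    SimulationTruth,
    build_genome,
    shotgun_reads,
)
from .tandem import TandemAnnotation, filter_tandem_contigs

log = logging.getLogger("tandemscout")


@dataclass
class PipelineResult:
    contigs: List[Contig]
    tandem: List[Tuple[Contig, List[TandemAnnotation]]]
    recruitment: Optional[RecruitmentResult]
    families: List[RepeatFamily]
    total_fraction: float
    composition: CompositionReport
    truth: Optional[SimulationTruth] = None
    reads: List[SequenceRecord] = field(default_factory=list)


def run_from_reads(
    reads: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
    truth: Optional[SimulationTruth] = None,
) -> PipelineResult:
    """Run every analysis stage on an existing read set."""
    config = config or PipelineConfig()
    contigs = assemble_contigs(
        reads,
        k=config.assembly_k,
        min_contig_length=config.min_contig_length,
        min_kmer_count=config.min_kmer_count,
        dominance_ratio=config.dominance_ratio,
    )
    tandem, _discarded = filter_tandem_contigs(contigs, config.scoring)
    if not tandem:
        comp = composition_report([], 0.0, truth)
        return PipelineResult(contigs, [], None, [], 0.0, comp, truth, list(reads))
    index = ReadKmerIndex(reads, config.seed_k)
    recruitment = recruit_reads(
        reads, [c for c, _ in tandem], config.seed_k, config.min_identity, index=index
    )
    families = extract_top_families(
        tandem,
        recruitment,
        n_families=config.n_families,
        params=config.homology,
        min_monomer_length=config.min_monomer_length,
    )
    for fam in families:
        family_composition(fam, reads, config.seed_k, config.min_identity, index=index)
    total = total_tandem_fraction(recruitment) if reads else 0.0
    comp = composition_report(families, total, truth)
    return PipelineResult(
        contigs, tandem, recruitment, families, total, comp, truth, list(reads)
    )


def demo_genome_spec(seed: int, length: int = 1_000_000) -> GenomeSpec:
    """The package's reference simulation: three tandem families at roughly
    10%, 5% and 1% of a 1 Mb genome (monomers of 180, 350 and 184 bp, the
    monomer lengths typical of grass knob/centromere satellites), plus a
    dispersed TE-like repeat, on a random background."""
    targets = [("sat180", 180, 0.10, 4), ("sat350", 350, 0.05, 2), ("sat184", 184, 0.01, 1)]
    fams = [
        RepeatFamilySpec(
            name=name,
            monomer_length=p,
            n_arrays=n_arrays,
            copies_per_array=max(2, round(frac * length / (p * n_arrays))),
            per_copy_mutation_rate=0.01,
        )
        for name, p, frac, n_arrays in targets
    ]
    return GenomeSpec(
        length=length,
        gc=0.47,
        families=fams,
        te_spec=(3000, max(1, round(10 * length / 1_000_000)), 0.05),
        seed=seed,
    )


def run_synthetic(
    spec: GenomeSpec,
    config: PipelineConfig | None = None,
    n_reads: int | None = None,
) -> PipelineResult:
    """Simulate a genome + reads from ``spec`` and run the full pipeline.

    ``n_reads`` overrides the configured coverage (reads = coverage * G / L).
    """
    config = config or PipelineConfig()
    genome, truth = build_genome(spec)
    coverage = config.coverage
    if n_reads is not None:
        coverage = n_reads * config.read_length / len(genome)
    reads = shotgun_reads(
        genome,
        coverage=coverage,
        read_length=config.read_length,
        error_rate=config.error_rate,
        seed=spec.seed + 1,
    )
    return run_from_reads(reads, config, truth)


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write every pipeline artifact as deterministic text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_contigs(result.contigs, out / "contigs.fasta")
    write_contigs([c for c, _ in result.tandem], out / "tandem_contigs.fasta")

    with open(out / "annotations.tsv", "w") as fh:
        fh.write("contig_id\tstart\tend\tperiod\tcopy_number\tscore\tconsensus\n")
        for c, anns in result.tandem:
            for a in anns:
                fh.write(
                    f"{a.contig_id}\t{a.start}\t{a.end}\t{a.period}\t"
                    f"{a.copy_number:.6g}\t{a.score}\t{a.consensus}\n"
                )

    if result.recruitment is not None:
        result.recruitment.to_frame().to_csv(
            out / "recruitment.tsv", sep="\t", index=False, float_format="%.10g"
        )
    else:
        (out / "recruitment.tsv").write_text("contig_id\treads\tfraction\n")

    with open(out / "families.tsv", "w") as fh:
        fh.write(
            "rank\tseed_contig\tmonomer_length\tmembers\treads\tgenomic_fraction\n"
        )
        for f in result.families:
            fh.write(
                f"{f.rank}\t{f.seed_contig_id}\t{len(f.seed_monomer)}\t"
                f"{','.join(sorted(f.members))}\t{f.recruited_reads}\t"
                f"{f.genomic_fraction:.10g}\n"
            )
    monomer_records = [
        SequenceRecord(f"family_{f.rank}", f.seed_monomer) for f in result.families
    ]
    if monomer_records:
        write_sequences(monomer_records, out / "family_monomers.fasta", "fasta")
    else:
        (out / "family_monomers.fasta").write_text("")

    result.composition.to_tsv(out / "composition.tsv")
    if result.truth is not None:
        result.truth.to_tsv(out / "truth.tsv")
    log.info("wrote pipeline outputs to %s", out)
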