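"""End-to-end orchestration: simulate -> call -> filter -> matrix -> caps.

Each stage writes a file the next stage can consume, so a run leaves a
fully inspectable trail: reference FASTA, per-sample pileups, raw and
filtered VCFs, the cohort frequency matrix and the designed assay sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats, snp_matrix, variant_calling
from .caps_design import PrimerConstraints, design_assays
from .io_formats import iter_pileup, write_assay_table, write_fasta, write_vcf_min
from .snp_matrix import export_matrix, select_joint_sites, subsample_sites
from .synthetic_cohort import CohortConfig, generate_genotypes, generate_reference, simulate_pileups
from .variant_calling import FilterParams, apply_filters, call_candidates, filter_clause_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterParams = field(default_factory=FilterParams)
    min_joint_dp: int = 5
    subsample: Optional[int] = None
    subsample_seed: int = 7
    primer_constraints: PrimerConstraints = field(default_factory=PrimerConstraints)


@dataclass
class PipelineResult:
    reference: object
    truth: object
    pileup_paths: dict
    raw_vcf_paths: dict
    filtered_vcf_paths: dict
    candidate_sites: list
    matrix: object
    assays: list
    paths: dict


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage on a freshly simulated cohort; returns all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort

    logger.info("stage simulate: %d samples, %d bp, seed %d",
                cohort.n_samples, cohort.genome_length, cohort.seed)
    reference, motifs = generate_reference(cohort)
    truth = generate_genotypes(cohort, reference, motifs)
    fasta_path = outdir / "genome.fasta"
    write_fasta([reference], fasta_path)
    _write_truth(truth, outdir)
    pileup_paths = simulate_pileups(truth, reference, cohort, outdir / "pileups")

    raw_vcf_paths: dict[str, Path] = {}
    filtered_vcf_paths: dict[str, Path] = {}
    union: dict[tuple, None] = {}
    error_rate = max(cohort.error_rate, 1e-4)  # calling model needs a positive rate
    for sample, ppath in pileup_paths.items():
        records = call_candidates(iter_pileup(ppath), error_rate)
        raw = outdir / f"{sample}.vcf"
        write_vcf_min(records, raw)
        raw_vcf_paths[sample] = raw
        report = filter_clause_report(records, config.filters)
        logger.info("stage filter [%s]: %s", sample, report)
        kept = apply_filters(records, config.filters)
        fpath = outdir / f"{sample}.filtered.vcf"
        write_vcf_min(kept, fpath)
        filtered_vcf_paths[sample] = fpath
        for r in kept:
            union.setdefault(r.site, None)

    candidate_sites = sorted(union, key=lambda s: (s[0], s[1]))
    logger.info("stage matrix: %d candidate sites across cohort", len(candidate_sites))
    matrix = select_joint_sites(
        {s: iter_pileup(p) for s, p in pileup_paths.items()},
        candidate_sites,
        min_joint_dp=config.min_joint_dp,
    )
    if config.subsample is not None:
        matrix = subsample_sites(matrix, config.subsample, seed=config.subsample_seed)
    matrix_path = outdir / "matrix.tsv"
    export_matrix(matrix, matrix_path)

    logger.info("stage caps: designing assays for %d sites", len(matrix.sites))
    assays = design_assays(reference, matrix.sites, constraints=config.primer_constraints)
    assay_path = outdir / "assays.tsv"
    write_assay_table(assays, assay_path)
    logger.info("designed %d assays", len(assays))

    return PipelineResult(
        reference=reference,
        truth=truth,
        pileup_paths=pileup_paths,
        raw_vcf_paths=raw_vcf_paths,
        filtered_vcf_paths=filtered_vcf_paths,
        candidate_sites=candidate_sites,
        matrix=matrix,
        assays=assays,
        paths={
            "fasta": fasta_path,
            "matrix": matrix_path,
            "assays": assay_path,
        },
    )


def _write_truth(truth, outdir: Path) -> None:
    with open(outdir / "truth_sites.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(truth.sample_ids) + "\n")
        for i, (chrom, pos, ref, alt) in enumerate(truth.sites):
            gts = "\t".join(str(int(g)) for g in truth.genotypes[i])
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{gts}\n")
    with open(outdir / "truth_planted.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tenzyme\n")
        for p in truth.planted:
            fh.write(f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.alt}\t{p.enzyme}\n")
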