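"""Cohort-wide variant-allele frequencies at jointly covered sites.

A site enters the matrix only if every sample in the cohort covers it with
at least ``min_joint_dp`` counted bases (default 5).  The frequency of the
designated alternate allele is then ``count(alt) / total counted bases``
per sample, so in a diploid it sits near 0 for homozygous-reference
samples, near 1 for homozygous-alternate samples and near 0.5 for
heterozygotes.  The alt allele of each site is fixed cohort-wide, so one
matrix column means the same substitution in every sample.

"Depth" for the joint-coverage gate is counted base calls
(``BaseCounts.total``), not the printed pileup depth field: frequencies
are ratios over counted bases, so the gate matches the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BaseCounts, PileupColumn

__all__ = [
    "GenotypeClass",
    "AlleleFrequencyMatrix",
    "allele_frequency",
    "select_joint_sites",
    "classify_genotype",
    "classify_matrix",
    "subsample_sites",
    "export_matrix",
    "heatmap_data",
]

logger = logging.getLogger(__name__)

Site = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


class GenotypeClass(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass
class AlleleFrequencyMatrix:
    """sites x samples variant-allele frequencies plus counted depths."""

    sites: list[Site]
    samples: list[str]
    freq: np.ndarray  # float, shape (n_sites, n_samples)
    depth: np.ndarray  # int, shape (n_sites, n_samples)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float).reshape(
            len(self.sites), len(self.samples)
        )
        self.depth = np.asarray(self.depth, dtype=int).reshape(
            len(self.sites), len(self.samples)
        )
        if self.freq.size and (self.freq.min() < 0.0 or self.freq.max() > 1.0):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def allele_frequency(counts: BaseCounts, alt: str) -> float:
    """count(alt) / total counted bases; undefined at zero depth."""
    total = counts.total
    if total == 0:
        raise ValueError("allele frequency undefined at zero counted depth")
    return counts.count(alt) / total


def select_joint_sites(
    pileups: Mapping[str, Iterable[PileupColumn]],
    candidate_sites: Sequence[Site],
    min_joint_dp: int = 5,
) -> AlleleFrequencyMatrix:
    """Build the frequency matrix over sites jointly covered by all samples.

    ``pileups`` maps sample id to a (sorted) stream of pileup columns; only
    columns at candidate positions are retained, so streams may cover the
    whole genome cheaply.  A sample stream that never reaches a candidate's
    contig contributes zero coverage there, which drops the site (logged).
    Third-allele mass (bases that are neither ref nor the designated alt)
    is tolerated and logged in aggregate.
    """
    needed = {(chrom, pos) for (chrom, pos, _r, _a) in candidate_sites}
    col_by_sample: dict[str, dict[tuple[str, int], PileupColumn]] = {}
    for sample, stream in pileups.items():
        picked: dict[tuple[str, int], PileupColumn] = {}
        for col in stream:
            key = (col.chrom, col.pos)
            if key in needed:
                picked[key] = col
        col_by_sample[sample] = picked

    samples = list(pileups)
    kept: list[Site] = []
    freq_rows: list[list[float]] = []
    depth_rows: list[list[int]] = []
    dropped = 0
    third_allele_mass = 0
    total_mass = 0
    for site in candidate_sites:
        chrom, pos, ref, alt = site
        cols = [col_by_sample[s].get((chrom, pos)) for s in samples]
        totals = [c.counts.total if c is not None else 0 for c in cols]
        if min(totals, default=0) < min_joint_dp:
            dropped += 1
            if any(c is None for c in cols):
                logger.debug("site %s:%d missing from >=1 sample stream", chrom, pos)
            continue
        freqs = []
        depths = []
        for c in cols:
            counts = c.counts
            freqs.append(allele_frequency(counts, alt))
            depths.append(counts.total)
            third_allele_mass += counts.total - counts.count(alt) - (
                counts.count(ref) if ref in "ACGT" else 0
            )
            total_mass += counts.total
        kept.append(site)
        freq_rows.append(freqs)
        depth_rows.append(depths)

    if dropped:
        logger.info(
            "joint-coverage gate (>=%dx in all %d samples): kept %d / %d sites",
            min_joint_dp, len(samples), len(kept), len(candidate_sites),
        )
    if total_mass:
        logger.info(
            "third-allele mass at retained sites: %.4f",
            third_allele_mass / total_mass,
        )
    return AlleleFrequencyMatrix(
        sites=kept,
        samples=samples,
        freq=np.array(freq_rows, dtype=float).reshape(len(kept), len(samples)),
        depth=np.array(depth_rows, dtype=int).reshape(len(kept), len(samples)),
    )


def classify_genotype(
    freq: float, het_low: float = 0.2, het_high: float = 0.8
) -> GenotypeClass:
    """Diploid genotype class from a variant-allele frequency.

    Below ``het_low`` is homozygous reference, above ``het_high`` homozygous
    alternate, the closed band [het_low, het_high] heterozygous.
    """
    if not (0.0 <= freq <= 1.0):
        raise ValueError(f"frequency must be in [0, 1], got {freq}")
    if not (0.0 < het_low < het_high < 1.0):
        raise ValueError("need 0 < het_low < het_high < 1")
    if freq < het_low:
        return GenotypeClass.HOM_REF
    if freq > het_high:
        return GenotypeClass.HOM_ALT
    return GenotypeClass.HET


def classify_matrix(
    matrix: AlleleFrequencyMatrix, het_low: float = 0.2, het_high: float = 0.8
) -> np.ndarray:
    """Vectorised genotype classing; returns an object array of GenotypeClass."""
    codes = np.where(
        matrix.freq < het_low, 0, np.where(matrix.freq > het_high, 2, 1)
    )
    lut = np.empty(3, dtype=object)
    lut[0], lut[1], lut[2] = GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT
    return lut[codes]


def subsample_sites(
    matrix: AlleleFrequencyMatrix, n: int = 20000, seed: Optional[int] = None
) -> AlleleFrequencyMatrix:
    """Uniform site subsample without replacement, genomic order preserved."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= matrix.n_sites:
        return matrix
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_sites, size=n, replace=False))
    return AlleleFrequencyMatrix(
        sites=[matrix.sites[i] for i in idx],
        samples=list(matrix.samples),
        freq=matrix.freq[idx, :].copy(),
        depth=matrix.depth[idx, :].copy(),
    )


def _site_label(site: Site) -> str:
    chrom, pos, ref, alt = site
    return f"{chrom}:{pos}_{ref}>{alt}"


def export_matrix(matrix: AlleleFrequencyMatrix, path: str | Path) -> None:
    """TSV with one row per sample and one column per site, 3 decimals."""
    df = pd.DataFrame(
        matrix.freq.T,
        index=pd.Index(matrix.samples, name="sample"),
        columns=[_site_label(s) for s in matrix.sites],
    )
    df.to_csv(path, sep="\t", float_format="%.3f")


def heatmap_data(matrix: AlleleFrequencyMatrix) -> np.ndarray:
    """Plottable samples x sites array (rows = samples, columns = sites)."""
    return matrix.freq.T.copy()
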