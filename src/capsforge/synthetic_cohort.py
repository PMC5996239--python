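"""Synthetic diploid resequencing cohorts with known truth.

Generates a random reference contig, a multi-sample diploid genotype truth
set and per-sample mpileup files with the statistical structure the
downstream analysis assumes:

* polymorphic sites arise Bernoulli(snp_rate) per bp (default one per
  kilobase);
* each sample at a polymorphic site is heterozygous with probability
  ``het_fraction``, otherwise homozygous for either allele equiprobably;
* per-sample coverage is Poisson around that sample's mean depth — the
  default means are a 17-value panel spanning 7.0x to 45.8x, mirroring a
  real resequencing cohort's spread;
* at heterozygous sites the variant-read count is Binomial(depth, 0.5);
* every emitted base miscalls to a uniformly chosen other base with
  probability ``error_rate``.

Reads are simulated column-wise: there is no read-length structure and no
mapping artefact model, which is sufficient because every downstream stage
consumes per-position columns only.  A configurable number of SNPs is
planted inside restriction recognition sites (with flanks scrubbed of
confounding sites) so assay-design recovery can be tested against truth.

All randomness flows from ``CohortConfig.seed``; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .caps_design import RestrictionEnzyme, assess_cleavability, find_recognition_sites
from .io_formats import ReferenceSequence

__all__ = [
    "DEFAULT_DEPTH_MEANS",
    "CohortConfig",
    "PlantedMotif",
    "PlantedSnp",
    "TruthSet",
    "generate_reference",
    "generate_genotypes",
    "simulate_pileups",
    "simulate_genotype_columns",
]

logger = logging.getLogger(__name__)

# Per-sample mean coverages of a 17-accession resequencing panel (7.0-45.8x).
DEFAULT_DEPTH_MEANS: tuple[float, ...] = (
    7.36, 8.04, 15.64, 45.81, 18.25, 18.43, 9.21, 9.43, 8.86,
    8.66, 7.00, 8.24, 20.69, 17.16, 21.75, 16.54, 17.96,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_PLANT_MARGIN = 2000  # bp kept clear of contig ends around planted motifs
_CLEAN_RADIUS = 700  # bp scrubbed of confounding sites around planted motifs


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    genome_length: int = 100_000
    n_samples: int = 17
    snp_rate: float = 0.001
    het_fraction: float = 0.4
    depth_means: Optional[tuple[float, ...]] = None
    error_rate: float = 0.005
    planted_caps_sites: int = 10
    indel_rate: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise CohortConfigError("genome_length must be positive")
        for name in ("snp_rate", "het_fraction", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise CohortConfigError(f"{name} must lie in [0, 1), got {v}")
        if self.n_samples < 1:
            raise CohortConfigError("n_samples must be >= 1")
        if self.depth_means is not None:
            object.__setattr__(self, "depth_means", tuple(self.depth_means))
            if len(self.depth_means) != self.n_samples:
                raise CohortConfigError(
                    "depth_means length must equal n_samples"
                )

    def resolved_depth_means(self) -> tuple[float, ...]:
        if self.depth_means is not None:
            return self.depth_means
        if self.n_samples == 17:
            return DEFAULT_DEPTH_MEANS
        rng = np.random.default_rng([self.seed, 99])
        return tuple(rng.uniform(7.0, 46.0, self.n_samples))

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_samples)]


class PlantedMotif(NamedTuple):
    enzyme: RestrictionEnzyme
    start: int  # 1-based start of the written recognition sequence


class PlantedSnp(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str
    enzyme: str


@dataclass
class TruthSet:
    """Truth genotypes (alt-allele copy counts 0/1/2) and planted CAPS SNPs."""

    sites: list[tuple[str, int, str, str]]
    genotypes: np.ndarray  # int8, shape (n_sites, n_samples)
    sample_ids: list[str]
    planted: list[PlantedSnp] = field(default_factory=list)
    indel_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    indel_genotypes: Optional[np.ndarray] = None


def generate_reference(
    config: CohortConfig,
) -> tuple[ReferenceSequence, list[PlantedMotif]]:
    """Uniform-random reference with recognition motifs written at spaced
    positions; flanks around each motif are scrubbed of accidental sites of
    the packaged panel so planted assays have clean band patterns."""
    from .resources import load_default_enzymes

    rng = np.random.default_rng([config.seed, 0])
    n = config.genome_length
    seq = list(_BASES[rng.integers(0, 4, n)])

    planted: list[PlantedMotif] = []
    if config.planted_caps_sites > 0:
        enzymes = load_default_enzymes()
        motif_len = max(len(e) for e in enzymes)
        usable = n - 2 * _PLANT_MARGIN - motif_len
        if usable < 0 or (
            config.planted_caps_sites > 1
            and usable / (config.planted_caps_sites - 1) < 2 * _CLEAN_RADIUS
        ):
            raise CohortConfigError(
                f"genome of {n} bp too short for {config.planted_caps_sites} "
                "planted CAPS sites with clean flanks"
            )
        starts0 = np.linspace(
            _PLANT_MARGIN, n - _PLANT_MARGIN - motif_len, config.planted_caps_sites
        ).astype(int)
        for i, p0 in enumerate(starts0):
            enz = enzymes[i % len(enzymes)]
            seq[p0 : p0 + len(enz)] = list(enz.recognition)
            planted.append(PlantedMotif(enzyme=enz, start=int(p0) + 1))
        _scrub_flanks(seq, planted, enzymes, rng)

    return ReferenceSequence(config.chrom, "".join(seq)), planted


def _scrub_flanks(
    seq: list[str],
    planted: Sequence[PlantedMotif],
    enzymes: Sequence[RestrictionEnzyme],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Break every accidental recognition site near a planted motif.

    Substituted bases never touch a planted motif; iterate to a fixpoint
    because a substitution can itself create a new site.
    """
    protected = {
        (m.start - 1 + k) for m in planted for k in range(len(m.enzyme))
    }
    planted_keys = {(m.enzyme.name, m.start) for m in planted}
    n = len(seq)
    for _ in range(max_rounds):
        dirty = False
        for m in planted:
            w0 = max(0, m.start - 1 - _CLEAN_RADIUS)
            w1 = min(n, m.start - 1 + len(m.enzyme) + _CLEAN_RADIUS)
            window = "".join(seq[w0:w1])
            for enz in enzymes:
                for local_start in find_recognition_sites(window, enz):
                    gstart = w0 + local_start  # 1-based global
                    if (enz.name, gstart) in planted_keys:
                        continue
                    targets = [
                        q for q in range(gstart - 1, gstart - 1 + len(enz))
                        if q not in protected
                    ]
                    if not targets:
                        continue
                    q = targets[len(targets) // 2]
                    current = seq[q]
                    options = [b for b in "ACGT" if b != current]
                    seq[q] = options[int(rng.integers(0, 3))]
                    dirty = True
        if not dirty:
            return
    logger.warning("flank scrubbing did not converge in %d rounds", max_rounds)


def generate_genotypes(
    config: CohortConfig,
    reference: ReferenceSequence,
    planted_motifs: Sequence[PlantedMotif] = (),
) -> TruthSet:
    """Draw polymorphic sites and per-sample diploid genotypes.

    Planted CAPS SNPs sit mid-motif with an alt allele chosen (and
    verified) to destroy the written recognition site; every planted site
    is guaranteed at least one alt-carrying sample so it is observable.
    """
    rng = np.random.default_rng([config.seed, 1])
    s = reference.seq
    n = len(s)

    planted_snps: list[PlantedSnp] = []
    planted_pos: set[int] = set()
    for motif in planted_motifs:
        mid0 = motif.start - 1 + len(motif.enzyme) // 2
        ref_base = s[mid0]
        alt_base = None
        for cand in sorted(b for b in "ACGT" if b != ref_base):
            res = assess_cleavability(
                (reference.id, mid0 + 1, ref_base, cand), motif.enzyme, reference
            )
            if res.informative and res.cleavable_allele == "ref":
                alt_base = cand
                break
        if alt_base is None:  # pragma: no cover - scrubbed flanks prevent this
            logger.warning("no site-destroying alt at motif %s:%d", motif.enzyme.name, motif.start)
            continue
        planted_snps.append(
            PlantedSnp(reference.id, mid0 + 1, ref_base, alt_base, motif.enzyme.name)
        )
        planted_pos.add(mid0 + 1)

    random_pos0 = np.flatnonzero(rng.random(n) < config.snp_rate)
    sites: list[tuple[str, int, str, str]] = []
    for p0 in random_pos0:
        pos = int(p0) + 1
        if pos in planted_pos or s[p0] == "N":
            continue
        ref_base = s[p0]
        others = [b for b in "ACGT" if b != ref_base]
        sites.append((reference.id, pos, ref_base, others[int(rng.integers(0, 3))]))
    sites.extend((p.chrom, p.pos, p.ref, p.alt) for p in planted_snps)
    sites.sort(key=lambda t: t[1])

    n_sites = len(sites)
    u_het = rng.random((n_sites, config.n_samples))
    u_hom = rng.random((n_sites, config.n_samples))
    genotypes = np.where(
        u_het < config.het_fraction, 1, np.where(u_hom < 0.5, 0, 2)
    ).astype(np.int8)

    pos_to_row = {site[1]: i for i, site in enumerate(sites)}
    for p in planted_snps:
        row = pos_to_row[p.pos]
        if not genotypes[row].any():
            genotypes[row, 0] = 1  # keep every planted SNP observable

    indel_sites: list[tuple[str, int, str, str]] = []
    indel_genotypes = None
    if config.indel_rate > 0:
        occupied = set(pos_to_row) | {pos + 1 for pos in pos_to_row}
        cand0 = np.flatnonzero(rng.random(n - 1) < config.indel_rate)
        rows = []
        for p0 in cand0:
            pos = int(p0) + 1
            if pos in occupied or pos + 1 in occupied:
                continue
            indel_sites.append(
                (reference.id, pos, s[p0 : p0 + 2], s[p0])
            )  # single-base deletion
            rows.append(rng.random(config.n_samples))
        if rows:
            u = np.array(rows)
            u2 = rng.random(u.shape)
            indel_genotypes = np.where(
                u < config.het_fraction, 1, np.where(u2 < 0.5, 0, 2)
            ).astype(np.int8)

    return TruthSet(
        sites=sites,
        genotypes=genotypes,
        sample_ids=config.sample_ids,
        planted=planted_snps,
        indel_sites=indel_sites,
        indel_genotypes=indel_genotypes,
    )


def _column_string(
    rng: np.random.Generator,
    ref: str,
    alt: Optional[str],
    depth: int,
    n_alt: int,
    error_rate: float,
) -> str:
    """One pileup base column: n_alt variant reads, the rest reference,
    each miscalling to a uniform other base with probability error_rate."""
    if depth == 0:
        return ""  # empty column: no base calls to report
    bits = rng.integers(0, 2, depth)
    bases = [alt] * n_alt + [ref] * (depth - n_alt)
    if error_rate > 0.0:
        err = np.flatnonzero(rng.random(depth) < error_rate)
        for i in err:
            others = [b for b in "ACGT" if b != bases[i]]
            bases[i] = others[int(rng.integers(0, 3))]
    chars = []
    for i in range(depth):
        b = bases[i]
        if b == ref:
            chars.append("." if bits[i] else ",")
        else:
            chars.append(b if bits[i] else b.lower())
    return "".join(chars)


def simulate_pileups(
    truth: TruthSet,
    reference: ReferenceSequence,
    config: CohortConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one mpileup file per sample; returns sample id -> path.

    Clean homozygous-reference columns (the overwhelming majority) take a
    vectorised fast path; variant columns, error-carrying columns and
    indel-adjacent columns are rebuilt individually.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = reference.seq
    n = len(s)
    depth_means = config.resolved_depth_means()

    site_by_pos0 = {site[1] - 1: (row, site) for row, site in enumerate(truth.sites)}
    indel_by_pos0 = {
        site[1] - 1: (row, site)
        for row, site in enumerate(truth.indel_sites)
    }

    paths: dict[str, Path] = {}
    for j, sample in enumerate(truth.sample_ids):
        rng = np.random.default_rng([config.seed, 2, j])
        depths = rng.poisson(depth_means[j], n)
        err_counts = (
            rng.binomial(depths, config.error_rate)
            if config.error_rate > 0
            else np.zeros(n, dtype=int)
        )

        # fast-path material: one './,' stream shared by all clean columns
        offsets = np.concatenate([[0], np.cumsum(depths)])
        bits = rng.integers(0, 2, int(offsets[-1]), dtype=np.uint8)
        stream = np.where(bits, ord("."), ord(",")).astype(np.uint8).tobytes().decode()

        # pending deletion placeholders spilling into the next column
        spill: dict[int, tuple[int, str]] = {}  # pos0 -> (n_del_reads, token_seq)

        path = outdir / f"{sample}.pileup"
        with open(path, "w") as fh:
            for p0 in range(n):
                depth = int(depths[p0])
                ref_base = s[p0]
                variant = site_by_pos0.get(p0)
                indel = indel_by_pos0.get(p0)
                spilled = spill.pop(p0, None)
                if (
                    variant is None
                    and indel is None
                    and spilled is None
                    and err_counts[p0] == 0
                ):
                    bases = stream[offsets[p0] : offsets[p0 + 1]]
                    fh.write(f"{config.chrom}\t{p0 + 1}\t{ref_base}\t{depth}\t{bases}\t{'I' * depth}\n")
                    continue

                alt = None
                n_alt = 0
                if variant is not None:
                    row, (_c, _p, _r, alt) = variant
                    gt = int(truth.genotypes[row, j])
                    if gt == 1:
                        n_alt = int(rng.binomial(depth, 0.5))
                    elif gt == 2:
                        n_alt = depth
                col = _column_string(
                    rng, ref_base, alt, depth, n_alt, config.error_rate
                )
                if spilled is not None and depth > 0:
                    n_del, _seq = spilled
                    n_del = min(n_del, depth)
                    col = "*" * n_del + col[n_del:] if n_del else col
                if indel is not None and depth > 0:
                    row, (_c, _p, iref, _ialt) = indel
                    gt = (
                        int(truth.indel_genotypes[row, j])
                        if truth.indel_genotypes is not None
                        else 0
                    )
                    n_del = (
                        int(rng.binomial(depth, 0.5)) if gt == 1 else depth if gt == 2 else 0
                    )
                    if n_del:
                        deleted = iref[1:]
                        # one token per deletion-carrying read, as mpileup does
                        col += f"-{len(deleted)}{deleted}" * n_del
                        spill[p0 + 1] = (n_del, deleted)
                fh.write(
                    f"{config.chrom}\t{p0 + 1}\t{ref_base}\t{depth}\t{col}\t{'I' * depth}\n"
                )
        paths[sample] = path
    return paths


def simulate_genotype_columns(
    n_sites: int,
    genotype: str,
    depth_mean: float,
    error_rate: float,
    seed: int,
    chrom: str = "sim",
) -> tuple[list[str], list[tuple[str, int, str, str]]]:
    """Pileup lines for ``n_sites`` positions that all share one true
    diploid genotype ('hom_ref' | 'het' | 'hom_alt').

    Ref and alt alleles are drawn per site; depth is Poisson(depth_mean).
    Returns (lines, sites) with sites as (chrom, pos, ref, alt).  Useful
    for calibration checks of the allele-frequency machinery against known
    genotype classes.
    """
    if genotype not in {"hom_ref", "het", "hom_alt"}:
        raise ValueError(f"unknown genotype class {genotype!r}")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    sites: list[tuple[str, int, str, str]] = []
    for i in range(n_sites):
        pos = i + 1
        ref, alt = [str(b) for b in rng.choice(_BASES, size=2, replace=False)]
        depth = int(rng.poisson(depth_mean))
        if genotype == "het":
            n_alt = int(rng.binomial(depth, 0.5))
        elif genotype == "hom_alt":
            n_alt = depth
        else:
            n_alt = 0
        col = _column_string(rng, ref, alt, depth, n_alt, error_rate)
        lines.append(f"{chrom}\t{pos}\t{ref}\t{depth}\t{col}\t{'I' * depth}")
        sites.append((chrom, pos, ref, alt))
    return lines, sites
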