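"""CAPS / PCR-RFLP genotyping-assay design.

A CAPS (cleaved amplified polymorphic sequence) marker exploits a SNP that
sits inside the recognition site of a restriction enzyme so that exactly
one allele is cleavable: amplify a product flanking the SNP, digest, and
read the genotype from the band pattern.  This module finds such SNPs for
a panel of enzymes, picks flanking primers with simple deterministic
heuristics, and predicts the allele-specific digest fragments.

Enzyme definitions (IUPAC recognition sequence plus top-strand cut offset)
ship as editable packaged data; the six defaults are the common palindromic
6-cutters EcoRV (GAT^ATC), ClaI (AT^CGAT), HindIII (A^AGCTT), BglII
(A^GATCT), BamHI (G^GATCC) and PstI (CTGCA^G).

Cleavability is judged over *every* recognition-length window overlapping
the SNP, on both strands, because a substitution can create a site offset
from itself.  Complete digestion is assumed; star activity and methylation
sensitivity are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .io_formats import ReferenceSequence, VariantRecord

__all__ = [
    "RestrictionEnzyme",
    "CleavabilityResult",
    "PrimerConstraints",
    "Amplicon",
    "CapsAssay",
    "iupac_match",
    "reverse_complement",
    "find_recognition_sites",
    "assess_cleavability",
    "pick_primers",
    "digest_fragments",
    "amplicon_length",
    "design_assays",
]

logger = logging.getLogger(__name__)

IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """name, IUPAC recognition sequence and top-strand cut offset.

    ``cut_offset`` is the number of recognition-site bases left of the cut
    on the top strand (0 <= offset <= len(recognition)); EcoRV GAT^ATC has
    offset 3.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec or any(ch not in IUPAC_CLASSES for ch in rec):
            raise ValueError(f"recognition must be an IUPAC string, got {self.recognition!r}")
        if not (0 <= self.cut_offset <= len(rec)):
            raise ValueError("cut_offset must lie within the recognition site")
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    def __len__(self) -> int:
        return len(self.recognition)


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every window base belongs to the matching IUPAC class.

    An unconstrained 'N' in the pattern matches anything; an 'N' in the
    window never satisfies a constrained pattern class.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern and window lengths differ: {len(pattern)} vs {len(window)}"
        )
    for p, w in zip(pattern.upper(), window.upper()):
        if p == "N":
            continue
        if w not in IUPAC_CLASSES[p]:
            return False
    return True


def _seq_of(seq: Union[str, ReferenceSequence]) -> str:
    return seq.seq if isinstance(seq, ReferenceSequence) else seq


def _scan(s: str, pattern: str) -> list[int]:
    """1-based start positions of all (overlapping) matches of pattern in s."""
    k = len(pattern)
    if k == 0 or k > len(s):
        return []
    if all(ch in "ACGT" for ch in pattern):  # exact motif: use str.find
        out = []
        i = s.find(pattern)
        while i != -1:
            out.append(i + 1)
            i = s.find(pattern, i + 1)
        return out
    return [i + 1 for i in range(len(s) - k + 1) if iupac_match(pattern, s[i : i + k])]


def find_recognition_sites(
    seq: Union[str, ReferenceSequence],
    enzyme: RestrictionEnzyme,
    strand: str = "+",
) -> Union[list[int], list[tuple[int, str]]]:
    """Recognition-site start positions (1-based, top-strand coordinates).

    strand "+" scans the given strand, "-" scans for the reverse complement
    of the recognition sequence (i.e. bottom-strand sites, reported on
    top-strand coordinates), "both" returns (start, strand) pairs.  For
    palindromic enzymes "+" and "-" coincide.
    """
    s = _seq_of(seq).upper()
    if strand == "+":
        return _scan(s, enzyme.recognition)
    if strand == "-":
        return _scan(s, reverse_complement(enzyme.recognition))
    if strand == "both":
        top = [(p, "+") for p in _scan(s, enzyme.recognition)]
        bottom = [(p, "-") for p in _scan(s, reverse_complement(enzyme.recognition))]
        return sorted(set(top + bottom))
    raise ValueError(f"strand must be '+', '-' or 'both', got {strand!r}")


@dataclass(frozen=True)
class CleavabilityResult:
    snp: tuple[str, int, str, str]
    enzyme: str
    informative: bool
    cleavable_allele: Optional[str] = None  # "ref" | "alt"
    site_start: Optional[int] = None  # 1-based start of the matching window


def _as_snp_tuple(snp) -> tuple[str, int, str, str]:
    if isinstance(snp, VariantRecord):
        return snp.site
    chrom, pos, ref, alt = snp
    return (chrom, int(pos), ref.upper(), alt.upper())


def assess_cleavability(
    snp, enzyme: RestrictionEnzyme, ref_seq: ReferenceSequence
) -> CleavabilityResult:
    """Is exactly one allele of this SNP cleavable by the enzyme?

    Examines every recognition-length window overlapping the SNP position
    under both alleles (both strands).  Informative means one allele yields
    at least one matching window while the other yields none.
    """
    chrom, pos, ref, alt = _as_snp_tuple(snp)
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("cleavability assessment requires a single-base substitution")
    s = _seq_of(ref_seq)
    if not (1 <= pos <= len(s)):
        raise ValueError(f"SNP position {pos} outside sequence of length {len(s)}")
    if s[pos - 1] != ref:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: sequence has "
            f"{s[pos - 1]!r}, SNP says {ref!r}"
        )
    k = len(enzyme)
    lo = max(0, pos - k)  # 0-based slice covering all windows that touch pos
    hi = min(len(s), pos - 1 + k)
    local = s[lo:hi]
    idx = pos - 1 - lo
    patterns = {enzyme.recognition, reverse_complement(enzyme.recognition)}

    def matches(allele: str) -> list[int]:
        variant = local[:idx] + allele + local[idx + 1 :]
        starts = []
        for i in range(len(variant) - k + 1):
            if not (i <= idx <= i + k - 1):
                continue
            window = variant[i : i + k]
            if any(iupac_match(p, window) for p in patterns):
                starts.append(lo + i + 1)
        return starts

    ref_hits = matches(ref)
    alt_hits = matches(alt)
    informative = (len(ref_hits) > 0) != (len(alt_hits) > 0)
    if not informative:
        return CleavabilityResult(snp=(chrom, pos, ref, alt), enzyme=enzyme.name, informative=False)
    cleavable = "ref" if ref_hits else "alt"
    site_start = (ref_hits or alt_hits)[0]
    return CleavabilityResult(
        snp=(chrom, pos, ref, alt),
        enzyme=enzyme.name,
        informative=True,
        cleavable_allele=cleavable,
        site_start=site_start,
    )


@dataclass(frozen=True)
class PrimerConstraints:
    """Primer-picking constraints: length 18-25 nt, product 100-500 bp,
    GC 35-65 %, homopolymer runs <= 4, Wallace Tm (2(A+T)+4(G+C)) 52-68 C,
    pair Tm difference <= 4 C."""

    min_primer_len: int = 18
    max_primer_len: int = 25
    min_product: int = 100
    max_product: int = 500
    min_gc: float = 35.0
    max_gc: float = 65.0
    max_homopolymer: int = 4
    min_tm: float = 52.0
    max_tm: float = 68.0
    max_tm_diff: float = 4.0


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("amplicon start must not exceed end")

    @property
    def length(self) -> int:
        return amplicon_length(self.start, self.end)


@dataclass(frozen=True)
class CapsAssay:
    amplicon: Amplicon
    enzyme: RestrictionEnzyme
    snp: tuple[str, int, str, str]
    cleavable_allele: str
    fragments_cleaved: tuple[int, ...]
    fragments_uncleaved: tuple[int, ...]


def amplicon_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive span: end - start + 1."""
    if start > end:
        raise ValueError(f"start ({start}) must not exceed end ({end})")
    return end - start + 1


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _primer_tm(primer: str, c: PrimerConstraints) -> Optional[float]:
    """Wallace Tm if the primer passes composition checks, else None."""
    if "N" in primer:
        return None
    gc = primer.count("G") + primer.count("C")
    at = len(primer) - gc
    gc_pct = 100.0 * gc / len(primer)
    if not (c.min_gc <= gc_pct <= c.max_gc):
        return None
    if _max_run(primer) > c.max_homopolymer:
        return None
    tm = 2.0 * at + 4.0 * gc
    if not (c.min_tm <= tm <= c.max_tm):
        return None
    return tm


def pick_primers(
    ref_seq: ReferenceSequence,
    snp_pos: int,
    constraints: Optional[PrimerConstraints] = None,
) -> Optional[Amplicon]:
    """Deterministic flanking-primer search around a SNP.

    Scans product lengths outward from the minimum, then amplicon start
    positions and primer lengths in ascending order, returning the first
    pair for which both primers satisfy all composition constraints, the
    Tm difference is within bounds, and the SNP lies strictly inside the
    product without touching either primer.  Returns ``None`` when no pair
    exists within the maximum product size (design failure; caller skips).

    The forward primer is the reference prefix of the span; the reverse
    primer is the reverse complement of the reference suffix.
    """
    c = constraints or PrimerConstraints()
    s = ref_seq.seq
    n = len(s)
    p0 = snp_pos - 1
    fwd_cache: dict[tuple[int, int], Optional[float]] = {}
    rev_cache: dict[tuple[int, int], Optional[float]] = {}

    def fwd_tm(start0: int, ln: int) -> Optional[float]:
        key = (start0, ln)
        if key not in fwd_cache:
            fwd_cache[key] = _primer_tm(s[start0 : start0 + ln], c)
        return fwd_cache[key]

    def rev_tm(end0: int, ln: int) -> Optional[float]:
        key = (end0, ln)
        if key not in rev_cache:
            rev_cache[key] = _primer_tm(reverse_complement(s[end0 - ln + 1 : end0 + 1]), c)
        return rev_cache[key]

    for length in range(c.min_product, c.max_product + 1):
        start_lo = max(0, p0 - length + 2)  # keeps SNP strictly left of the end
        start_hi = min(p0 - 1, n - length)  # keeps SNP strictly right of the start
        for start0 in range(start_lo, start_hi + 1):
            end0 = start0 + length - 1
            for flen in range(c.min_primer_len, c.max_primer_len + 1):
                if start0 + flen - 1 >= p0:
                    break  # SNP would fall inside the forward primer
                ftm = fwd_tm(start0, flen)
                if ftm is None:
                    continue
                for rlen in range(c.min_primer_len, c.max_primer_len + 1):
                    if end0 - rlen + 1 <= p0:
                        break  # SNP would fall inside the reverse primer
                    rtm = rev_tm(end0, rlen)
                    if rtm is None:
                        continue
                    if abs(ftm - rtm) <= c.max_tm_diff:
                        return Amplicon(
                            chrom=ref_seq.id,
                            start=start0 + 1,
                            end=end0 + 1,
                            fwd_primer=s[start0 : start0 + flen],
                            rev_primer=reverse_complement(s[end0 - rlen + 1 : end0 + 1]),
                        )
    return None


def digest_fragments(amplicon_seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths after complete digestion, sorted ascending.

    Cuts fall after ``site_start - 1 + cut_offset`` bases for every
    top-strand recognition match; fragments always sum to the sequence
    length, and an uncut sequence yields a single full-length fragment.
    """
    if not amplicon_seq:
        raise ValueError("amplicon sequence must be non-empty")
    s = amplicon_seq.upper()
    cuts = sorted(
        {
            start - 1 + enzyme.cut_offset
            for start in _scan(s, enzyme.recognition)
            if 0 < start - 1 + enzyme.cut_offset < len(s)
        }
    )
    bounds = [0] + cuts + [len(s)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def _normalize_contigs(
    genome: Union[ReferenceSequence, Sequence[ReferenceSequence], Mapping[str, ReferenceSequence]]
) -> dict[str, ReferenceSequence]:
    if isinstance(genome, ReferenceSequence):
        return {genome.id: genome}
    if isinstance(genome, Mapping):
        return dict(genome)
    return {contig.id: contig for contig in genome}


def design_assays(
    genome,
    snps: Iterable,
    enzymes: Optional[Sequence[RestrictionEnzyme]] = None,
    constraints: Optional[PrimerConstraints] = None,
) -> list[CapsAssay]:
    """Design one CAPS assay per designable SNP; failures are logged skips.

    For each SNP, enzymes are tried in the given order (default: the
    packaged panel in alphabetical order) and the first informative enzyme
    wins.  The assay must then survive primer design and a band-pattern
    check: the uncleavable allele's amplicon must carry no recognition site
    of the chosen enzyme at all (any constitutive site would make the gel
    pattern ambiguous), while the cleavable allele's amplicon must digest
    into at least two fragments.  Output preserves genomic order.
    """
    from .resources import load_default_enzymes

    contigs = _normalize_contigs(genome)
    enzymes = list(enzymes) if enzymes is not None else load_default_enzymes()
    constraints = constraints or PrimerConstraints()

    snp_tuples = []
    for snp in snps:
        if isinstance(snp, VariantRecord):
            if snp.is_indel:
                continue
            snp = snp.site
        chrom, pos, ref, alt = _as_snp_tuple(snp)
        if len(ref) != 1 or len(alt) != 1:
            continue
        snp_tuples.append((chrom, pos, ref, alt))
    snp_tuples.sort(key=lambda s: (s[0], s[1]))

    assays: list[CapsAssay] = []
    for chrom, pos, ref, alt in snp_tuples:
        contig = contigs.get(chrom)
        if contig is None:
            logger.warning("skip %s:%d: contig not in genome", chrom, pos)
            continue
        for enzyme in enzymes:
            result = assess_cleavability((chrom, pos, ref, alt), enzyme, contig)
            if not result.informative:
                continue
            amp = pick_primers(contig, pos, constraints)
            if amp is None:
                logger.info("skip %s:%d: no valid primer pair (%s)", chrom, pos, enzyme.name)
                break  # first informative enzyme wins; no fallback
            ref_amp = contig.seq[amp.start - 1 : amp.end]
            i = pos - amp.start
            alt_amp = ref_amp[:i] + alt + ref_amp[i + 1 :]
            if result.cleavable_allele == "ref":
                cle_seq, unc_seq = ref_amp, alt_amp
            else:
                cle_seq, unc_seq = alt_amp, ref_amp
            frag_c = digest_fragments(cle_seq, enzyme)
            frag_u = digest_fragments(unc_seq, enzyme)
            if len(frag_u) != 1 or len(frag_c) < 2:
                logger.info(
                    "skip %s:%d: constitutive %s site in amplicon "
                    "(cleaved=%d, uncleaved=%d fragments)",
                    chrom, pos, enzyme.name, len(frag_c), len(frag_u),
                )
                break
            assays.append(
                CapsAssay(
                    amplicon=amp,
                    enzyme=enzyme,
                    snp=(chrom, pos, ref, alt),
                    cleavable_allele=result.cleavable_allele,
                    fragments_cleaved=tuple(frag_c),
                    fragments_uncleaved=tuple(frag_u),
                )
            )
            break
    return assays
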