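"""Plain-text genomics I/O: FASTA, samtools-mpileup columns, a minimal VCF
subset, and the genotyping-assay sheet.

Coordinate convention
---------------------
All positions in this package are 1-based and inclusive, matching how
restriction maps and PCR target spans are conventionally printed (a span
``start–end`` has length ``end - start + 1``).  Any half-open arithmetic
needed to slice Python strings stays inside the functions that slice.

The pileup base-column census (:func:`count_bases`) is the analytical core
of the SNP-frequency stage: every downstream allele frequency is a ratio of
the counts produced here, so the dialect rules (read-start ``^X`` pairs,
read-end ``$``, length-prefixed indel tokens, ``*`` deletion placeholders)
are handled explicitly rather than approximated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "FastaFormatError",
    "PileupFormatError",
    "VcfFormatError",
    "ReferenceSequence",
    "BaseCounts",
    "PileupColumn",
    "VariantRecord",
    "read_fasta",
    "write_fasta",
    "count_bases",
    "parse_pileup_line",
    "iter_pileup",
    "read_vcf_min",
    "write_vcf_min",
    "write_assay_table",
]


class FormatError(ValueError):
    """A file did not conform to the expected plain-text format."""


class FastaFormatError(FormatError):
    pass


class PileupFormatError(FormatError):
    pass


class VcfFormatError(FormatError):
    pass


# IUPAC ambiguity codes collapse to N on input: the downstream stages can
# only reason about concrete A/C/G/T calls.
_AMBIGUITY = str.maketrans({c: "N" for c in "RYSWKMBDHVryswkmbdhv"})
_VALID_REF_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceSequence:
    """One reference contig: identifier plus an upper-case A/C/G/T/N string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        normalized = self.seq.upper().translate(_AMBIGUITY)
        if not normalized:
            raise FastaFormatError(f"sequence {self.id!r} is empty")
        bad = set(normalized) - _VALID_REF_CHARS
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", normalized)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BaseCounts:
    """Per-column base census.

    Reference-matching calls ('.' and ',') are resolved to the reference
    base; ``total`` counts concrete base calls only.  Indel tokens are
    tallied as *events* (and kept verbatim in ``indel_tokens``), never as
    base calls; ``*`` placeholders are tallied as ``deletions``.
    """

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    deletions: int = 0
    insertion_events: int = 0
    deletion_events: int = 0
    indel_tokens: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def count(self, base: str) -> int:
        """Count for one concrete base (case-insensitive)."""
        try:
            return int(getattr(self, base.lower()))
        except AttributeError:
            raise ValueError(f"not a concrete base: {base!r}") from None


@dataclass(frozen=True)
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    base_string: str
    counts: BaseCounts


def count_bases(base_string: str, ref_base: str) -> BaseCounts:
    """Single-pass census of one pileup base column.

    Dialect handled: '.' ',' (reference match, forward/reverse strand),
    ACGTN letters in either case (mismatch calls), '*' (deletion
    placeholder), '^X' (read start; the mapping-quality character X is
    consumed blindly, whatever it is), '$' (read end), '+n<seq>'/'-n<seq>'
    (indel following this position), '<' '>' (reference skips, ignored).

    A reference base of 'N' leaves '.'/',' uncredited: they cannot be
    resolved to a concrete base, so such columns are unusable for
    frequency work.
    """
    ref = ref_base.upper()
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    deletions = 0
    ins_events = 0
    del_events = 0
    tokens: dict[str, int] = {}

    i = 0
    n = len(base_string)
    while i < n:
        ch = base_string[i]
        if ch == "^":
            i += 2  # '^' plus mapping-quality char, consumed blindly
            continue
        if ch == "$":
            i += 1
            continue
        if ch in ".,":
            if ref in counts:
                counts[ref] += 1
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < n and base_string[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(
                    f"malformed indel token at offset {i} in {base_string!r}"
                )
            length = int(base_string[i + 1 : j])
            seq = base_string[j : j + length]
            if len(seq) < length:
                raise PileupFormatError(
                    f"indel token at offset {i} declares {length} bases but "
                    f"only {len(seq)} follow"
                )
            token = ch + seq.upper()
            tokens[token] = tokens.get(token, 0) + 1
            if ch == "+":
                ins_events += 1
            else:
                del_events += 1
            i = j + length
            continue
        if ch == "*":
            deletions += 1
            i += 1
            continue
        up = ch.upper()
        if up in counts:
            counts[up] += 1
            i += 1
            continue
        if up == "N" or ch in "<>":
            i += 1  # ambiguous call / reference skip: not countable
            continue
        raise PileupFormatError(f"unexpected pileup character {ch!r} in {base_string!r}")

    return BaseCounts(
        a=counts["A"],
        c=counts["C"],
        g=counts["G"],
        t=counts["T"],
        deletions=deletions,
        insertion_events=ins_events,
        deletion_events=del_events,
        indel_tokens=tokens,
    )


def parse_pileup_line(line: str) -> PileupColumn:
    """Parse one 6-column single-sample mpileup line."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupFormatError(
            f"expected 6 tab-separated pileup fields, got {len(fields)}"
        )
    chrom, pos_s, ref, depth_s, bases = fields[0], fields[1], fields[2], fields[3], fields[4]
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupFormatError(f"position is not an integer: {pos_s!r}") from None
    if pos < 1:
        raise PileupFormatError(f"position must be >= 1, got {pos}")
    try:
        depth = int(depth_s)
    except ValueError:
        raise PileupFormatError(f"depth is not an integer: {depth_s!r}") from None
    ref_base = ref.upper()
    return PileupColumn(
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        depth=depth,
        base_string=bases,
        counts=count_bases(bases, ref_base),
    )


def iter_pileup(path: str | Path) -> Iterator[PileupColumn]:
    """Lazily parse a pileup file; format errors name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                yield parse_pileup_line(line)
            except PileupFormatError as exc:
                raise PileupFormatError(f"{path}, line {lineno}: {exc}") from None


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    try:
        records = [
            ReferenceSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # e.g. sequence data before the first header
        raise FastaFormatError(f"{path}: {exc}") from None
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ReferenceSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# Minimal VCF subset

@dataclass
class VariantRecord:
    """One candidate variant with the annotations the filter expression uses.

    ``qual``/``dp``/``idv`` are ``None`` when the corresponding VCF field or
    INFO key is absent; absence is semantically distinct from zero and makes
    the matching filter clause fail.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float] = None
    dp: Optional[int] = None
    idv: Optional[int] = None
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfFormatError(f"POS must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VcfFormatError("REF and ALT must be non-empty")
        if len(self.ref) != len(self.alt):
            self.is_indel = True

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n'
    '##INFO=<ID=IDV,Number=1,Type=Integer,Description="Maximum number of raw reads supporting the variant">\n'
    '##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indicates that the variant is an indel">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def read_vcf_min(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfFormatError(
                    f"{path}, line {lineno}: expected 8 VCF columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt, qual_s, _filt, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfFormatError(
                    f"{path}, line {lineno}: POS is not an integer: {pos_s!r}"
                ) from None
            if pos < 1:
                raise VcfFormatError(f"{path}, line {lineno}: POS must be positive")
            qual = None if qual_s == "." else float(qual_s)
            dp: Optional[int] = None
            idv: Optional[int] = None
            indel_flag = False
            if info != ".":
                for item in info.split(";"):
                    if item == "INDEL":
                        indel_flag = True
                    elif item.startswith("DP="):
                        dp = int(item[3:])
                    elif item.startswith("IDV="):
                        idv = int(item[4:])
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    qual=qual, dp=dp, idv=idv, is_indel=indel_flag,
                )
            )
    return records


def write_vcf_min(records: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for r in records:
            info_parts = []
            if r.is_indel:
                info_parts.append("INDEL")
            if r.dp is not None:
                info_parts.append(f"DP={r.dp}")
            if r.idv is not None:
                info_parts.append(f"IDV={r.idv}")
            info = ";".join(info_parts) if info_parts else "."
            qual = "." if r.qual is None else format(r.qual, ".6g")
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t{info}\n")


# --------------------------------------------------------------------------
# Assay sheet

_ASSAY_COLUMNS = [
    "no",
    "forward_primer",
    "reverse_primer",
    "product_size_bp",
    "enzyme",
    "target",
    "snp",
    "cleavable_allele",
    "fragments_cleaved_bp",
    "fragments_uncleaved_bp",
]


def write_assay_table(assays: Sequence, path: str | Path) -> None:
    """Write designed CAPS assays as a TSV sheet.

    One row per assay, in input order.  ``product_size_bp`` is computed from
    the amplicon span (end − start + 1); the target span is printed as
    ``"contig: start-end"``.
    """
    import pandas as pd

    rows = []
    for i, a in enumerate(assays, start=1):
        amp = a.amplicon
        chrom, pos, ref, alt = a.snp
        rows.append(
            {
                "no": i,
                "forward_primer": amp.fwd_primer,
                "reverse_primer": amp.rev_primer,
                "product_size_bp": amp.length,
                "enzyme": a.enzyme.name,
                "target": f"{amp.chrom}: {amp.start}-{amp.end}",
                "snp": f"{chrom}:{pos}{ref}>{alt}",
                "cleavable_allele": a.cleavable_allele,
                "fragments_cleaved_bp": ",".join(str(x) for x in a.fragments_cleaved),
                "fragments_uncleaved_bp": ",".join(str(x) for x in a.fragments_uncleaved),
            }
        )
    pd.DataFrame(rows, columns=_ASSAY_COLUMNS).to_csv(path, sep="\t", index=False)
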