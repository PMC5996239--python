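"""Candidate SNV identification and threshold filtering.

Candidates are scored with an explicit binomial miscall model: the QUAL of
a candidate with ``idv`` variant-supporting reads out of ``dp`` counted
bases is the Phred-scaled probability that at least ``idv`` miscalls arise
by chance under ``Binomial(dp, error_rate)``.  This is deliberately simpler
than a full genotype-likelihood caller — the filter semantics downstream
are the point, and the scoring model is a single swappable function.

Filtering implements the expression
``(REF in {A,C,G,T}) & QUAL>=35 & IDV>=2 & DP>=5 & INDEL=0`` together with
an indel-proximity rule: any SNV within ``snp_gap`` bp (inclusive) of an
indel record on the same contig is removed, because alignment artefacts
cluster near indels.  Indel records themselves never survive filtering.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import binom

from .io_formats import PileupColumn, VariantRecord

__all__ = [
    "FilterParams",
    "phred_binomial_qual",
    "call_candidates",
    "apply_filters",
    "filter_clause_report",
    "snp_gap_mask",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the variant filter expression.

    Defaults: QUAL >= 35, DP >= 5, IDV >= 2, SNVs within 100 bp of an indel
    removed, reference allele restricted to concrete bases.
    """

    min_qual: float = 35.0
    min_dp: int = 5
    min_idv: int = 2
    snp_gap: int = 100
    allowed_ref: frozenset[str] = field(default_factory=lambda: frozenset(_BASES))

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_dp < 0 or self.min_idv < 0 or self.snp_gap < 0:
            raise ValueError("thresholds must be non-negative")
        if not frozenset(self.allowed_ref) <= frozenset(_BASES):
            raise ValueError("allowed_ref must be a subset of {A,C,G,T}")
        object.__setattr__(self, "allowed_ref", frozenset(self.allowed_ref))


def phred_binomial_qual(idv: int, dp: int, error_rate: float) -> float:
    """Phred-scaled P[Binomial(dp, error_rate) >= idv], capped at 255."""
    p = float(binom.sf(idv - 1, dp, error_rate))
    if p <= 0.0:
        return 255.0
    return min(255.0, -10.0 * math.log10(p))


def call_candidates(
    columns: Iterable[PileupColumn], error_rate: float
) -> list[VariantRecord]:
    """Emit a candidate record for every column with non-reference evidence.

    For substitutions: alt is the most frequent non-reference base
    (lexicographically first on ties), dp the counted base total, idv the
    alt count.  Columns whose base census carries indel tokens additionally
    yield an indel-flagged record reconstructed from the most frequent
    token, so downstream proximity filtering can see indels.  Columns with
    reference base N are skipped (no resolvable reference allele).

    Input must be sorted by (chrom, pos); contigs may appear in any order
    but positions within a contig must increase.
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError(f"error_rate must be in (0, 0.5), got {error_rate}")
    out: list[VariantRecord] = []
    last: dict[str, int] = {}
    for col in columns:
        prev = last.get(col.chrom)
        if prev is not None and col.pos <= prev:
            raise ValueError(
                f"pileup not sorted: {col.chrom}:{col.pos} after {col.chrom}:{prev}"
            )
        last[col.chrom] = col.pos
        counts = col.counts
        if col.ref_base in _BASES:
            non_ref = [
                (counts.count(b), b) for b in _BASES if b != col.ref_base
            ]
            # ties on count resolve to the lexicographically first base
            top_count, top_base = min(non_ref, key=lambda cb: (-cb[0], cb[1]))
            if top_count >= 1:
                out.append(
                    VariantRecord(
                        chrom=col.chrom,
                        pos=col.pos,
                        ref=col.ref_base,
                        alt=top_base,
                        qual=phred_binomial_qual(top_count, counts.total, error_rate),
                        dp=counts.total,
                        idv=top_count,
                        is_indel=False,
                    )
                )
        if counts.indel_tokens:
            token, token_count = max(
                counts.indel_tokens.items(), key=lambda kv: (kv[1], kv[0])
            )
            seq = token[1:]
            if token[0] == "+":
                ref, alt = col.ref_base, col.ref_base + seq
            else:
                ref, alt = col.ref_base + seq, col.ref_base
            out.append(
                VariantRecord(
                    chrom=col.chrom,
                    pos=col.pos,
                    ref=ref,
                    alt=alt,
                    qual=phred_binomial_qual(token_count, max(counts.total, token_count), error_rate),
                    dp=counts.total,
                    idv=token_count,
                    is_indel=True,
                )
            )
    return out


def _indel_positions(records: Iterable[VariantRecord]) -> dict[str, list[int]]:
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for r in records:
        if r.is_indel:
            by_chrom[r.chrom].append(r.pos)
    for positions in by_chrom.values():
        positions.sort()
    return by_chrom


def _near_indel(r: VariantRecord, indels: dict[str, list[int]], gap: int) -> bool:
    positions = indels.get(r.chrom)
    if not positions:
        return False
    i = bisect_left(positions, r.pos)
    for j in (i - 1, i):
        if 0 <= j < len(positions) and abs(positions[j] - r.pos) <= gap:
            return True
    return False


def apply_filters(
    records: Sequence[VariantRecord], params: Optional[FilterParams] = None
) -> list[VariantRecord]:
    """Apply all filter clauses; retained records keep input order.

    A clause whose annotation is absent (``None``) fails: a record without
    an IDV (or DP, or QUAL) cannot demonstrate that it passes the
    threshold.  The proximity clause uses inclusive distance: an SNV
    exactly ``snp_gap`` bp from an indel is removed.
    """
    params = params or FilterParams()
    indels = _indel_positions(records)
    out = []
    for r in records:
        if r.is_indel:
            continue
        if r.ref not in params.allowed_ref:
            continue
        if r.qual is None or r.qual < params.min_qual:
            continue
        if r.dp is None or r.dp < params.min_dp:
            continue
        if r.idv is None or r.idv < params.min_idv:
            continue
        if _near_indel(r, indels, params.snp_gap):
            continue
        out.append(r)
    return out


def filter_clause_report(
    records: Sequence[VariantRecord], params: Optional[FilterParams] = None
) -> dict[str, int]:
    """Count, independently per clause, how many records fail it.

    Used by the CLI to log in/out counts for every clause of the filter
    expression; a record may be counted under several clauses.
    """
    params = params or FilterParams()
    indels = _indel_positions(records)
    report = {
        "input": len(records),
        "indel": 0,
        "ref_not_allowed": 0,
        "low_qual": 0,
        "low_dp": 0,
        "low_idv": 0,
        "near_indel": 0,
        "retained": 0,
    }
    for r in records:
        if r.is_indel:
            report["indel"] += 1
            continue
        if r.ref not in params.allowed_ref:
            report["ref_not_allowed"] += 1
        if r.qual is None or r.qual < params.min_qual:
            report["low_qual"] += 1
        if r.dp is None or r.dp < params.min_dp:
            report["low_dp"] += 1
        if r.idv is None or r.idv < params.min_idv:
            report["low_idv"] += 1
        if _near_indel(r, indels, params.snp_gap):
            report["near_indel"] += 1
    report["retained"] = len(apply_filters(records, params))
    return report


def snp_gap_mask(
    records: Sequence[VariantRecord], snp_gap: int = 100
) -> set[tuple[str, int]]:
    """(chrom, pos) of every SNV record with an indel within snp_gap bp.

    Only the proximity clause is evaluated; the result is independent of
    record order.
    """
    indels = _indel_positions(records)
    return {
        (r.chrom, r.pos)
        for r in records
        if not r.is_indel and _near_indel(r, indels, snp_gap)
    }
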