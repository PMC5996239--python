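"""Candidate calling and filter semantics against brute-force oracles."""

import math
import random

import pytest

from capsforge.io_formats import VariantRecord
from capsforge.variant_calling import (
    FilterParams,
    apply_filters,
    call_candidates,
    phred_binomial_qual,
    snp_gap_mask,
)
from conftest import make_column


def _exact_binomial_tail(idv, dp, e):
    """P[Binomial(dp, e) >= idv] by direct summation."""
    return sum(
        math.comb(dp, k) * e**k * (1 - e) ** (dp - k) for k in range(idv, dp + 1)
    )


def test_no_record_without_variant_evidence():
    cols = [make_column("c1", 1, "A", "." * 10)]
    assert call_candidates(cols, 0.01) == []


def test_candidate_qual_matches_exact_binomial_tail():
    cols = [make_column("c1", 5, "A", ".....GGGGG")]
    (rec,) = call_candidates(cols, 0.01)
    assert (rec.alt, rec.dp, rec.idv) == ("G", 10, 5)
    expected = min(255.0, -10 * math.log10(_exact_binomial_tail(5, 10, 0.01)))
    assert rec.qual == pytest.approx(expected, rel=1e-9)


def test_alt_tie_break_is_lexicographic():
    cols = [make_column("c1", 9, "A", "....GGGTTT")]
    (rec,) = call_candidates(cols, 0.01)
    assert rec.alt == "G"


def test_qual_non_increasing_in_error_rate():
    quals = [phred_binomial_qual(5, 20, e) for e in (0.001, 0.005, 0.01, 0.05, 0.2)]
    assert quals == sorted(quals, reverse=True)


def test_unsorted_input_rejected():
    cols = [make_column("c1", 5, "A", "....."), make_column("c1", 4, "A", ".....")]
    with pytest.raises(ValueError, match="sorted"):
        call_candidates(cols, 0.01)


def test_indel_tokens_yield_indel_records():
    cols = [make_column("c1", 7, "A", ".+2AG.+2AG..")]
    records = call_candidates(cols, 0.01)
    indels = [r for r in records if r.is_indel]
    assert len(indels) == 1
    assert (indels[0].ref, indels[0].alt, indels[0].idv) == ("A", "AAG", 2)


# ---------------------------------------------------------------- filtering

def _snv(pos, qual=50.0, dp=20, idv=10, ref="A", chrom="c1"):
    alt = "G" if ref != "G" else "T"
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, dp=dp, idv=idv)


def _indel(pos, chrom="c1"):
    return VariantRecord(chrom=chrom, pos=pos, ref="AT", alt="A", qual=60.0, dp=20, idv=10)


def test_qual_boundary_is_inclusive():
    assert apply_filters([_snv(10, qual=34.9)]) == []
    assert apply_filters([_snv(10, qual=35.0)]) != []


def test_snp_gap_distance_is_inclusive():
    records = [_snv(200), _indel(300)]
    assert apply_filters(records, FilterParams(snp_gap=100)) == []
    assert apply_filters(records, FilterParams(snp_gap=99)) == [records[0]]


def test_absent_annotations_fail_their_clause():
    assert apply_filters([_snv(10, idv=None)]) == []
    assert apply_filters([_snv(10, dp=None)]) == []
    assert apply_filters([_snv(10, qual=None)]) == []


def _oracle_filter(records, p):
    """Clause-by-clause check plus an all-pairs indel-proximity scan."""
    indels = [r for r in records if r.is_indel]
    out = []
    for r in records:
        if r.is_indel:
            continue
        ok = (
            r.ref in p.allowed_ref
            and r.qual is not None and r.qual >= p.min_qual
            and r.dp is not None and r.dp >= p.min_dp
            and r.idv is not None and r.idv >= p.min_idv
        )
        near = any(
            i.chrom == r.chrom and abs(i.pos - r.pos) <= p.snp_gap for i in indels
        )
        if ok and not near:
            out.append(r)
    return out


def _random_filter_records(rnd, n):
    records = []
    for _ in range(n):
        chrom = rnd.choice(["c1", "c2"])
        pos = rnd.randint(1, 5000)
        if rnd.random() < 0.1:
            records.append(_indel(pos, chrom=chrom))
        else:
            records.append(
                _snv(
                    pos,
                    chrom=chrom,
                    qual=None if rnd.random() < 0.05 else round(rnd.uniform(0, 80), 1),
                    dp=None if rnd.random() < 0.05 else rnd.randint(0, 40),
                    idv=None if rnd.random() < 0.05 else rnd.randint(0, 20),
                    ref=rnd.choice("ACGT"),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


@pytest.mark.parametrize("snp_gap", [0, 10, 100])
def test_apply_filters_matches_brute_force(snp_gap, rnd):
    records = _random_filter_records(rnd, 1000)
    params = FilterParams(snp_gap=snp_gap)
    assert apply_filters(records, params) == _oracle_filter(records, params)


def test_apply_filters_idempotent(rnd):
    records = _random_filter_records(rnd, 500)
    once = apply_filters(records)
    assert apply_filters(once) == once


def test_raising_thresholds_never_retains_more(rnd):
    records = _random_filter_records(rnd, 500)
    base = len(apply_filters(records))
    for params in (
        FilterParams(min_qual=50),
        FilterParams(min_dp=15),
        FilterParams(min_idv=8),
        FilterParams(snp_gap=500),
    ):
        assert len(apply_filters(records, params)) <= base


def test_proximity_clause_inert_without_indels(rnd):
    records = [r for r in _random_filter_records(rnd, 300) if not r.is_indel]
    params = FilterParams(snp_gap=0)
    clause_only = [
        r for r in records
        if r.ref in params.allowed_ref
        and r.qual is not None and r.qual >= params.min_qual
        and r.dp is not None and r.dp >= params.min_dp
        and r.idv is not None and r.idv >= params.min_idv
    ]
    assert apply_filters(records, params) == clause_only


# ---------------------------------------------------------------- snp_gap_mask

def test_snp_gap_mask_arithmetic():
    records = [_snv(100), _snv(250), _indel(140)]
    assert snp_gap_mask(records, 100) == {("c1", 100)}
    assert snp_gap_mask([_snv(100), _snv(250)], 100) == set()


def test_snp_gap_mask_matches_all_pairs_oracle(rnd):
    records = _random_filter_records(rnd, 400)
    indels = [r for r in records if r.is_indel]
    expected = {
        (r.chrom, r.pos)
        for r in records
        if not r.is_indel
        and any(i.chrom == r.chrom and abs(i.pos - r.pos) <= 50 for i in indels)
    }
    assert snp_gap_mask(records, 50) == expected
    rnd.shuffle(records)
    assert snp_gap_mask(records, 50) == expected  # order-independent
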