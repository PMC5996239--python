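"""Restriction-site scanning, cleavability, primer picking and digests.

Digest predictions are cross-checked against Biopython's Restriction
module, an independent implementation of the same enzymes.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsforge.caps_design import (
    Amplicon,
    IUPAC_CLASSES,
    PrimerConstraints,
    RestrictionEnzyme,
    amplicon_length,
    assess_cleavability,
    design_assays,
    digest_fragments,
    find_recognition_sites,
    iupac_match,
    pick_primers,
    reverse_complement,
)
from capsforge.io_formats import ReferenceSequence
from capsforge.resources import load_default_enzymes

ENZYMES = load_default_enzymes()
ECORV = next(e for e in ENZYMES if e.name == "EcoRV")


def _random_seq(rnd, n):
    return "".join(rnd.choice("ACGT") for _ in range(n))


def _scrub(seq, motif, rnd):
    """Remove every occurrence of motif (and its revcomp) from seq."""
    patterns = {motif, reverse_complement(motif)}
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for p in patterns:
            i = text.find(p)
            if i != -1:
                j = i + len(p) // 2
                s[j] = rnd.choice([b for b in "ACGT" if b != s[j]])
                changed = True
    return "".join(s)


# ---------------------------------------------------------------- IUPAC

def test_iupac_match_examples():
    assert iupac_match("GATATC", "GATATC")
    assert iupac_match("GANTC", "GACTC")
    assert not iupac_match("GATATC", "GACATC")
    assert not iupac_match("R", "N")  # window N never matches a constrained class
    assert iupac_match("N", "N")
    with pytest.raises(ValueError):
        iupac_match("GAT", "GATA")


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    pattern=st.text(alphabet=sorted(IUPAC_CLASSES), min_size=1, max_size=8),
    data=st.data(),
)
def test_iupac_match_equals_set_membership(pattern, data):
    window = data.draw(
        st.text(alphabet="ACGTN", min_size=len(pattern), max_size=len(pattern))
    )
    expected = all(
        (p == "N") or (w in IUPAC_CLASSES[p]) for p, w in zip(pattern, window)
    )
    assert iupac_match(pattern, window) == expected


# ---------------------------------------------------------------- site scan

def test_find_recognition_sites_examples():
    assert find_recognition_sites("GGATATCC", ECORV) == [2]
    assert find_recognition_sites("AAAAAAAA", ECORV) == []


def test_find_recognition_sites_matches_sliding_window(rnd):
    seq = _random_seq(rnd, 10_000)
    for enz in ENZYMES:
        k = len(enz.recognition)
        expected = [
            i + 1
            for i in range(len(seq) - k + 1)
            if iupac_match(enz.recognition, seq[i : i + k])
        ]
        assert find_recognition_sites(seq, enz) == expected


def test_palindromic_enzymes_strand_symmetric(rnd):
    for enz in ENZYMES:
        assert enz.is_palindromic
        seq = _random_seq(rnd, 5000)
        assert find_recognition_sites(seq, enz) == find_recognition_sites(seq, enz, strand="-")


# ---------------------------------------------------------------- cleavability

def test_site_destroying_snp_is_informative(rnd):
    left, right = _random_seq(rnd, 40), _random_seq(rnd, 40)
    seq = _scrub(left, "GATATC", rnd) + "GATATC" + _scrub(right, "GATATC", rnd)
    ref = ReferenceSequence("c1", seq)
    pos = 41 + 2  # the 'T' of GAT^ATC
    res = assess_cleavability(("c1", pos, seq[pos - 1], "C"), ECORV, ref)
    assert res.informative and res.cleavable_allele == "ref"
    assert res.site_start == 41


def test_snp_outside_any_window_not_informative(rnd):
    seq = _scrub(_random_seq(rnd, 100), "GATATC", rnd)
    ref = ReferenceSequence("c1", seq)
    res = assess_cleavability(("c1", 50, seq[49], [b for b in "ACGT" if b != seq[49]][0]), ECORV, ref)
    # no EcoRV site under either allele unless the substitution creates one;
    # informativeness must then mean the alt created a site
    if res.informative:
        assert res.cleavable_allele == "alt"


def test_indel_input_rejected():
    ref = ReferenceSequence("c1", "ACGTACGTACGT")
    with pytest.raises(ValueError):
        assess_cleavability(("c1", 5, "AC", "A"), ECORV, ref)


def _oracle_cleavability(seq, pos, ref_allele, alt_allele, enz):
    """Rebuild both full allele sequences, scan each, keep windows touching
    the SNP, and compare match presence."""
    k = len(enz.recognition)
    hits = {}
    for name, allele in (("ref", ref_allele), ("alt", alt_allele)):
        s2 = seq[: pos - 1] + allele + seq[pos:]
        starts = [
            p
            for strand in ("+", "-")
            for p in find_recognition_sites(s2, enz, strand=strand)
            if p <= pos <= p + k - 1
        ]
        hits[name] = bool(starts)
    return hits["ref"] != hits["alt"]


def test_cleavability_matches_rebuild_and_scan_oracle(rnd):
    for _ in range(300):
        seq = _random_seq(rnd, 60)
        # half the time plant a motif so informative cases are common
        enz = rnd.choice(ENZYMES)
        if rnd.random() < 0.5:
            i = rnd.randint(10, 40)
            seq = seq[:i] + enz.recognition + seq[i + 6 :]
        ref = ReferenceSequence("c1", seq)
        pos = rnd.randint(5, 55)
        ref_allele = seq[pos - 1]
        alt_allele = rnd.choice([b for b in "ACGT" if b != ref_allele])
        res = assess_cleavability(("c1", pos, ref_allele, alt_allele), enz, ref)
        assert res.informative == _oracle_cleavability(seq, pos, ref_allele, alt_allele, enz)


# ---------------------------------------------------------------- primers

def _check_amplicon(amp, ref, snp_pos, c):
    s = ref.seq
    assert amp.start < snp_pos < amp.end
    assert c.min_product <= amp.length <= c.max_product
    assert amp.fwd_primer == s[amp.start - 1 : amp.start - 1 + len(amp.fwd_primer)]
    assert amp.rev_primer == reverse_complement(s[amp.end - len(amp.rev_primer) : amp.end])
    # SNP not inside either primer
    assert snp_pos > amp.start + len(amp.fwd_primer) - 1
    assert snp_pos < amp.end - len(amp.rev_primer) + 1
    tms = []
    for primer in (amp.fwd_primer, amp.rev_primer):
        assert c.min_primer_len <= len(primer) <= c.max_primer_len
        gc = primer.count("G") + primer.count("C")
        assert c.min_gc <= 100 * gc / len(primer) <= c.max_gc
        for b in "ACGT":
            assert b * (c.max_homopolymer + 1) not in primer
        tm = 2 * (len(primer) - gc) + 4 * gc
        assert c.min_tm <= tm <= c.max_tm
        tms.append(tm)
    assert abs(tms[0] - tms[1]) <= c.max_tm_diff


def test_pick_primers_satisfies_all_constraints(rnd):
    c = PrimerConstraints()
    for seed in range(5):
        local = random.Random(seed)
        ref = ReferenceSequence("c1", _random_seq(local, 2000))
        amp = pick_primers(ref, 1000, c)
        assert amp is not None
        _check_amplicon(amp, ref, 1000, c)
        assert pick_primers(ref, 1000, c) == amp  # deterministic


def test_pick_primers_fails_without_flank(rnd):
    ref = ReferenceSequence("c1", _random_seq(rnd, 2000))
    assert pick_primers(ref, len(ref.seq) - 10) is None
    assert pick_primers(ref, 10) is None


# ---------------------------------------------------------------- digest

def test_digest_single_site_cut_arithmetic(rnd):
    body = _scrub(_random_seq(rnd, 395), "GATATC", rnd)
    seq = body[:99] + "GATATC" + body[105:]  # site starts at position 100
    assert len(seq) == 395
    assert digest_fragments(seq, ECORV) == [102, 293]
    assert digest_fragments(_scrub(seq, "GATATC", rnd), ECORV) == [395]


def test_digest_matches_biopython_restriction(rnd):
    from Bio import Restriction
    from Bio.Seq import Seq

    for enz in ENZYMES:
        bio_enz = getattr(Restriction, enz.name)
        for _ in range(50):
            seq = _random_seq(rnd, rnd.randint(60, 600))
            fragments = digest_fragments(seq, enz)
            expected = sorted(len(f) for f in bio_enz.catalyse(Seq(seq)))
            assert fragments == expected
            assert sum(fragments) == len(seq)


def test_amplicon_length_examples():
    assert amplicon_length(86778, 87172) == 395
    assert amplicon_length(16598, 16697) == 100
    assert amplicon_length(5, 5) == 1
    with pytest.raises(ValueError):
        amplicon_length(10, 9)


# ---------------------------------------------------------------- design

def test_design_assays_on_planted_truth():
    from capsforge.synthetic_cohort import CohortConfig, generate_genotypes, generate_reference

    config = CohortConfig(genome_length=30_000, n_samples=2, snp_rate=0.0,
                          planted_caps_sites=5, seed=21, depth_means=(10.0, 10.0))
    reference, motifs = generate_reference(config)
    truth = generate_genotypes(config, reference, motifs)
    assays = design_assays(reference, [ (p.chrom, p.pos, p.ref, p.alt) for p in truth.planted ])
    assert len(assays) == 5
    for assay in assays:
        assert len(assay.fragments_cleaved) >= 2
        assert list(assay.fragments_uncleaved) == [assay.amplicon.length]
        assert sum(assay.fragments_cleaved) == assay.amplicon.length


def test_design_skips_uninformative_snp(rnd):
    seq = _random_seq(rnd, 3000)
    for enz in ENZYMES:
        seq = _scrub(seq, enz.recognition, rnd)
    ref = ReferenceSequence("c1", seq)
    pos = 1500
    alt = None
    # pick an alt that creates no recognition site for any enzyme
    for cand in "ACGT":
        if cand == seq[pos - 1]:
            continue
        if not any(
            assess_cleavability(("c1", pos, seq[pos - 1], cand), e, ref).informative
            for e in ENZYMES
        ):
            alt = cand
            break
    assert alt is not None
    assert design_assays(ref, [("c1", pos, seq[pos - 1], alt)]) == []


def test_design_rejects_constitutive_second_site(rnd):
    left = _scrub(_random_seq(rnd, 1000), "GATATC", rnd)
    right = _scrub(_random_seq(rnd, 1000), "GATATC", rnd)
    # SNP-bearing site, then a constant EcoRV site 8 bp downstream
    core = "GATATC" + right[:8] + "GATATC"
    seq = left + core + right[8:]
    ref = ReferenceSequence("c1", seq)
    pos = len(left) + 3  # the 'T' of GAT^ATC in the first site
    res = assess_cleavability(("c1", pos, seq[pos - 1], "C"), ECORV, ref)
    assert res.informative
    assert design_assays(ref, [("c1", pos, seq[pos - 1], "C")], enzymes=[ECORV]) == []
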