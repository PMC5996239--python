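# Methods

## Pileup census and coordinate conventions

All coordinates are 1-based and inclusive; a span `start–end` has length
`end − start + 1`. The packaged enset PCR-RFLP reference panel obeys this
convention in 21 of its 22 rows; one row (no. 16, JTFG02006088:4069–4489)
prints a product size of 419 bp while its coordinate span computes to
421 bp. The toolkit always reports span-derived lengths and leaves the
panel's printed values verbatim.

The base census resolves `.`/`,` to the reference base, counts explicit
letter calls case-insensitively, consumes `^X` pairs blindly (the
mapping-quality character can be any byte, including `$` or `,`), skips
`$`, consumes `+n<seq>`/`-n<seq>` tokens whole (tallied as indel events
and kept verbatim, never as base calls) and tallies `*` as deletion
placeholders. Base qualities are parsed but ignored: frequencies are read
counts, not quality-weighted sums. Columns with reference base `N` are
parsed but their `.`/`,` calls stay uncredited, making such columns
unusable for frequency work by construction.

## Candidate calling

The caller is deliberately not a genotype-likelihood model. A candidate
substitution is emitted wherever any non-reference base is observed; its
QUAL is the Phred-scaled tail probability that at least `idv` miscalls
arise under Binomial(dp, e), with `e` the assumed per-base miscall rate,
capped at 255. This makes QUAL monotone in the evidence and transparent to
test, but its absolute values are not comparable with QUALs from
likelihood-based callers. Ties for the top non-reference base resolve
lexicographically. Columns carrying indel tokens additionally yield an
indel-flagged record reconstructed from the most frequent token so the
proximity filter has indels to work with.

## Filtering

Retained SNVs satisfy: reference allele in {A,C,G,T}, QUAL ≥ 35, DP ≥ 5,
IDV ≥ 2, not an indel, and no indel record within `snp_gap` bp (inclusive
distance between POS fields) on the same contig. Defaults follow the
filter expression the pipeline re-implements; note that the prose
accompanying that expression elsewhere describes a 10-bp indel exclusion
zone while the expression itself uses 100 bp — the default here is 100,
and `--snp-gap 10` reproduces the narrower reading. Records missing QUAL,
DP or IDV fail the corresponding clause: absence of evidence is treated
conservatively, not as zero-but-passing. Indel records never survive.
`MIN(DP)`/`MIN(IDV)` semantics reduce to plain comparisons because records
here are single-sample.

## Allele-frequency matrix

A site enters the matrix only when *every* sample covers it with at least
`min_joint_dp` (default 5) counted bases. The gate uses counted bases
rather than the pileup's printed depth field because the frequency
denominator is counted bases; gating and denominator therefore agree. The
alt allele is fixed cohort-wide from the merged candidate list, so a
column means the same substitution everywhere; third-allele mass is
tolerated and logged. Genotype classes: `f < 0.2` hom-ref, `f > 0.8`
hom-alt, the closed band in between het. The 0.2/0.8 thresholds are a
package choice (the diploid expectation is only "near 0, near 0.5, near
1") and are configurable. Site subsampling for visualisation (default
20,000) is uniform without replacement, order-preserving and seeded.

## CAPS design

Cleavability is evaluated over every recognition-length window overlapping
the SNP, on both strands, under both alleles; informative means exactly
one allele matches at least one window. The packaged enzymes are six
palindromic 6-cutters (BamHI G^GATCC, BglII A^GATCT, ClaI AT^CGAT, EcoRV
GAT^ATC, HindIII A^AGCTT, PstI CTGCA^G); the table is editable and
REBASE-conventional. Enzymes are tried in alphabetical order and the first
informative one wins (deterministic; no quality ranking is implied).

Primer picking scans product lengths outward from the minimum, then start
positions and primer lengths ascending, returning the first pair
satisfying: length 18–25 nt, product 100–500 bp, GC 35–65 %, homopolymer
runs ≤ 4, Wallace Tm (2(A+T) + 4(G+C)) in 52–68 °C, pair ΔTm ≤ 4 °C, SNP
strictly inside the product and outside both primers. The scan is
deterministic, so identical inputs give identical assays. Because the
minimum product length is tried first, designed amplicons sit at the short
end of the allowed range unless constraints force longer products.
Digestion is modelled as complete, with cuts after
`site_start − 1 + cut_offset` bases; fragment lengths always sum to the
amplicon length. An assay is rejected when the uncleavable allele's
amplicon contains any recognition site of the chosen enzyme (the band
pattern would not be SNP-attributable). Primer uniqueness against the
whole genome (off-target PCR), thermodynamic Tm, primer dimers and dCAPS
mismatch primers are out of scope.

## Synthetic cohorts

The generator emulates column-wise resequencing of a diploid cohort:
uniform-random reference; polymorphic sites Bernoulli(snp_rate, default
0.001/bp); per sample per site heterozygous with probability
`het_fraction` (default 0.4), otherwise hom-ref or hom-alt equiprobably;
depth Poisson per sample around fixed means — the default 17-sample means
span 7.0–45.8x, matching the coverage spread of a real 17-accession
cohort; het variant reads Binomial(depth, 0.5); every emitted base
miscalls to a uniform other base with probability `error_rate` (default
0.005). Strand marks are Bernoulli(0.5); counting downstream is
strand-agnostic. A configurable number of SNPs (default 10) is planted
mid-motif inside written recognition sites, with flanks (±700 bp) scrubbed
of accidental panel-enzyme sites so planted assays are recoverable with
clean band patterns; each planted alt is verified to destroy its site.
Optionally, single-base deletions are planted and emitted as `-1X` tokens
plus spill-over `*` placeholders to exercise the indel-proximity filter.

What the generator does *not* emulate: read-length structure, mapping and
alignment artefacts, BAQ recalibration, GC-coverage bias, quality-score
variation, or linked variation (no demography). Passing recovery tests
therefore demonstrates correctness of the column-level statistics and the
design logic, not robustness to alignment pathology in real data.

All randomness derives from a single integer seed via independent spawned
streams per stage and sample; identical configurations produce
byte-identical outputs.

## Problem sizes used in the checks

The acceptance-style checks run on desk-scale inputs chosen once: 1,000
simulated sites per genotype class at depth 20 for frequency calibration;
1,000 randomized records for filter-semantics comparison; 500 random
amplicons per enzyme for digest conservation; a 100-kb genome with 10
planted SNPs for design recovery; and a full 17-sample, 100-kb cohort for
end-to-end density and genotype recovery (realized SNP count within 3
binomial SDs of the nominal rate; genotype-class accuracy above 95 % at
jointly covered sites — at low-coverage samples the binomial spread at
heterozygous sites is the dominant error source).

## Known limitations

* The candidate caller handles the top non-reference base only; genuinely
  multi-allelic sites report the designated alt's frequency and log the
  remainder.
* QUAL values are model-specific; do not compare them across callers.
* The pileup parser accepts the text dialect as defined by the format;
  producer-specific BAQ adjustments change base strings upstream of it.
* Cross-species primer mapping ("does this amplicon exist in a relative's
  genome?") is out of scope.
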