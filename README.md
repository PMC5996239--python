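# capsforge

Multi-sample SNP detection from sequence-alignment pileups, cohort
allele-frequency matrices, and CAPS / PCR-RFLP genotyping-assay design.

## What problem this solves

Resequencing a panel of plant accessions (the motivating case is enset,
*Ensete ventricosum*, a staple crop in Ethiopia) yields thousands of
single-nucleotide variants, but genotyping *new* material at those variants
should not require sequencing. A CAPS (cleaved amplified polymorphic
sequence) marker turns one SNP into a cheap gel assay: if the SNP sits
inside a restriction enzyme's recognition site so that exactly one allele
is cleavable, a PCR product spanning the SNP digests into allele-specific
band patterns. `capsforge` covers the full path from alignments to markers:

1. **Pileup base census** — parse samtools-mpileup text and count concrete
   base calls per position (read-start/end marks, indel tokens and deletion
   placeholders handled exactly).
2. **Candidate calling & filtering** — emit candidate SNVs with a binomial
   miscall QUAL, then filter with `QUAL >= 35 & DP >= 5 & IDV >= 2 &
   INDEL = 0`, reference allele in {A,C,G,T}, and removal of SNVs within
   `--snp-gap` bp (default 100) of an indel.
3. **Allele-frequency matrix** — at sites covered at least 5x in *every*
   sample, the variant-allele frequency `f = count(alt) / counted bases`
   per sample. In a diploid, `f ~ 0` (hom-ref), `~ 0.5` (het), `~ 1`
   (hom-alt); genotype classes use the band `[0.2, 0.8]` for hets.
4. **CAPS design** — find SNPs where exactly one allele matches an enzyme
   recognition site (all overlapping windows, both strands), pick flanking
   primers (length 18–25 nt, product 100–500 bp, GC 35–65 %, Wallace
   Tm 52–68 °C, pair ΔTm ≤ 4 °C), and predict allele-specific digest
   fragments, rejecting amplicons with constitutive sites.
5. **Synthetic cohorts** — a seeded generator producing a reference,
   diploid truth genotypes and per-sample pileups (Poisson depth, binomial
   allele sampling at hets, uniform miscalls), so every stage is testable
   against known truth without any downloads.

## Worked example

```sh
cat > cohort.yaml <<EOF
cohort:
  genome_length: 50000
  n_samples: 6
  snp_rate: 0.001
  depth_means: [12.0, 18.0, 25.0, 9.0, 33.0, 15.0]
  planted_caps_sites: 4
  seed: 42
EOF
caps-forge run --config cohort.yaml --outdir out
```

prints

```
61 candidate sites, 56 matrix sites, 4 assays -> out
```

i.e. 61 distinct filtered candidate SNVs across the 6 samples, of which 56
were covered ≥ 5x in every sample and entered the frequency matrix, and 4
yielded valid CAPS assays (the 4 planted site-disrupting SNPs). The matrix
(`out/matrix.tsv`, one row per sample, one column per site) starts

```
sample  chr1:843_T>C  chr1:1448_T>C  chr1:1468_C>A
s01     0.583         0.571          0.429
s02     0.500         0.947          0.522
s03     0.531         0.476          0.000
```

— values near 0.5 are heterozygous calls, 0.000 homozygous reference,
0.947 homozygous variant. The assay sheet (`out/assays.tsv`) reads

```
no  product_size_bp  enzyme  target            cleavable_allele  fragments_cleaved_bp  fragments_uncleaved_bp
1   100              BamHI   chr1: 1939-2038   ref               37,63                 100
2   100              BglII   chr1: 17254-17353 ref               21,79                 100
```

Row 1: a 100-bp product whose reference allele is cut by BamHI into 37 +
63 bp fragments while the variant allele stays uncut, so the three
genotypes give distinct band patterns. The stages are also available
individually (`caps-forge simulate | call | filter | matrix | caps`) and as
library functions.

The package also ships a reference panel of 22 published enset PCR-RFLP
assays (primers, enzymes, product sizes and JTFG02-contig target spans)
used to pin the 1-based inclusive coordinate convention:

```python
from capsforge.resources import load_enset_rflp_panel
load_enset_rflp_panel().head()
```

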