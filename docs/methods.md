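# Methods

This document states the statistical model implemented by each module, the
default parameters and why they are set where they are, the scope of the
synthetic-world generator, and the numerical choices and limitations a user
should know before trusting the output.

## Site classification (`passcan.variants`)

Input is a multi-sample diploid VCF with two designated populations A and B.
Per site, a population's genotypes are reduced to its set of called alleles
(missing alleles ignored). A site is first subjected to a retention filter:
at least `min_called_a` samples fully called in A **and** `min_called_b` in B
(defaults 10 of 12 and 9 of 11); otherwise it is `UNINFORMATIVE`. Classes:

- `FIXED_A` — every called A-genotype is homozygous for one alternate allele,
  and B does not share that state (B polymorphic, or fixed for reference or a
  different allele). `FIXED_B` symmetric.
- `SHARED_FIXED_ALT` — both populations fixed for the same alternate allele.
  Both fixed for *different* alternates is `UNINFORMATIVE` (no polymorphic
  side to anchor the contrast).
- `POLY_A_ONLY`, `POLY_B_ONLY`, `POLY_BOTH` — segregating in the named
  population(s), the other fixed (reference or alternate).
- `MONOMORPHIC_REF` — all called genotypes homozygous reference.

Classification uses genotypes only; it is invariant to swapping A and B
labels up to the obvious class renaming (tested).

## Sweep scan (`passcan.sweep_scan`)

Windows of 50 kb advance in 10-kb steps along each chromosome (a chromosome
shorter than one window is a single truncated window; terminal windows are
truncated at the chromosome end). Per window, the counts
`F_A = |FIXED_A|`, `P_A = |POLY_A_ONLY| + |POLY_BOTH|` (and symmetrically for
B) form the 2×2 table `[[F_A, P_A], [F_B, P_B]]`, tested for homogeneity
with Fisher's exact test (default; a Pearson chi-square without continuity
correction is available, but the exact test is the default because
polymorphism-poor inbred windows routinely have cells below 5). A table with
a zero row or zero column carries no information about the ratio and is
assigned p = 1; a window with no counted sites at all is untestable and is
excluded from the multiplicity correction. Bonferroni is applied over the m
testable windows; a window is selected when `p_adj < alpha` (strict, default
alpha 0.05) **and** it is oriented toward A: `F_A·P_B > F_B·P_A` and
`F_A > F_B` (an optional `min_f_ratio` additionally requires
`F_A > k·F_B`). Selected windows on the same chromosome are merged into PASS
regions when they overlap or are bookended (distance 0); each region records
its window count and minimum adjusted p.

## Window statistics (`passcan.popgen`)

Computed in non-overlapping 10-kb tiles over the sites that pass the same
retention filter as classification.

**Tajima's D** uses the 1989 constants (a1, a2, b1, b2, c1, c2, e1, e2). For
a window, the haplotype count is `n = 2 × (minimum fully-called samples over
the window's sites)` and each site's alternate count is projected onto that
common n (rounded hypergeometric expectation). θπ is computed from allele
counts as `Σ k(n−k)/C(n,2)` — phase-free, correct for unphased diploid data
under the random-union convention. D is undefined (NaN) for n < 4 or S = 0.

**Fst** is Weir & Cockerham (1984) with r = 2 populations: per-site variance
components a (between), b (within-population between-individual), c
(within-individual, from observed heterozygosity). The window estimate is the
ratio-of-sums `Σa / Σ(a+b+c)` ("weighted") alongside the mean of per-site
ratios. Sites monomorphic across the pooled sample are skipped; negative
estimates are reported as-is (truncating them at zero would bias window
means upward).

**Fixed-variant density** is fixed sites per kb of *actual* window length
(truncated terminal windows use their true length).

## Effect annotation (`passcan.effects`)

Gene models come from GFF3 (`gffutils`); per gene the transcript with the
longest CDS is kept, and models whose CDS length is not a multiple of 3 are
skipped with a warning. For an SNV inside the CDS, the affected codon is
rebuilt in transcript orientation (reverse-complementing for minus-strand
genes), translated with the standard code, and labelled `SYNONYMOUS`,
`NONSYNONYMOUS` (with `G86R`-style notation), `STOPGAIN`, or `STOPLOSS`
(a stop-to-stop change is counted synonymous). Indels inside the CDS are
`FRAMESHIFT` when the length difference is not a multiple of 3, else
`NONFRAMESHIFT_INDEL`. Variants within 2 bp of an intron/exon boundary are
`SPLICE_REGION`; everything else in the gene span or outside genes is
`NONCODING`. The annotator refuses (raises) when the VCF reference allele
does not match the FASTA at that position — a silent mismatch would corrupt
every downstream count.

**SAAC sets** (population-exclusive amino-acid-change genes): a gene is in
SAAC-A if some A-fixed variant changes its protein (non-synonymous, stop
gain/loss, or any CDS indel) and no B-fixed variant does; set difference of
the per-population amino-acid-changed gene sets. The NS/S enrichment test is
Fisher's exact on `[[NS_in, S_in], [NS_out, S_out]]` with PASS-region overlap
defining "in".

## Differential expression (`passcan.expression`)

Counts are TPM-normalized (length-corrected, columns scaled to 1e6), then
log2(TPM+1)-transformed. Per developmental stage, paired case/control
samples are compared with a regularized paired t-statistic in the Cyber-T
style: the per-gene SD s of paired differences is shrunk toward a background
σ₀, the mean SD of the w = 101 genes nearest in expression rank, giving

    σp² = (v₀·σ₀² + (n−1)·s²) / (v₀ + n − 2),   df = v₀ + n − 2

with prior weight v₀ = 10 by default. At v₀ = 0 the formula above would
divide the (n−1)-weighted variance by n−2, which is *not* the classical
paired t; v₀ = 0 is therefore special-cased to the exact classical paired
t-test (σp = s, df = n−1), and the test suite pins this limit to
`scipy.stats.ttest_rel` at 1e-10. P-values are Benjamini–Hochberg corrected
(via `statsmodels`); DE means q < 0.05 at any stage.

**Candidate integration**: candidates = marked genes ∩ SAAC-A ∩ (genes
overlapping a PASS region by ≥ 1 bp ∪ DE-at-any-stage genes).

## Synthetic worlds (`passcan.synthetic`)

The generator produces, from one integer seed, a complete deterministic
input set: FASTA reference, GFF3 gene models, multi-sample VCF, QTL BED,
paired count matrix, marked-gene list, and a ground-truth record.

Model and default parameters (the study conditions):

- Genome: 2 chromosomes × 2 Mb, uniform random bases.
- Genes: 200 intact CDS models (100–300 codons, 1–3 exons, both strands,
  ATG…stop with no internal stops), at least one inside every sweep.
- Founder sites: 3 per kb, positions drawn without replacement,
  independent across sites (**no linkage**). Each site gets a truth class:
  inside a planted sweep, `FIXED_A` with probability 0.9; elsewhere fixation
  probability 0.02 per population, the rest split among polymorphic classes.
  Polymorphic sites segregate homozygous 0/0 vs 1/1 across samples (inbred
  lines), with forced segregation. 2% of sites are 1–3-bp indels.
- Sweeps: two 200-kb intervals (chr1 at 0.5–0.7 Mb, chr2 at 1.0–1.2 Mb).
- Noise, applied after truth is recorded: residual heterozygosity 0.04 per
  genotype (real inbred colonies are not perfectly homozygous; this leaves
  per-sample variant calls ≈ 90–94% homozygous, matching the regime the
  method is designed for), then missingness 0.02.
- Expression: negative-binomial counts (dispersion 0.1), lognormal gene
  means, per-sample depth factors U(0.8, 1.2) so TPM normalization is doing
  real work; 30 planted DE genes shifted by log2FC = 2 in all A samples over
  3 stages × 3 pairs.
- QTLs: one interval covering each sweep with random margins, plus random
  ones, merged.

The founder density of 3 sites/kb is a power choice made a priori: with 4%
residual heterozygosity, a planted fixed site survives as observed-fixed with
probability ≈ 0.96²³ ≈ 0.39, and at 1 site/kb the expected sweep-window table
(≈ [[17, 30], [0, 16]]) gives a Fisher p around 4e-4 — not significant after
Bonferroni over ~400 windows. At 3 sites/kb the expected table
(≈ [[52, 64], [0, 55]]) gives p ≈ 1e-9, comfortably detectable, so the
generator exercises the pipeline in a regime where the planted signal is
recoverable by design rather than by tuning against test outcomes.

Out of scope for the generator: linkage and haplotype structure, coalescent
or forward-simulation realism, read-level sequencing error, multi-allelic
sites, structural variants. Every implemented statistic is count-based per
window, so independent sites suffice for validating correctness; they do
**not** validate behavior under linked background selection.

## Numerical and engineering choices

- Fisher's exact p-values come from `scipy.stats.fisher_exact` (two-sided by
  the minimum-likelihood rule); the test suite checks them against direct
  hypergeometric enumeration for every table with row margins ≤ 12.
- Bonferroni only counts testable windows; strict inequality at alpha.
- All randomness flows from a single `numpy.random.default_rng(seed)` chain
  per world; output files are written deterministically (fixed column
  orders, fixed float formats), and `manifest.json` records parameters and
  input MD5 checksums, so identical seed + inputs ⇒ byte-identical outputs.
- Window binning uses sorted position arrays and `searchsorted`; memory is
  bounded in windows per chromosome, not sites.

## Limitations

- The homogeneity test treats windows as independent; Bonferroni over
  overlapping windows is conservative in number but the 50-kb/10-kb overlap
  correlates neighboring tests — region boundaries are resolution-limited
  to about one window (the worked example recovers 200-kb sweeps with
  Jaccard ≈ 0.8 against truth).
- Tajima's D windows project sites onto a common haplotype count; windows
  mixing very different call rates lose a little information.
- The effect annotator evaluates one variant at a time; compound effects of
  multiple fixed variants in one codon are not combined.
- The Cyber-T background σ₀ uses a rank-window mean, not a full hierarchical
  fit; v₀ is a fixed prior weight, not estimated from data.
- With few true polymorphic sites inside a sweep (as in the synthetic
  worlds), residual-heterozygosity singletons dominate both populations'
  site-frequency spectra there, so Tajima's D drops inside sweeps for the
  *non*-selected population too; the discriminating signals between
  populations are the fixed-variant classes, density, and Fst.
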