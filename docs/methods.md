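# Methods

This note documents the models implemented in `stratld`, the defaults and
the reasoning behind them, the synthetic data generator used for
validation, and what the validation experiments do and do not demonstrate.

## Heritability model and regression

The generative model is the standard additive polygenic architecture with
annotation-dependent effect-size variance: phenotypes follow
**Y = Xβ + ε** on standardized genotypes, with
var(β_j) = Σ_c a_cj τ_c. Marginal GWAS χ² statistics then satisfy
E[χ²_j] = N Σ_c l(j,c) τ_c + 1, where l(j,c) = Σ_k a_ck r²_jk is the
stratified LD score of SNP j for annotation c, summed over SNPs k within a
window around j (including k = j). The "+1" is the no-confounding
expectation; the intercept is estimated freely by default (a fixed-at-1
mode exists), so uncorrected stratification inflates the intercept rather
than the coefficients.

**LD score estimation.** r²_jk is the squared Pearson correlation of
mean-imputed, standardized reference dosages. The default estimator applies
the small-sample adjustment r̃² = r² − (1 − r²)/(N_ref − 2), which removes
the ~1/N_ref upward bias for independent SNPs (a raw-r² flag exists, and is
the right choice when the same scores are used both to generate and to fit
a simulation). Windows are symmetric around the focal SNP: 1 cM when a
genetic map is available, otherwise a kb half-width (library default
1,000 kb; the validation experiments use 100 kb, which amply covers the
generator's LD blocks). Computation streams over SNP chunks, so memory is
O(window × N_ref), and results are independent of the chunk size (tested).

**Fitting.** Weighted least squares of χ²_j on {N_j · l(j,c)}_c plus an
intercept column. Default regression weights multiply two terms evaluated
on a designated weight-annotation score l_w (the all-ones base column by
default): an LD over-counting term 1/max(l_w, 1) and a heteroskedasticity
term 1/(2(N l_w ĥ²/M + 1)²) with ĥ² from an unweighted one-pass pre-fit;
the product is normalized to mean 1. Uniform weights are available. Rank
deficiency raises an error naming the (near-)collinear columns.

**Uncertainty.** Delete-one block jackknife over 200 contiguous,
equal-count (±1) blocks in genome order: cov = (B−1)/B Σ_b (θ̂_(b) −
θ̄)(θ̂_(b) − θ̄)'. Blocks are long relative to LD, making the SEs robust to
correlation between nearby regression SNPs. On well-specified synthetic
data the jackknife SEs agree with analytic WLS SEs within a factor 1.5 and
nominal 95% intervals cover the truth in ≥ 85% of replicates (tested).

**Derived metrics.**

* Total SNP heritability h²_g = Σ_c τ_c Σ_j a_cj, with the sums taken over
  the *full* panel (M SNPs) regardless of the regression-SNP subset.
* Enrichment E_c = (h²_g(c)/h²_g)/(Σ_j a_cj/M), where h²_g(c) =
  Σ_j a_cj var(β_j); defined for binary and probabilistic annotations only
  (for an unbounded continuous column "share of SNPs" has no meaning).
  Computed via the full-panel gram matrix A'A, so E_c = (A'Aτ)_c/(s'τ) ·
  M/s_c; the all-ones base annotation has E = 1 identically. SEs by
  jackknife of the ratio (delete-one τ estimates, annotation sums fixed);
  p-values test E = 1.
* Standardized effect size τ*_c = τ_c sd_c/(h²_g/M), the proportionate
  change in per-SNP heritability per 1-sd increase of the annotation.
  sd_c is the annotation's population standard deviation over the full
  panel (the natural reading of "per standard deviation of the
  annotation"). In the jackknife, sd_c and h²_g are held at full-sample
  values so that only τ varies; p-values are two-sided normal on
  τ*/se(τ*). τ* of a zero-variance annotation is undefined: the base
  column is omitted from τ* tables, and requesting it raises.

## Conditional analyses and meta-analysis

A focal annotation's unique contribution is its τ* estimated jointly with a
fixed conditioning set, meta-analyzed across traits. Meta-analysis defaults
to random effects (DerSimonian–Laird method-of-moments between-trait
variance); fixed-effects inverse-variance weighting is available; a single
trait passes through unchanged. Significance is assessed at α/B with an
explicit Bonferroni denominator B — never inferred from the number of
tests run.

Forward stepwise elimination starts from all (caller-screened) marginally
significant candidates plus the conditioning set, and repeatedly removes
the candidate with the largest meta-analyzed τ* p-value (ties broken
lexicographically by name, making the procedure deterministic and
input-order invariant) until every remaining candidate passes α/B. One
candidate is removed per refit; the final refit's statistics are the ones
reported. Stepwise selection among highly correlated annotations is
inherently somewhat arbitrary — the trace of removals is returned so any
run can be replayed and audited.

## Weighted k-mer enrichment

For a probabilistic annotation D over SNPs and per-window k-mer counts
κ_s, WKE = (Σ_s D_s κ_s)/(D̄ Σ_s κ_s): the D-weighted mean count relative
to a null annotation holding every value at D̄. WKE is scale-invariant in
D and equals 1 exactly for constant D.

K-mers are merged with reverse complements into canonical classes named by
the lexicographically smaller member; a class's count in a window is the
number of positions (overlaps allowed) matching either member on the given
strand — equivalent to counting one member on both strands — and
palindromic classes, which have a single member, are counted once per
position. K-mers overlapping an ambiguous base contribute nothing.
Enumeration for 1 ≤ k ≤ 5 yields 2 + 10 + 32 + 136 + 512 = 692 classes
(verified against a brute-force enumerate-and-merge oracle up to k = 6);
a count of 682 sometimes quoted for this enumeration is not reproducible
under any merging convention we could construct, so the package reports
the enumerated 692.

Significance: D is permuted across SNPs n_perm times (default 10,000), a
Gaussian is fitted to the permuted WKE values, and z = (WKE − μ̂)/σ̂ gives a
one-sided upper p by default (enrichment being the hypothesis of interest;
a two-sided flag exists). An empirical rank p is reported alongside for
diagnostics. Degenerate nulls (constant counts) raise rather than return
p = 0.5. Windows share the annotation module's coordinate convention
(below).

## SNP classification

Positives are matched 1:1 to controls drawn without replacement from the
same covariate bin (MAF by default, bin width 0.01; further covariates such
as local GC content can be added), deterministically per seed; an exhausted
bin raises with the bin and shortfall named. Feature sets are evaluated by
pooled out-of-fold AUROC — the probability a random positive outranks a
random control, ties half — under leave-one-chromosome-out CV by default
(preventing leakage through LD between nearby train/test SNPs) or
stratified k-fold. The learner is pluggable behind a fit/predict_proba
contract; the default is gradient-boosted trees with conservative fixed
hyperparameters (depth 3, 150 rounds, learning rate 0.1, 80% row/column
subsampling, L2 regularization) chosen to limit overfitting while staying
deterministic; they are settings to be tuned per application, not a claim
of optimality.

## Coordinate conventions

Panel positions are 1-based; BED and all internal intervals are 0-based
half-open. A 1-based position p lies in [start, end) iff p − 1 does. The
"±w bp window around a SNP" is the 0-based interval
[pos − 1 − w, pos − 1 + w + 1), i.e. 2w + 1 bases untruncated (w = 500
gives the conventional 1 kb window), truncated at chromosome ends.
Ambiguous bases are excluded from local-content denominators (GC content:
non-N bases; CpG content: dinucleotide positions with both bases non-N).
Overlapping gene-score windows resolve to the maximum score (conservative
for deleteriousness-style scores; configurable to sum).

Quantile matching maps source ranks (average ranks for ties) onto the
reference's order statistics; with equal lengths and no ties the sorted
output equals the sorted reference exactly, and unequal lengths interpolate
the reference empirical quantile function. Matching of aggregated
annotations is applied after aggregation (each aggregate matched onto its
counterpart); per-tissue matching before aggregation is possible by calling
the same function on the tissue columns.

## Synthetic data generator

The generator reproduces the statistical structure the estimators assume,
not population-genetic realism:

* **Genotypes**: per-haplotype latent Gaussians, equicorrelated (ρ,
  default 0.7) within contiguous blocks of 50 SNPs, thresholded at the
  per-SNP MAF quantile (MAF ~ Uniform[0.05, 0.5]) and summed to {0,1,2}
  dosages; blocks are laid out contiguously across 4 chromosomes with
  0.5–1.5 kb spacing. SNPs with minor allele count < 5 are dropped.
* **Annotations**: equicorrelated Gaussian latents (target pairwise r,
  default 0.2) thresholded for binary columns (target size = the
  threshold quantile), logistic-squashed for probabilistic columns; an
  all-ones base column is prepended. Default set: base + 2 binary (sizes
  0.1, 0.3) + 2 probabilistic.
* **Summary statistics**: per-SNP variances Σ_c a_cj τ_c (negative values
  clipped at 0 with the fraction logged; > 5% clipped is an error; total
  h² > 1 is an error). Summary mode draws z_j ~ N(0, √(1 + N Σ_c l(j,c)
  τ_c)) from LD scores computed on the reference genotypes — exact in the
  marginal expectation, but independent across SNPs (it ignores the LD
  between test statistics). Individual mode draws β, fresh genotypes and
  phenotypes and computes marginal χ² per SNP — the fidelity reference,
  used at small scale; the two modes give τ̂ estimates that agree within
  combined uncertainty (tested). Default τ places h²/2 on the base and
  splits h²/2 evenly across the other annotations (h² = 0.5).
* **Sequences**: i.i.d. uniform ACGT windows with a target canonical k-mer
  planted Poisson(rate_s) times, rate_s = base_rate · max(0, 1 + effect ·
  (D_s − D̄)); base_rate 3 per window, and effect = 4 is the documented
  "strong" setting used in power experiments. Planting displaces a small
  fraction of background sequence, so at very small windows non-target
  classes can be slightly depleted; at the standard ±500 bp window the
  displacement is negligible.

Everything is deterministic given the config seed.

Because LD, MAF spectra and annotation geometries are stylized, passing
validation demonstrates the correctness and calibration of the estimators
under their assumed model — not robustness to coalescent LD, MAF-dependent
architectures, imputation noise or annotation mis-specification in real
data.

## Validation experiment scales

The reference experiments (`stratld.experiments`, asserted in
`tests/test_acceptance.py` and reported by `scripts/acceptance.py`) use:
τ recovery at M = 20,000 / C = 5 / N_gwas = 50,000, 50 replicates; null
calibration at M = 10,000, 200 replicates; oracle equivalences at
M = 1,000–4,000; permutation calibration with 500 null draws (250 windows
of ±100 bp, 300 permutations each) and power with 50 replicates at 10,000
permutations; stepwise behaviour at M = 3,000 with 3–5 traits. These sizes
were chosen so the full suite completes in well under a minute on one core
while leaving Monte-Carlo margins comfortably wide.

## Known limitations

* Summary-mode simulation ignores correlation between χ² statistics;
  jackknife calibration under realistic statistic-level LD is exercised
  only qualitatively (blocked LD, individual mode at small scale).
* Enrichment SEs treat annotation sums as fixed (only τ is resampled), as
  is conventional.
* Stepwise elimination is a heuristic; with highly correlated candidates
  the retained choice can be nearly arbitrary (the trace is reported).
* The allele-harmonization policy for summary statistics is match-by-id
  with dropped mismatches (counted in a warning); no strand-flip
  resolution is attempted.
* No haplotype phasing, signed LD matrices, per-allele effect scales, or
  genetic-correlation machinery.
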