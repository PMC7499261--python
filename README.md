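# stratld

Stratified LD score regression and evaluation machinery for **continuous
per-SNP functional annotations** — aimed at statistical geneticists who want
to ask whether an annotation (for example, a model-predicted chromatin-mark
probability, or an allelic-effect score |ref − alt|) carries *unique*
information about complex-trait heritability, conditional on everything else
already in the model.

## The model

An annotation assigns a value *a<sub>cj</sub>* to every SNP *j* of a
reference panel (binary 0/1, probabilistic in [0, 1], or unrestricted
continuous). Per-SNP effect-size variance is assumed linear in annotations,

&nbsp;&nbsp;&nbsp;&nbsp;var(β<sub>j</sub>) = Σ<sub>c</sub> a<sub>cj</sub> τ<sub>c</sub>,

which links GWAS χ² statistics to the coefficients τ<sub>c</sub> through the
stratified LD scores l(j,c) = Σ<sub>k</sub> a<sub>ck</sub> r²<sub>jk</sub>:

&nbsp;&nbsp;&nbsp;&nbsp;E[χ²<sub>j</sub>] = N Σ<sub>c</sub> l(j,c) τ<sub>c</sub> + 1.

`stratld` estimates τ by weighted least squares with a free intercept and
delete-one **block jackknife** standard errors (200 contiguous genomic
blocks), and reports two per-annotation metrics:

* **Enrichment** E<sub>c</sub> = (h²<sub>g</sub>(c)/h²<sub>g</sub>) /
  (Σ<sub>j</sub> a<sub>cj</sub>/M) — value-weighted share of heritability
  over share of SNPs (binary/probabilistic annotations);
* **Standardized effect size** τ*<sub>c</sub> = τ<sub>c</sub> sd<sub>c</sub> /
  (h²<sub>g</sub>/M) — proportionate change in per-SNP heritability per
  1-sd increase in the annotation, *conditional* on the other annotations;
  this is the quantity that measures unique information.

Around this core the package provides:

* **annotations** — construction and transformation: tissue aggregation
  (avg/max), quantile matching onto a reference distribution, allelic-effect
  scores, region restriction, local CpG/GC content, gene-score windows, and
  ldsc-style `.annot` I/O;
* **ldscores** — stratified LD scores from a PLINK reference panel
  (kb or cM windows, bias-adjusted r̃² = r² − (1 − r²)/(N − 2) by default);
* **sldsc** — the regression itself, statsmodels-style:
  `StratifiedLDRegression(...).fit()` returns `SLDSCResults` with
  `enrichment()`, `tau_star()` and `summary()`;
* **conditional** — marginal τ* analyses meta-analyzed across traits
  (random- or fixed-effects), and forward stepwise elimination to a joint
  model under Bonferroni correction;
* **kmer** — the weighted k-mer enrichment statistic
  WKE = Σ<sub>s</sub> D<sub>s</sub>κ<sub>s</sub> / (D̄ Σ<sub>s</sub>κ<sub>s</sub>)
  over canonical (reverse-complement-merged) k-mers in SNP windows, with a
  Gaussian-fit permutation test;
* **classify** — MAF-matched control selection and cross-validated AUROC of
  annotation feature sets for disease-associated SNP classification
  (leave-one-chromosome-out by default, gradient-boosted trees by default);
* **simulate** — a synthetic generator (block-LD panels, correlated
  annotations, χ² summary statistics with known τ, sequence windows with
  planted k-mer signal) so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from stratld import (SimConfig, WindowSpec, fit_sldsc, gen_annotations,
                     gen_panel, gen_sumstats, stratified_ld_scores)
from stratld.simulate import default_tau

cfg = SimConfig(m=10_000, n_ref=500, n_gwas=50_000, seed=42)
panel, geno = gen_panel(cfg)
annots = gen_annotations(cfg, panel)          # base + 2 binary + 2 probabilistic
tau = default_tau(cfg, annots)                # true coefficients, h2 = 0.5

scores = stratified_ld_scores(geno, annots, WindowSpec("kb", 100),
                              adjusted=False)
ss = gen_sumstats(panel, geno, annots, tau, cfg.n_gwas, mode="summary",
                  seed=43, ldscores=scores)

res = fit_sldsc(ss, scores, n_blocks=200)
print(res.summary())
print("true tau:", np.array2string(tau, precision=3))
```

prints

```
Stratified LD score regression
================================================================
trait:        sim_trait
regression SNPs: 10000   panel SNPs (M): 10000
jackknife blocks: 200   intercept: free
h2_g = 0.5206 (SE 0.0442)   intercept = -0.01924 (SE 2.15)
----------------------------------------------------------------
             size        tau    tau_se     tau_p  tau_star  tau_star_se  tau_star_p  enrichment  enrichment_se  enrichment_p
annotation
base            1  1.808e-05 1.469e-05    0.2187       NaN          NaN         NaN           1      1.469e-15        0.8799
ann1       0.1004   6.71e-05 1.746e-05 0.0001211    0.3874       0.1008   0.0001211       2.274         0.3141     5.002e-05
ann2       0.2947  2.318e-05 9.791e-06   0.01789     0.203      0.08574     0.01789       1.406          0.136      0.002807
ann3       0.5013 -9.728e-06 2.445e-05    0.6907  -0.03903      0.09809      0.6907       1.034        0.03834        0.3774
ann4       0.4968  5.091e-05   2.4e-05   0.03393    0.2025      0.09545     0.03393       1.112        0.04025      0.005543

true tau: [2.500e-05 6.225e-05 2.121e-05 1.247e-05 1.258e-05]
```

Reading the table: the total SNP heritability estimate (0.52, truth 0.50)
and every τ̂ fall within ~2 jackknife SEs of the truth; the all-ones base
annotation has enrichment exactly 1 by construction (and no τ*, since a
constant annotation has no standard deviation); the 10%-of-SNPs binary
annotation `ann1`, which carries a concentrated share of heritability, shows
the strongest enrichment (2.27×) and the largest standardized effect size
(τ* = 0.39, p ≈ 1e-4).

The same operations are exposed as a CLI:

```bash
stratld simulate --config sim.yaml --out data/
stratld ldscore  --bfile data/panel --annot data/annotations.annot.gz \
                 --window-kb 100 --raw-r2 --out data/scores
stratld sldsc    --sumstats data/trait.sumstats.gz --ldscores data/scores \
                 --out fit.tsv
```

plus `make-annot`, `stepwise`, `kmer-enrich` and `classify` subcommands.

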