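"""Synthetic panels, annotations, summary statistics and sequences.

The generator reproduces the statistical structure the analyses assume,
without coalescent realism: genotypes come from block-equicorrelated latent
Gaussians thresholded to Hardy-Weinberg dosages; annotations from
correlated Gaussians (thresholded for binary, logistic-transformed for
probabilistic); chi-square statistics from the additive polygenic model in
which per-SNP effect-size variance is a linear combination of annotation
values (var(beta_j) = sum_c a_cj tau_c); and sequence windows are uniform
background DNA with a target k-mer planted at a rate that covaries with a
chosen annotation.  Everything is deterministic given the config seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotations import Annotation, AnnotationMatrix
from .io import SummaryStats
from .kmer import CanonicalKmer
from .ldscores import StratifiedLDScores, WindowSpec, stratified_ld_scores
from .panel import GenotypePanel, SnpPanel


@dataclass
class AnnotationSpec:
    """One simulated annotation: kind and (for binary) target size."""
    name: str
    kind: str = "probabilistic"
    size: float = 0.1            # target mean for binary annotations


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the scale at which the package's recovery experiments
    run: a 20,000-SNP panel with 50-SNP LD blocks of within-block latent
    correlation 0.7, MAF uniform on [0.05, 0.5], a 500-sample reference
    panel and GWAS sample size 50,000, with total SNP heritability 0.5
    split evenly between a uniform (base) component and the annotation
    effects.
    """
    m: int = 20_000
    n_ref: int = 500
    n_gwas: int = 50_000
    block_len: int = 50
    rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    n_chroms: int = 4
    annotations: list = field(default_factory=list)
    annot_corr: float = 0.2      # target pairwise correlation of latents
    tau: np.ndarray | None = None
    h2_total: float = 0.5        # used when tau is None
    intercept: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("within-block correlation rho must be in [0, 1)")
        if not self.annotations:
            self.annotations = [
                AnnotationSpec("ann1", "binary", 0.1),
                AnnotationSpec("ann2", "binary", 0.3),
                AnnotationSpec("ann3", "probabilistic"),
                AnnotationSpec("ann4", "probabilistic"),
            ]


def gen_panel(config: SimConfig, rng=None) -> tuple[SnpPanel, GenotypePanel]:
    """Block-LD reference panel: dosages from per-haplotype latent Gaussians
    with equicorrelation rho inside contiguous blocks, thresholded at the
    per-SNP MAF quantile."""
    rng = rng or np.random.default_rng(config.seed)
    m, n = config.m, config.n_ref
    maf = rng.uniform(*config.maf_range, size=m)
    block = np.arange(m) // config.block_len
    n_blocks = block[-1] + 1
    dosages = _draw_dosages(rng, n, maf, block, n_blocks, config.rho)

    # genome coordinates: blocks assigned to chromosomes in contiguous runs
    chrom_of_block = np.minimum(
        (np.arange(n_blocks) * config.n_chroms) // n_blocks,
        config.n_chroms - 1)
    chrom = np.array([f"chr{chrom_of_block[b] + 1}" for b in block],
                     dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for c in range(config.n_chroms):
        mask = chrom == f"chr{c + 1}"
        steps = rng.integers(500, 1500, size=mask.sum())
        pos[mask] = 1_000_000 + np.cumsum(steps)

    freq = dosages.mean(axis=0) / 2.0
    realized_maf = np.minimum(freq, 1 - freq)
    mac = np.minimum(dosages.sum(axis=0),
                     2 * n - dosages.sum(axis=0)).astype(np.int64)
    keep = mac >= 5
    panel = SnpPanel(
        np.array([f"rs{i}" for i in range(m)], dtype=object)[keep],
        chrom[keep], pos[keep],
        np.full(keep.sum(), "A", dtype=object),
        np.full(keep.sum(), "G", dtype=object),
        np.clip(realized_maf[keep], 1e-6, 0.5), mac[keep])
    return panel, GenotypePanel(panel, dosages[:, keep])


def _draw_dosages(rng, n, maf, block, n_blocks, rho):
    thresh = stats.norm.ppf(1 - maf)
    dos = np.zeros((n, len(maf)), dtype=np.int8)
    for _hap in range(2):
        u = rng.standard_normal((n, n_blocks))
        e = rng.standard_normal((n, len(maf)))
        z = np.sqrt(rho) * u[:, block] + np.sqrt(1 - rho) * e
        dos += (z > thresh[None, :]).astype(np.int8)
    return dos


def gen_annotations(config: SimConfig, panel: SnpPanel,
                    rng=None, include_base: bool = True) -> AnnotationMatrix:
    """Correlated annotations over the panel.

    Latents per SNP are equicorrelated Gaussians at the target pairwise
    correlation; binary annotations threshold at the size quantile,
    probabilistic ones pass through a logistic squashing, continuous ones
    stay Gaussian.  An all-ones base annotation is prepended by default.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    specs = config.annotations
    c = len(specs)
    r = config.annot_corr
    corr = np.full((c, c), r) + np.eye(c) * (1 - r)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"target correlation matrix (pairwise r={r}) is not positive "
            "semidefinite") from None
    g = rng.standard_normal((panel.m, c)) @ chol.T
    mat = AnnotationMatrix(panel)
    if include_base:
        mat.add(Annotation("base", np.ones(panel.m), "binary",
                           {"source": "synthetic"}))
    for i, spec in enumerate(specs):
        if spec.kind == "binary":
            t = stats.norm.ppf(1 - spec.size)
            vals = (g[:, i] > t).astype(float)
        elif spec.kind == "probabilistic":
            vals = 1.0 / (1.0 + np.exp(-g[:, i]))
        elif spec.kind == "continuous":
            vals = g[:, i]
        else:
            raise ValueError(f"unknown annotation kind {spec.kind!r}")
        mat.add(Annotation(spec.name, vals, spec.kind, {"source": "synthetic"}))
    return mat


def default_tau(config: SimConfig, annotations: AnnotationMatrix) -> np.ndarray:
    """Per-annotation coefficients placing h2_total/2 on the base annotation
    and splitting the rest evenly across the other columns (scaled by their
    value sums so each contributes equal heritability)."""
    sums = annotations.values().sum(axis=0)
    names = annotations.names
    tau = np.zeros(len(names))
    others = [i for i, n in enumerate(names) if n != "base"]
    if "base" in names:
        tau[names.index("base")] = config.h2_total / 2 / sums[names.index("base")]
        budget = config.h2_total / 2
    else:
        budget = config.h2_total
    for i in others:
        tau[i] = budget / len(others) / sums[i]
    return tau


def per_snp_variance(annotations: AnnotationMatrix, tau: np.ndarray,
                     max_clip_fraction: float = 0.05) -> np.ndarray:
    """var(beta_j) = sum_c a_cj tau_c, clipped below at 0.

    The clip fraction is logged via a warning; above ``max_clip_fraction``
    it is an error (the generative model cannot realize that tau)."""
    v = annotations.values() @ np.asarray(tau, float)
    frac = float((v < 0).mean())
    if frac > max_clip_fraction:
        raise ValueError(f"{frac:.1%} of per-SNP variances are negative; "
                         "tau is not realizable generatively")
    if frac > 0:
        warnings.warn(f"clipped {frac:.2%} negative per-SNP variances to 0")
    return np.clip(v, 0.0, None)


def gen_sumstats(panel: SnpPanel, genotypes: GenotypePanel,
                 annotations: AnnotationMatrix, tau, n_gwas: int,
                 mode: str = "summary", seed: int = 0,
                 ldscores: StratifiedLDScores | None = None,
                 intercept: float = 1.0,
                 trait: str = "sim_trait") -> SummaryStats:
    """Simulated GWAS chi-square statistics under the additive model.

    ``mode="summary"``: draw z_j ~ Normal(0, sqrt(intercept + N sum_c
    l(j,c) tau_c)) using LD scores computed from the reference genotypes
    (independence across statistics is an approximation; the marginal
    expectation matches the regression model exactly).  ``mode="individual"``:
    draw per-SNP effects beta_j ~ Normal(0, var(beta_j)), simulate fresh
    genotypes and phenotypes, and compute per-SNP marginal chi-squares —
    the fidelity reference, practical at small scale.
    """
    rng = np.random.default_rng(seed)
    tau = np.asarray(tau, float)
    v = per_snp_variance(annotations, tau)
    h2 = float(v.sum())
    if h2 > 1:
        raise ValueError(f"total h2 = {h2:.3f} > 1")
    if mode == "summary":
        if ldscores is None:
            ldscores = stratified_ld_scores(genotypes, annotations,
                                            WindowSpec("kb", 1000),
                                            adjusted=False)
        var = intercept + n_gwas * (ldscores.values @ tau)
        var = np.maximum(var, 0.05)
        z = rng.normal(0.0, np.sqrt(var))
        chi2 = z ** 2
    elif mode == "individual":
        n = int(n_gwas)
        beta = rng.normal(0.0, np.sqrt(v))
        x = _fresh_genotypes(rng, n, panel, genotypes)
        xs = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-12)
        gvalue = xs @ beta
        eps = rng.normal(0.0, np.sqrt(max(1.0 - h2, 1e-12)), size=n)
        y = gvalue + eps
        y = (y - y.mean()) / y.std()
        r = (xs.T @ y) / n
        chi2 = n * r ** 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SummaryStats(panel.snp_id, chi2, float(n_gwas), trait)


def _fresh_genotypes(rng, n, panel: SnpPanel, ref: GenotypePanel):
    """Fresh GWAS-cohort dosages matching the reference panel's MAFs, with
    block-equicorrelated latents whose correlation is estimated from the
    reference panel's mean adjacent-SNP dosage correlation."""
    m = panel.m
    maf = panel.maf
    thresh = stats.norm.ppf(1 - maf)
    # estimate a single latent rho from adjacent standardized correlations
    xs = ref.standardized()
    adj = np.einsum("ij,ij->j", xs[:, :-1], xs[:, 1:]) / ref.n_samples
    rho_hat = float(np.clip(np.mean(adj), 0.0, 0.95))
    block = np.arange(m) // 50
    dos = _draw_dosages(rng, n, maf, block, block[-1] + 1, rho_hat)
    return dos.astype(np.float64)


# ---------------------------------------------------------------------------
# sequence windows with planted k-mer signal
# ---------------------------------------------------------------------------

STRONG_EFFECT = 4.0      # documented strong planted-association setting
DEFAULT_BASE_RATE = 3.0  # expected planted occurrences per window at D = Dbar


def gen_sequences(panel: SnpPanel, target_kmer: CanonicalKmer,
                  annotation: Annotation, effect: float,
                  window_bp: int = 500, seed: int = 0,
                  base_rate: float = DEFAULT_BASE_RATE) -> dict:
    """Per-SNP window sequences: i.i.d. uniform ACGT background with the
    target k-mer planted Poisson(rate_s) times, where

        rate_s = base_rate * max(0, 1 + effect * (D_s - Dbar)).

    ``effect = 0`` gives no association between annotation and composition.
    Returns a mapping snp_id -> sequence of length 2*window_bp + 1.
    """
    rng = np.random.default_rng(seed)
    length = 2 * window_bp + 1
    k = target_kmer.k
    dv = annotation.values
    rate = base_rate * np.maximum(0.0, 1.0 + effect * (dv - dv.mean()))
    capacity = length // k
    if np.any(rate > 0.5 * capacity):
        raise ValueError("planting rate exceeds half the window capacity; "
                         "reduce base_rate or effect")
    bases = np.array(list("ACGT"))
    out = {}
    for s in range(panel.m):
        seq = bases[rng.integers(0, 4, size=length)]
        n_plant = rng.poisson(rate[s])
        if n_plant > 0:
            starts = rng.integers(0, length - k + 1, size=n_plant)
            member = target_kmer.members[
                rng.integers(0, len(target_kmer.members))]
            for st in starts:
                seq[st:st + k] = list(member)
        out[panel.snp_id[s]] = "".join(seq)
    return out
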