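"""Stratified LD score regression (S-LDSC).

The model links GWAS chi-square statistics to per-annotation heritability
coefficients tau_c through

    E[chi2_j] = N * sum_c l(j,c) * tau_c + intercept,

where l(j,c) are stratified LD scores.  Per-SNP heritability decomposes as
var(beta_j) = sum_c a_cj tau_c, so total SNP heritability is
h2 = sum_c tau_c * sum_j a_cj over the full panel.  The fit is weighted
least squares; standard errors come from a delete-one block jackknife over
contiguous genomic blocks, which is robust to local LD between regression
SNPs.  Two derived per-annotation metrics are reported:

* enrichment E_c: share of h2 explained by annotation c (value-weighted)
  divided by its share of SNPs — defined for binary/probabilistic
  annotations only;
* standardized effect size tau*_c = tau_c * sd_c / (h2 / M): proportionate
  change in per-SNP heritability per 1-sd increase in the annotation,
  conditional on the other annotations in the model.

Organisation follows the statsmodels convention: build a
:class:`StratifiedLDRegression` from data, call :meth:`fit`, and read
estimates off the returned :class:`SLDSCResults` (``summary()`` renders a
table).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SummaryStats
from .ldscores import StratifiedLDScores


class CollinearityError(ValueError):
    """Design matrix is rank deficient; message names the offending columns."""


def _find_collinear(design: np.ndarray, names) -> str:
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(design, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1 - 1e-8:
                pairs.append(f"{names[i]} ~ {names[j]}")
    if pairs:
        return "collinear annotation columns: " + "; ".join(pairs)
    return "design matrix is rank deficient (no single collinear pair found)"


def make_jackknife_blocks(n_snps: int, n_blocks: int) -> list:
    """Contiguous genome-order blocks with equal SNP counts (+/-1)."""
    if n_snps < n_blocks:
        raise ValueError(f"fewer regression SNPs ({n_snps}) than jackknife "
                         f"blocks ({n_blocks})")
    return [np.arange(b[0], b[-1] + 1)
            for b in np.array_split(np.arange(n_snps), n_blocks)]


def default_weights(weight_ld: np.ndarray, chi2: np.ndarray, n: np.ndarray,
                    m_total: int, h2_pre: float) -> np.ndarray:
    """Regression weights combining LD over-counting and heteroskedasticity.

    The over-counting term 1/max(l_w, 1) downweights SNPs whose signal is
    duplicated across LD partners; the heteroskedasticity term
    1/(2 * (N * l_w * h2/M + 1)^2) is the inverse approximate variance of a
    chi-square statistic under the model.  The product is normalized to
    mean 1.
    """
    lw = np.maximum(weight_ld, 1.0)
    h2 = min(max(h2_pre, 0.0), 1.0)
    overcount = 1.0 / lw
    hetero = 1.0 / (2.0 * (n * lw * h2 / m_total + 1.0) ** 2)
    w = overcount * hetero
    return w / w.mean()


class StratifiedLDRegression:
    """Weighted LD score regression model for one trait.

    Parameters
    ----------
    sumstats : SummaryStats
        chi2 and N per regression SNP (a subset of the score panel).
    ldscores : StratifiedLDScores
        Scores over the full panel; also carries full-panel annotation sums,
        sds and gram matrix used for h2, enrichment and tau* denominators.
    weights : {"default", "uniform"} or array
    intercept : {"free", "fixed"}
        "fixed" pins the intercept at 1 (the no-confounding expectation).
    n_blocks : int
        Jackknife blocks (contiguous, equal SNP counts).
    weight_annotation : str or None
        Name of the LD score column used in the default weights; defaults to
        the first column (conventionally the all-ones base annotation).
    """

    def __init__(self, sumstats: SummaryStats, ldscores: StratifiedLDScores,
                 *, weights="default", intercept: str = "free",
                 n_blocks: int = 200, weight_annotation: str | None = None):
        self.sumstats = sumstats
        self.ldscores = ldscores
        self.weights = weights
        self.intercept_mode = intercept
        self.n_blocks = n_blocks
        self.weight_annotation = weight_annotation
        if intercept not in ("free", "fixed"):
            raise ValueError("intercept must be 'free' or 'fixed'")
        # align regression SNPs to panel (genome) order
        panel = ldscores.panel
        idx = panel.index_of(sumstats.snp_id)
        order = np.argsort(idx, kind="mergesort")
        self._panel_idx = idx[order]
        self._chi2 = sumstats.chi2[order]
        self._n = sumstats.n[order]

    @classmethod
    def from_files(cls, sumstats_path, ldscore_prefix, **kwargs):
        from .io import read_ldscores, read_sumstats
        scores = read_ldscores(ldscore_prefix)
        ss = read_sumstats(sumstats_path)
        keep = pd.Series(ss.snp_id).isin(scores.panel.snp_id).to_numpy()
        ss = SummaryStats(ss.snp_id[keep], ss.chi2[keep], ss.n[keep], ss.trait)
        return cls(ss, scores, **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "SLDSCResults":
        scores = self.ldscores
        L = scores.values[self._panel_idx]          # (n_reg, C)
        chi2, n = self._chi2, self._n
        n_reg, c = L.shape
        design = n[:, None] * L
        free = self.intercept_mode == "free"
        if free:
            design = np.column_stack([design, np.ones(n_reg)])
            y = chi2
        else:
            y = chi2 - 1.0
        names = list(scores.names) + (["intercept"] if free else [])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearityError(_find_collinear(design, names))

        if isinstance(self.weights, str) and self.weights == "default":
            wname = self.weight_annotation or scores.names[0]
            lw = scores.column(wname)[self._panel_idx]
            # one-pass unweighted pre-fit for the heteroskedasticity term
            pre, *_ = np.linalg.lstsq(design, y, rcond=None)
            h2_pre = float(scores.annot_sums @ pre[:c])
            w = default_weights(lw, chi2, n, scores.m_total, h2_pre)
        elif isinstance(self.weights, str) and self.weights == "uniform":
            w = np.ones(n_reg)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (n_reg,):
                raise ValueError("weight vector length does not match "
                                 "regression SNPs")

        blocks = make_jackknife_blocks(n_reg, self.n_blocks)
        xw = design * w[:, None]
        xtwx = design.T @ xw
        xtwy = xw.T @ y
        theta = np.linalg.solve(xtwx, xtwy)
        # delete-one-block estimates
        theta_del = np.empty((len(blocks), design.shape[1]))
        for b, idx in enumerate(blocks):
            xb = design[idx]
            xwb = xw[idx]
            a_b = xtwx - xb.T @ xwb
            b_b = xtwy - xwb.T @ y[idx]
            theta_del[b] = np.linalg.solve(a_b, b_b)
        nb = len(blocks)
        dev = theta_del - theta_del.mean(axis=0)
        jack_cov = (nb - 1) / nb * (dev.T @ dev)
        return SLDSCResults(self, theta, theta_del, jack_cov, w, blocks)


class SLDSCResults:
    """Estimates, jackknife uncertainties and derived metrics of one fit."""

    def __init__(self, model: StratifiedLDRegression, theta, theta_del,
                 jack_cov, weights, blocks):
        self.model = model
        scores = model.ldscores
        c = scores.c
        self.names = list(scores.names)
        self.tau = theta[:c]
        self.tau_del = theta_del[:, :c]     # (n_blocks, C) delete-one values
        self.tau_cov = jack_cov[:c, :c]
        self.tau_se = np.sqrt(np.diag(jack_cov)[:c])
        free = model.intercept_mode == "free"
        self.intercept = float(theta[c]) if free else 1.0
        self.intercept_se = float(np.sqrt(jack_cov[c, c])) if free else 0.0
        self.weights_used = weights
        self.blocks = blocks
        self.n_blocks = len(blocks)
        self.m_total = scores.m_total
        self.annot_sums = scores.annot_sums
        self.annot_sds = scores.annot_sds
        self.kinds = list(scores.kinds)
        self.gram = scores.gram

    # -- heritability -----------------------------------------------------
    @property
    def h2_total(self) -> float:
        """Total SNP heritability sum_j sum_c a_cj tau_c over the panel."""
        return float(self.annot_sums @ self.tau)

    @property
    def h2_total_se(self) -> float:
        h2_del = self.tau_del @ self.annot_sums
        nb = self.n_blocks
        return float(np.sqrt((nb - 1) / nb *
                             np.sum((h2_del - h2_del.mean()) ** 2)))

    def tau_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.tau / self.tau_se
        return 2 * stats.norm.sf(np.abs(z))

    # -- enrichment -------------------------------------------------------
    def enrichment(self) -> pd.DataFrame:
        """Per-annotation enrichment with jackknife SE and p (tests E = 1).

        E_c = (h2(c)/h2) / (sum_j a_cj / M) with h2(c) = sum_j a_cj *
        var(beta_j); restricted to binary/probabilistic annotations.
        Computed via the full-panel gram matrix A'A: h2(c) = (A'A tau)_c.
        """
        if self.gram is None:
            raise ValueError("LD scores carry no annotation gram matrix; "
                             "enrichment needs full-panel annotation values")
        rows = []
        for i, name in enumerate(self.names):
            if self.kinds[i] == "continuous":
                continue
            size = self.annot_sums[i] / self.m_total
            if self.annot_sums[i] == 0:
                raise ValueError(f"annotation {name!r} has size 0; "
                                 "enrichment undefined")
            e = self._enrich_value(self.tau, i)
            e_del = np.array([self._enrich_value(t, i) for t in self.tau_del])
            nb = self.n_blocks
            se = np.sqrt((nb - 1) / nb * np.sum((e_del - e_del.mean()) ** 2))
            if se > 0:
                p = 2 * stats.norm.sf(abs(e - 1.0) / se)
            else:
                p = 1.0 if e == 1.0 else 0.0  # exact identity (base) or not
            rows.append((name, size, e, se, p))
        return pd.DataFrame(rows, columns=["annotation", "size", "enrichment",
                                           "se", "p"]).set_index("annotation")

    def _enrich_value(self, tau, i):
        h2c = float(self.gram[i] @ tau)
        h2 = float(self.annot_sums @ tau)
        return (h2c / h2) / (self.annot_sums[i] / self.m_total)

    # -- standardized effect size ----------------------------------------
    def tau_star(self, m_total: int | None = None,
                 names=None) -> pd.DataFrame:
        """tau*_c = tau_c * sd_c / (h2 / M) with jackknife SE and two-sided
        normal p-value; sd_c and h2 are held at full-sample values in the
        jackknife (only tau varies across delete-one blocks).

        By default zero-variance annotations (e.g. the all-ones base, for
        which tau* is undefined) are omitted; requesting one by name raises.
        """
        m = m_total or self.m_total
        h2 = self.h2_total
        if h2 <= 0:
            raise ValueError(f"total h2 = {h2:.3g} <= 0; tau* undefined")
        if names is None:
            keep = [i for i, sd in enumerate(self.annot_sds) if sd > 0]
        else:
            keep = [self.names.index(n) for n in names]
            for i in keep:
                if self.annot_sds[i] == 0:
                    raise ValueError(f"annotation {self.names[i]!r} has zero "
                                     "variance; tau* undefined")
        keep = np.asarray(keep, dtype=int)
        scale = self.annot_sds[keep] / (h2 / m)
        ts = self.tau[keep] * scale
        ts_del = self.tau_del[:, keep] * scale[None, :]
        nb = self.n_blocks
        dev = ts_del - ts_del.mean(axis=0)
        se = np.sqrt((nb - 1) / nb * np.sum(dev ** 2, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = ts / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"tau_star": ts, "se": se, "p": p},
            index=pd.Index([self.names[i] for i in keep], name="annotation"))

    # -- presentation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        ts = self.tau_star()
        df = pd.DataFrame({
            "size": self.annot_sums / self.m_total,
            "tau": self.tau, "tau_se": self.tau_se, "tau_p": self.tau_p(),
            "tau_star": ts["tau_star"], "tau_star_se": ts["se"],
            "tau_star_p": ts["p"]},
            index=pd.Index(self.names, name="annotation"))
        try:
            enr = self.enrichment()
            df["enrichment"] = enr["enrichment"]
            df["enrichment_se"] = enr["se"]
            df["enrichment_p"] = enr["p"]
        except ValueError:
            pass
        return df

    def summary(self) -> str:
        lines = [
            "Stratified LD score regression",
            "=" * 64,
            f"trait:        {self.model.sumstats.trait}",
            f"regression SNPs: {len(self.model._chi2)}   "
            f"panel SNPs (M): {self.m_total}",
            f"jackknife blocks: {self.n_blocks}   "
            f"intercept: {self.model.intercept_mode}",
            f"h2_g = {self.h2_total:.4g} (SE {self.h2_total_se:.3g})   "
            f"intercept = {self.intercept:.4g} (SE {self.intercept_se:.3g})",
            "-" * 64,
            self.to_frame().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_sldsc(sumstats: SummaryStats, ldscores: StratifiedLDScores,
              weights="default", n_blocks: int = 200,
              intercept: str = "free") -> SLDSCResults:
    """Convenience wrapper: build the model and fit in one call."""
    return StratifiedLDRegression(sumstats, ldscores, weights=weights,
                                  intercept=intercept,
                                  n_blocks=n_blocks).fit()


def enrichment(fit: SLDSCResults, annotations=None) -> pd.DataFrame:
    """Per-annotation enrichment (E, SE, p) of a fit.

    When an AnnotationMatrix is supplied its gram matrix replaces the one
    stored with the LD scores (useful for oracle checks on explicit values).
    """
    if annotations is not None:
        a = annotations.values()
        fit.gram = a.T @ a
        fit.annot_sums = a.sum(axis=0)
        fit.kinds = list(annotations.kinds)
    return fit.enrichment()


def tau_star(fit: SLDSCResults, m_total: int | None = None) -> pd.DataFrame:
    return fit.tau_star(m_total)
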