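"""Conditional informativeness analyses.

A focal annotation is "marginally" informative when its standardized effect
size tau*, estimated conditional on a fixed conditioning set (e.g. a
baseline model) and meta-analyzed across traits, survives Bonferroni
correction.  Marginally significant candidates then enter a joint model and
forward stepwise elimination iteratively drops the candidate with the
largest conditional meta p-value until all survivors are Bonferroni
significant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import Annotation, AnnotationMatrix
from .ldscores import LDScoreEngine
from .sldsc import CollinearityError, StratifiedLDRegression


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def meta_analyze(estimates, method: str = "random"):
    """Combine per-trait (value, SE) pairs.

    ``method="fixed"``: inverse-variance weighted mean.  ``method="random"``:
    DerSimonian-Laird method-of-moments between-trait variance added to the
    weights.  A single estimate is returned unchanged.  Returns
    (value, se, p) with a two-sided normal p-value.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 2 or est.shape[1] != 2 or len(est) == 0:
        raise ValueError("estimates must be a non-empty sequence of (value, SE)")
    v, se = est[:, 0], est[:, 1]
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    if method not in ("fixed", "random"):
        raise ValueError(f"unknown meta-analysis method {method!r}")
    if len(est) == 1:
        val, s = float(v[0]), float(se[0])
        return val, s, float(2 * stats.norm.sf(abs(val / s)))
    w = 1.0 / se ** 2
    mu_fixed = float(np.sum(w * v) / np.sum(w))
    if method == "random":
        q = float(np.sum(w * (v - mu_fixed) ** 2))
        df = len(v) - 1
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        w = 1.0 / (se ** 2 + tau2)
    mu = float(np.sum(w * v) / np.sum(w))
    s = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(mu / s)))
    return mu, s, p


# ---------------------------------------------------------------------------
# marginal analysis
# ---------------------------------------------------------------------------

@dataclass
class MarginalResult:
    focal: str
    per_trait: pd.DataFrame       # trait, tau_star, se, p
    meta_tau_star: float
    meta_se: float
    meta_p: float
    bonferroni_n: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.meta_p < self.alpha / self.bonferroni_n


def _fit_focal(matrix: AnnotationMatrix, focal_names, traits, engine,
               n_blocks, meta_method):
    """Fit each trait on the annotation matrix; meta-analyze tau* of each
    name in ``focal_names``.  Returns {name: (meta_ts, meta_se, meta_p,
    per-trait DataFrame)}."""
    scores = engine.scores_for(matrix)
    out = {}
    per_trait_rows = {name: [] for name in focal_names}
    for ss in traits:
        res = StratifiedLDRegression(ss, scores, n_blocks=n_blocks).fit()
        ts = res.tau_star()
        for name in focal_names:
            per_trait_rows[name].append(
                (ss.trait, ts.loc[name, "tau_star"], ts.loc[name, "se"],
                 ts.loc[name, "p"]))
    for name in focal_names:
        df = pd.DataFrame(per_trait_rows[name],
                          columns=["trait", "tau_star", "se", "p"])
        mu, se, p = meta_analyze(df[["tau_star", "se"]].to_numpy(), meta_method)
        out[name] = (mu, se, p, df)
    return out


def marginal_analysis(focal: Annotation, conditioning: AnnotationMatrix,
                      traits, engine: LDScoreEngine, bonferroni_n: int,
                      *, n_blocks: int = 200, meta: str = "random",
                      alpha: float = 0.05) -> MarginalResult:
    """Estimate the focal annotation's tau* conditional on the conditioning
    set, per trait, and meta-analyze across traits."""
    if focal.name in conditioning:
        raise CollinearityError(
            f"focal annotation {focal.name!r} already in conditioning set")
    matrix = AnnotationMatrix(conditioning.panel,
                              conditioning.annotations + [focal])
    # collinearity of focal with the conditioning columns
    a = conditioning.values()
    if a.shape[1] > 0:
        resid = focal.values - a @ np.linalg.lstsq(a, focal.values, rcond=None)[0]
        denom = float(np.linalg.norm(focal.values - focal.values.mean()))
        if denom == 0 or np.linalg.norm(resid) / denom < 1e-8:
            raise CollinearityError(
                f"focal annotation {focal.name!r} is collinear with the "
                "conditioning set")
    res = _fit_focal(matrix, [focal.name], traits, engine, n_blocks, meta)
    mu, se, p, df = res[focal.name]
    return MarginalResult(focal.name, df, mu, se, p, bonferroni_n, alpha)


# ---------------------------------------------------------------------------
# forward stepwise elimination
# ---------------------------------------------------------------------------

@dataclass
class JointModel:
    retained: list
    stats: pd.DataFrame           # per retained annotation: tau_star, se, p
    trace: list = field(default_factory=list)  # (removed_name, p_at_removal)
    alpha: float = 0.05
    bonferroni_n: int = 1

    @property
    def threshold(self) -> float:
        return self.alpha / self.bonferroni_n


def stepwise_elimination(candidates: AnnotationMatrix,
                         conditioning: AnnotationMatrix, traits,
                         engine: LDScoreEngine, alpha: float,
                         bonferroni_n: int, *, n_blocks: int = 200,
                         meta: str = "random") -> JointModel:
    """Iteratively remove the conditionally least significant candidate.

    Each iteration fits all remaining candidates jointly with the
    conditioning set across traits and meta-analyzes each candidate's tau*;
    if every candidate passes alpha/bonferroni_n the loop stops, otherwise
    the candidate with the largest meta p (ties broken lexicographically by
    name) is removed.  Deterministic and invariant to input order.
    """
    thr = alpha / bonferroni_n
    remaining = sorted(candidates.names)
    trace = []
    stats_df = pd.DataFrame(columns=["tau_star", "se", "p"])
    while remaining:
        matrix = AnnotationMatrix(
            conditioning.panel,
            conditioning.annotations + [candidates[n] for n in remaining])
        res = _fit_focal(matrix, remaining, traits, engine, n_blocks, meta)
        pvals = {n: res[n][2] for n in remaining}
        if all(p < thr for p in pvals.values()):
            stats_df = pd.DataFrame(
                {n: {"tau_star": res[n][0], "se": res[n][1], "p": res[n][2]}
                 for n in remaining}).T.loc[remaining]
            break
        worst = max(remaining, key=lambda n: (pvals[n], _neg_lex(n)))
        trace.append((worst, float(pvals[worst])))
        remaining.remove(worst)
    return JointModel(remaining, stats_df, trace, alpha, bonferroni_n)


def _neg_lex(name: str):
    # ties on p resolved toward the lexicographically largest name being
    # removed last -> invert ordering so max() picks the smallest name
    return tuple(-ord(ch) for ch in name)


def joint_model_to_json(model: JointModel) -> dict:
    return {
        "retained": list(model.retained),
        "stats": {n: {k: float(v) for k, v in row.items()}
                  for n, row in model.stats.iterrows()},
        "trace": [{"removed": n, "p": p} for n, p in model.trace],
        "alpha": model.alpha,
        "bonferroni_n": model.bonferroni_n,
    }
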