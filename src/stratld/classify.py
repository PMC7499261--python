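"""Classification of disease-associated or fine-mapped SNPs.

Positives (e.g. GWAS-catalog or fine-mapped SNPs) are compared against an
equal number of control SNPs matched on minor allele frequency (and
optionally further covariates such as local GC content).  Annotation
feature sets are then evaluated by the cross-validated AUROC of a
supervised learner: the probability that a random positive outranks a
random control (ties counting one half), computed on pooled out-of-fold
scores.  The default cross-validation is leave-one-chromosome-out, which
prevents leakage through LD between nearby train/test SNPs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .annotations import AnnotationMatrix
from .panel import SnpPanel


@dataclass
class LabeledSnpSet:
    positives: np.ndarray
    controls: np.ndarray
    matching: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positives = np.asarray(self.positives, dtype=object)
        self.controls = np.asarray(self.controls, dtype=object)
        if len(self.positives) != len(self.controls):
            raise ValueError("positives and controls must have equal size")
        if set(self.positives) & set(self.controls):
            raise ValueError("positives and controls overlap")


class BinExhaustedError(ValueError):
    pass


def select_matched_controls(positives, panel: SnpPanel, covariates=("maf",),
                            bin_width: float = 0.01, seed: int = 0,
                            extra_covariate_values: dict | None = None
                            ) -> LabeledSnpSet:
    """Sample one control per positive from the same covariate bin, without
    replacement, deterministically for a given seed.

    ``covariates`` defaults to MAF alone; additional covariate names must
    appear in ``extra_covariate_values`` (name -> per-panel-SNP array).
    """
    positives = np.asarray(list(positives), dtype=object)
    pos_idx = panel.index_of(positives)
    pos_set = set(pos_idx.tolist())

    cov_arrays = []
    for cov in covariates:
        if cov == "maf":
            cov_arrays.append(panel.maf)
        elif extra_covariate_values and cov in extra_covariate_values:
            cov_arrays.append(np.asarray(extra_covariate_values[cov], float))
        else:
            raise ValueError(f"unknown matching covariate {cov!r}")
    bins = np.stack([np.floor(c / bin_width).astype(np.int64)
                     for c in cov_arrays], axis=1)

    # candidate pool per bin, excluding positives
    pool: dict = {}
    for i in range(panel.m):
        if i in pos_set:
            continue
        pool.setdefault(tuple(bins[i]), []).append(i)

    need: dict = {}
    for i in pos_idx:
        need[tuple(bins[i])] = need.get(tuple(bins[i]), 0) + 1

    rng = np.random.default_rng(seed)
    chosen: dict = {}
    for b in sorted(need):
        avail = pool.get(b, [])
        if len(avail) < need[b]:
            raise BinExhaustedError(
                f"covariate bin {b} exhausted: need {need[b]} controls, "
                f"only {len(avail)} candidates available "
                f"(shortfall {need[b] - len(avail)})")
        picks = rng.choice(len(avail), size=need[b], replace=False)
        chosen[b] = [avail[j] for j in sorted(picks)]

    controls = []
    used = {b: 0 for b in chosen}
    for i in pos_idx:
        b = tuple(bins[i])
        controls.append(chosen[b][used[b]])
        used[b] += 1
    return LabeledSnpSet(
        positives, panel.snp_id[np.array(controls)],
        matching={"covariates": list(covariates), "bin_width": bin_width,
                  "seed": seed})


def default_learner(seed: int = 0):
    """Conservative gradient-boosted trees (shallow depth, subsampling, L2
    regularisation, fixed rounds) with the sklearn fit/predict_proba API."""
    from xgboost import XGBClassifier
    return XGBClassifier(
        max_depth=3, n_estimators=150, learning_rate=0.1,
        subsample=0.8, colsample_bytree=0.8, min_child_weight=5,
        reg_lambda=1.0, random_state=seed, n_jobs=1,
        tree_method="hist", eval_metric="logloss")


@dataclass
class AurocResult:
    auroc: float
    fold_aurocs: dict
    n_labeled: int
    cv: str
    seed: int
    matching: dict = field(default_factory=dict)


def evaluate_auroc(labeled: LabeledSnpSet, features: AnnotationMatrix,
                   learner=None, cv: str = "loco", seed: int = 0,
                   n_folds: int = 5) -> AurocResult:
    """Cross-validated AUROC of a feature set for positive-vs-control SNPs.

    Out-of-fold predicted scores are pooled across folds before computing
    the AUROC.  Folds are leave-one-chromosome-out (``cv="loco"``) or
    stratified k-fold (``cv="kfold"``).  Single-class folds are skipped
    with a warning; if every fold is skipped an error is raised.
    """
    panel = features.panel
    snp_ids = np.concatenate([labeled.positives, labeled.controls])
    y = np.concatenate([np.ones(len(labeled.positives)),
                        np.zeros(len(labeled.controls))])
    idx = panel.index_of(snp_ids)
    x = features.values()[idx]
    chroms = panel.chrom[idx]

    if learner is None:
        learner = default_learner(seed)
    if cv == "loco":
        folds = [(np.flatnonzero(chroms != c), np.flatnonzero(chroms == c), str(c))
                 for c in pd_unique(chroms)]
    elif cv == "kfold":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(tr, te, f"fold{i}") for i, (tr, te)
                 in enumerate(skf.split(x, y))]
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    oof_scores, oof_y = [], []
    fold_aurocs = {}
    import sklearn.base
    for tr, te, name in folds:
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {name} has a single class; skipped")
            continue
        est = sklearn.base.clone(learner)
        est.fit(x[tr], y[tr])
        s = est.predict_proba(x[te])[:, 1]
        oof_scores.append(s)
        oof_y.append(y[te])
        fold_aurocs[name] = float(roc_auc_score(y[te], s))
    if not oof_scores:
        raise ValueError("all cross-validation folds were skipped")
    scores = np.concatenate(oof_scores)
    yy = np.concatenate(oof_y)
    return AurocResult(float(roc_auc_score(yy, scores)), fold_aurocs,
                       len(y), cv, seed, dict(labeled.matching))


def pairwise_auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Brute-force AUROC: fraction of positive-control pairs where the
    positive outranks the control, ties counting one half."""
    sp = np.asarray(scores_pos, float)[:, None]
    sn = np.asarray(scores_neg, float)[None, :]
    wins = (sp > sn).sum() + 0.5 * (sp == sn).sum()
    return float(wins / (sp.shape[0] * sn.shape[1]))


def pd_unique(values):
    """Order-preserving unique (first-appearance order)."""
    seen = set()
    out = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
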