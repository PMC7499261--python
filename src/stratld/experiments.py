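"""Reference calibration and validation experiments.

Each function here sets up a complete synthetic study at documented
conditions, runs the relevant pipeline end to end, and returns the measured
quantities (coverage fractions, goodness-of-fit p-values, oracle
discrepancies).  They are used by the test suite and by the repository's
acceptance script; thresholds live with the callers, not here.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .annotations import Annotation, AnnotationMatrix, quantile_match
from .classify import (evaluate_auroc, pairwise_auroc,
                       select_matched_controls)
from .conditional import stepwise_elimination
from .io import SummaryStats
from .kmer import (CanonicalKmer, count_kmers_in_windows,
                   enumerate_canonical_kmers, permutation_test,
                   reverse_complement, weighted_kmer_enrichment)
from .ldscores import LDScoreEngine, WindowSpec, stratified_ld_scores
from .sldsc import enrichment, fit_sldsc
from .simulate import (STRONG_EFFECT, AnnotationSpec, SimConfig, default_tau,
                       gen_annotations, gen_panel, gen_sequences,
                       gen_sumstats)


# ---------------------------------------------------------------------------
# S-LDSC parameter recovery and null calibration
# ---------------------------------------------------------------------------

def tau_recovery_experiment(seed: int, m: int = 20_000, n_ref: int = 500,
                            n_gwas: int = 50_000, n_reps: int = 50,
                            n_blocks: int = 200) -> dict:
    """Recovery of known tau by the full gen -> ldscores -> fit pipeline.

    One panel with 5 annotation columns (all-ones base + 2 binary + 2
    probabilistic); n_reps independent summary-statistic draws; reports the
    fraction of (annotation, replicate) pairs whose estimate lies within
    +/-2 jackknife SEs of the truth.
    """
    cfg = SimConfig(m=m, n_ref=n_ref, n_gwas=n_gwas, seed=seed)
    panel, geno = gen_panel(cfg)
    mat = gen_annotations(cfg, panel)
    tau = default_tau(cfg, mat)
    scores = stratified_ld_scores(geno, mat, WindowSpec("kb", 100),
                                  adjusted=False)
    within = 0
    total = 0
    for rep in range(n_reps):
        ss = gen_sumstats(panel, geno, mat, tau, n_gwas, mode="summary",
                          seed=seed + 1000 + rep, ldscores=scores)
        res = fit_sldsc(ss, scores, n_blocks=n_blocks)
        within += int(np.sum(np.abs(res.tau - tau) <= 2 * res.tau_se))
        total += len(tau)
    return {"frac_within_2se": within / total, "n_pairs": total,
            "m": panel.m, "c": mat.c, "n_reps": n_reps}


def null_calibration_experiment(seed: int, m: int = 10_000,
                                n_reps: int = 200,
                                n_blocks: int = 200) -> dict:
    """Null (tau = 0) calibration of tau* p-values and the intercept.

    chi2 are central chi-square(1) draws; reports the KS uniformity p of
    the focal annotation's two-sided tau* p-values across replicates and
    the fraction of intercept estimates within +/-4 SE of 1.

    Because tau*_c is tau_c times a constant held fixed across jackknife
    blocks (sd_c and the full-sample h2), its z-score and two-sided p are
    identical to those of tau_c itself; computing the p-value from tau
    avoids the undefined tau* scale in null replicates where the fitted h2
    is not positive.
    """
    cfg = SimConfig(m=m, n_ref=400, seed=seed, annotations=[
        AnnotationSpec("a_bin", "binary", 0.2),
        AnnotationSpec("a_prob", "probabilistic")])
    panel, geno = gen_panel(cfg)
    mat = gen_annotations(cfg, panel)
    scores = stratified_ld_scores(geno, mat, WindowSpec("kb", 100),
                                  adjusted=False)
    rng = np.random.default_rng(seed + 77)
    pvals = []
    intercept_ok = 0
    for rep in range(n_reps):
        chi2 = rng.standard_normal(panel.m) ** 2
        ss = SummaryStats(panel.snp_id, chi2, 20_000.0, f"null{rep}")
        res = fit_sldsc(ss, scores, n_blocks=n_blocks)
        z = res.tau[1] / res.tau_se[1]          # focal = first real column
        pvals.append(2 * stats.norm.sf(abs(z)))
        intercept_ok += abs(res.intercept - 1.0) <= 4 * res.intercept_se
    ks = stats.kstest(pvals, "uniform")
    return {"tau_star_p_ks_p": float(ks.pvalue),
            "intercept_within_4se_frac": intercept_ok / n_reps,
            "n_reps": n_reps, "m": panel.m}


# ---------------------------------------------------------------------------
# oracle equivalences
# ---------------------------------------------------------------------------

def ldscore_oracle_experiment(seed: int, m: int = 1000) -> dict:
    """Windowed streaming LD scores vs the all-pairs brute force, 1000-SNP
    block panel, both raw and bias-adjusted r2."""
    cfg = SimConfig(m=m, n_ref=300, block_len=25, rho=0.6, n_chroms=2,
                    seed=seed)
    panel, geno = gen_panel(cfg)
    mat = gen_annotations(cfg, panel)
    window = WindowSpec("kb", 50)
    worst = 0.0
    for adjusted in (False, True):
        ours = stratified_ld_scores(geno, mat, window, adjusted=adjusted)
        a = mat.values()
        x = geno.standardized()
        r2 = (x.T @ x / geno.n_samples) ** 2
        if adjusted:
            r2 = r2 - (1 - r2) / (geno.n_samples - 2)
        mask = (panel.chrom[:, None] == panel.chrom[None, :]) & \
            (np.abs(panel.pos[:, None] - panel.pos[None, :]) <= 50_000)
        oracle = (r2 * mask) @ a
        worst = max(worst, float(np.max(np.abs(ours.values - oracle))))
    return {"max_abs_diff": worst, "m": panel.m}


def enrichment_oracle_experiment(seed: int, m: int = 4000) -> dict:
    """Module enrichment vs independent per-SNP summation on a fitted
    5-annotation model."""
    cfg = SimConfig(m=m, n_ref=300, seed=seed)
    panel, geno = gen_panel(cfg)
    mat = gen_annotations(cfg, panel)
    tau = default_tau(cfg, mat)
    scores = stratified_ld_scores(geno, mat, WindowSpec("kb", 100),
                                  adjusted=False)
    ss = gen_sumstats(panel, geno, mat, tau, 20_000, mode="summary",
                      seed=seed + 5, ldscores=scores)
    res = fit_sldsc(ss, scores, n_blocks=100)
    enr = enrichment(res, mat)
    a = mat.values()
    v = a @ res.tau
    h2 = float(v.sum())
    worst = 0.0
    for i, name in enumerate(mat.names):
        if mat.kinds[i] == "continuous":
            continue
        direct = (float(a[:, i] @ v) / h2) / (a[:, i].sum() / panel.m)
        worst = max(worst, abs(float(enr.loc[name, "enrichment"]) - direct))
    return {"max_abs_diff": worst,
            "base_enrichment": float(enr.loc["base", "enrichment"]),
            "m": panel.m}


def auroc_oracle_experiment(seed: int, m: int = 2000,
                            n_pos: int = 200) -> dict:
    """Pooled cross-validated AUROC vs the brute-force pairwise count over
    the same out-of-fold scores."""
    from sklearn.base import clone
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    cfg = SimConfig(m=m, n_ref=60, seed=seed)
    panel, _ = gen_panel(cfg)
    rng = np.random.default_rng(seed + 9)
    positives = panel.snp_id[rng.choice(panel.m, n_pos, replace=False)]
    labeled = select_matched_controls(positives, panel, bin_width=0.05,
                                      seed=seed)
    signal = rng.normal(size=panel.m)
    signal[panel.index_of(labeled.positives)] += 0.7
    feats = AnnotationMatrix(panel, [
        Annotation("sig", signal, "continuous"),
        Annotation("noise", rng.normal(size=panel.m), "continuous")])
    res = evaluate_auroc(labeled, feats, learner=LogisticRegression(),
                         cv="kfold", seed=seed)
    # rebuild the identical out-of-fold scores and apply the pairwise oracle
    snp_ids = np.concatenate([labeled.positives, labeled.controls])
    y = np.concatenate([np.ones(n_pos), np.zeros(n_pos)])
    x = feats.values()[panel.index_of(snp_ids)]
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    for tr, te in skf.split(x, y):
        est = clone(LogisticRegression()).fit(x[tr], y[tr])
        oof[te] = est.predict_proba(x[te])[:, 1]
    oracle = pairwise_auroc(oof[y == 1], oof[y == 0])
    return {"abs_diff": abs(res.auroc - oracle), "auroc": res.auroc,
            "n_labeled": 2 * n_pos}


def exact_identities_experiment(seed: int, m: int = 2000) -> dict:
    """The closed-form identities: base enrichment 1, WKE of a constant
    annotation 1, exact recovery from noiseless chi2, and sorted
    quantile-matched values equal to the sorted reference."""
    cfg = SimConfig(m=m, n_ref=250, seed=seed)
    panel, geno = gen_panel(cfg)
    mat = gen_annotations(cfg, panel)
    tau = default_tau(cfg, mat)
    scores = stratified_ld_scores(geno, mat, WindowSpec("kb", 100),
                                  adjusted=False)
    n = 25_000.0
    chi2 = n * (scores.values @ tau) + 1.0
    res = fit_sldsc(SummaryStats(panel.snp_id, chi2, n, "exact"), scores,
                    weights="uniform", n_blocks=100)
    tau_err = float(np.max(np.abs(res.tau - tau)))
    intercept_err = abs(res.intercept - 1.0)
    base_e = float(res.enrichment().loc["base", "enrichment"])

    rng = np.random.default_rng(seed + 3)
    kappa = rng.poisson(3.0, 500).astype(float)
    kappa[0] += 1  # ensure non-degenerate
    wke_const = weighted_kmer_enrichment(np.full(500, 0.5), kappa)

    src = Annotation("src", rng.normal(size=1500), "continuous")
    ref = Annotation("ref", rng.uniform(0, 1, 1500), "probabilistic")
    matched = quantile_match(src, ref)
    qm_exact = bool(np.array_equal(np.sort(matched.values),
                                   np.sort(ref.values)))
    return {"noiseless_tau_max_err": tau_err,
            "noiseless_intercept_err": float(intercept_err),
            "base_enrichment": base_e,
            "wke_constant_annotation": float(wke_const),
            "quantile_match_sorted_equal": qm_exact}


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------

def kmer_enumeration_experiment() -> dict:
    """Canonical-class counts per k against an independent enumerate-and-
    merge oracle, for k up to 6."""
    counts = {}
    match = True
    for k in range(1, 7):
        ours = {ck.sequence for ck in enumerate_canonical_kmers(k)
                if ck.k == k}
        oracle = {min("".join(t), reverse_complement("".join(t)))
                  for t in itertools.product("ACGT", repeat=k)}
        counts[k] = len(ours)
        match = match and ours == oracle
    return {"counts_per_k": counts, "total_k_le_5": sum(
        counts[k] for k in range(1, 6)), "oracle_match": match}


def permutation_null_experiment(seed: int, n_draws: int = 500,
                                n_snps: int = 250, window_bp: int = 100,
                                n_perm: int = 300) -> dict:
    """Calibration of the Gaussian-fit permutation p-value under the
    effect = 0 sequence generator: annotation and k-mer counts independent.
    Reports the KS uniformity p over one-sided p-values."""
    cfg = SimConfig(m=n_snps, n_ref=30, seed=seed)
    panel, _ = gen_panel(cfg)
    target = CanonicalKmer.from_string("CGCGC")
    rng = np.random.default_rng(seed + 1)
    pvals = []
    for draw in range(n_draws):
        d = Annotation("d", rng.uniform(0, 1, panel.m), "probabilistic")
        seqs = gen_sequences(panel, target, d, effect=0.0,
                             window_bp=window_bp, seed=seed + 10_000 + draw)
        table = count_kmers_in_windows(seqs, [target])
        r = permutation_test(d, table, target, n_perm=n_perm,
                             seed=seed + 20_000 + draw)
        pvals.append(r.p)
    ks = stats.kstest(pvals, "uniform")
    return {"p_ks_p": float(ks.pvalue), "n_draws": n_draws,
            "mean_p": float(np.mean(pvals))}


def permutation_power_experiment(seed: int, n_reps: int = 50,
                                 n_snps: int = 250, window_bp: int = 100,
                                 n_perm: int = 10_000) -> dict:
    """Power under the generator's documented strong planted effect:
    fraction of replicates with one-sided Gaussian p < 1e-4."""
    target = CanonicalKmer.from_string("CGCGC")
    hits = 0
    wkes = []
    for rep in range(n_reps):
        cfg = SimConfig(m=n_snps, n_ref=30, seed=seed + rep)
        panel, _ = gen_panel(cfg)
        rng = np.random.default_rng(seed + 500 + rep)
        d = Annotation("d", rng.uniform(0, 1, panel.m), "probabilistic")
        seqs = gen_sequences(panel, target, d, effect=STRONG_EFFECT,
                             window_bp=window_bp, seed=seed + 900 + rep)
        table = count_kmers_in_windows(seqs, [target])
        r = permutation_test(d, table, target, n_perm=n_perm,
                             seed=seed + 1300 + rep)
        hits += r.p < 1e-4
        wkes.append(r.wke)
    return {"frac_p_below_1e-4": hits / n_reps, "mean_wke": float(
        np.mean(wkes)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# stepwise behaviour
# ---------------------------------------------------------------------------

def _stepwise_setup(seed: int, m: int = 3000):
    cfg = SimConfig(m=m, n_ref=300, block_len=25, rho=0.6, n_chroms=4,
                    seed=seed, annotations=[
                        AnnotationSpec("cond_bin", "binary", 0.2),
                        AnnotationSpec("cond_prob", "probabilistic")])
    panel, geno = gen_panel(cfg)
    conditioning = gen_annotations(cfg, panel)
    engine = LDScoreEngine(geno, WindowSpec("kb", 100), adjusted=False)
    return panel, geno, conditioning, engine


def _stepwise_traits(panel, geno, full, tau, engine, n_traits, seed0):
    scores = engine.scores_for(full)
    return [gen_sumstats(panel, geno, full, tau, 20_000, mode="summary",
                         seed=seed0 + t, ldscores=scores, trait=f"t{t}")
            for t in range(n_traits)]


def stepwise_behaviour_experiment(seed: int, n_null_reps: int = 15) -> dict:
    """Three behavioural checks of forward stepwise elimination:
    a single significant candidate is retained; two noisy copies of one
    signal reduce to a single survivor; all-noise candidate sets end empty.
    """
    panel, geno, conditioning, engine = _stepwise_setup(seed)
    base_tau = [1e-5, 2e-5, 1e-5]

    # single marginally significant candidate -> automatically retained
    rng = np.random.default_rng(seed + 40)
    signal = Annotation("signal", rng.uniform(0, 1, panel.m), "probabilistic")
    cands = AnnotationMatrix(panel, [signal])
    full = conditioning.merged(cands)
    traits = _stepwise_traits(panel, geno, full,
                              np.array(base_tau + [8e-5]), engine, 5,
                              seed + 100)
    single = stepwise_elimination(cands, conditioning, traits, engine,
                                  0.05, 100, n_blocks=100)
    single_retained = single.retained == ["signal"]

    # duplicated signal -> exactly one survivor
    copy = Annotation("signal_copy", np.clip(
        signal.values + rng.normal(0, 0.05, panel.m), 0, 1), "probabilistic")
    cands2 = AnnotationMatrix(panel, [signal, copy])
    full2 = conditioning.merged(cands2)
    traits2 = _stepwise_traits(panel, geno, full2,
                               np.array(base_tau + [6e-5, 0.0]), engine, 5,
                               seed + 200)
    dup = stepwise_elimination(cands2, conditioning, traits2, engine,
                               0.05, 20, n_blocks=100)
    dup_one_survivor = len(dup.retained) == 1

    # all-noise candidates -> empty joint model
    empty = 0
    for rep in range(n_null_reps):
        r = np.random.default_rng(seed + 300 + rep)
        noise = AnnotationMatrix(panel, [
            Annotation(f"noise{j}", r.uniform(0, 1, panel.m),
                       "probabilistic") for j in range(3)])
        fullr = conditioning.merged(noise)
        traitsr = _stepwise_traits(
            panel, geno, fullr, np.array(base_tau + [0.0, 0.0, 0.0]),
            engine, 3, seed + 400 + 10 * rep)
        model = stepwise_elimination(noise, conditioning, traitsr, engine,
                                     0.05, 20, n_blocks=100)
        empty += len(model.retained) == 0
    return {"single_candidate_retained": bool(single_retained),
            "duplicated_signal_one_survivor": bool(dup_one_survivor),
            "noise_empty_frac": empty / n_null_reps,
            "n_null_reps": n_null_reps}
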