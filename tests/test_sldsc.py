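import numpy as np
import pandas as pd
import pytest

from stratld import (Annotation, AnnotationMatrix, SummaryStats, WindowSpec,
                     fit_sldsc, gen_sumstats, stratified_ld_scores)
from stratld.sldsc import (CollinearityError, StratifiedLDRegression,
                           default_weights, enrichment, make_jackknife_blocks)


def noiseless_stats(sim, tau=None, intercept=1.0):
    tau = sim["tau"] if tau is None else tau
    scores = sim["scores"]
    n = 20_000.0
    chi2 = n * (scores.values @ tau) + intercept
    return SummaryStats(sim["panel"].snp_id, chi2, n, "noiseless")


class TestFit:
    def test_noiseless_exact_recovery(self, sim):
        res = fit_sldsc(noiseless_stats(sim), sim["scores"],
                        weights="uniform", n_blocks=50)
        np.testing.assert_allclose(res.tau, sim["tau"], atol=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        # exact recovery holds under default (non-uniform) weights too
        res_w = fit_sldsc(noiseless_stats(sim), sim["scores"], n_blocks=50)
        np.testing.assert_allclose(res_w.tau, sim["tau"], atol=1e-12)

    def test_fixed_intercept_mode(self, sim):
        model = StratifiedLDRegression(noiseless_stats(sim), sim["scores"],
                                       weights="uniform", intercept="fixed",
                                       n_blocks=50)
        res = model.fit()
        np.testing.assert_allclose(res.tau, sim["tau"], atol=1e-12)
        assert res.intercept == 1.0 and res.intercept_se == 0.0

    def test_collinear_design_error(self, sim):
        scores = sim["scores"]
        dup = scores.subset_annotations(["base", "ann1"])
        dup.names = ["base", "ann1", "ann1_copy"]
        dup.values = np.column_stack([dup.values, dup.values[:, 1]])
        dup.annot_sums = np.append(dup.annot_sums, dup.annot_sums[1])
        dup.annot_sds = np.append(dup.annot_sds, dup.annot_sds[1])
        dup.kinds = dup.kinds + [dup.kinds[1]]
        dup.gram = None
        ss = SummaryStats(sim["panel"].snp_id, np.ones(sim["panel"].m),
                          20_000.0, "t")
        with pytest.raises(CollinearityError, match="ann1"):
            fit_sldsc(ss, dup)

    def test_fewer_snps_than_blocks(self, sim):
        ss = noiseless_stats(sim)
        small = SummaryStats(ss.snp_id[:100], ss.chi2[:100], ss.n[:100], "s")
        with pytest.raises(ValueError, match="blocks"):
            fit_sldsc(small, sim["scores"], n_blocks=200)

    def test_blocks_partition(self):
        blocks = make_jackknife_blocks(1003, 10)
        sizes = [len(b) for b in blocks]
        assert sum(sizes) == 1003
        assert max(sizes) - min(sizes) <= 1
        assert np.array_equal(np.concatenate(blocks), np.arange(1003))

    def test_parameter_recovery_within_se(self, sim):
        ss = gen_sumstats(sim["panel"], sim["geno"], sim["mat"], sim["tau"],
                          sim["cfg"].n_gwas, mode="summary", seed=101,
                          ldscores=sim["scores"])
        res = fit_sldsc(ss, sim["scores"], n_blocks=100)
        err = np.abs(res.tau - sim["tau"]) / res.tau_se
        assert np.all(err < 4.0)

    def test_scale_invariance(self, sim):
        # multiplying an annotation by a positive constant divides tau by it
        # and leaves tau* and enrichment unchanged
        lam = 7.0
        mat = sim["mat"]
        scaled = AnnotationMatrix(sim["panel"])
        for a in mat.annotations:
            if a.name == "ann1":
                scaled.add(Annotation("ann1", a.values * lam, "continuous"))
            else:
                scaled.add(a)
        scores_scaled = stratified_ld_scores(
            sim["geno"], scaled, WindowSpec("kb", 100), adjusted=False)
        ss = noiseless_stats(sim)
        base = fit_sldsc(ss, sim["scores"], weights="uniform", n_blocks=50)
        alt = fit_sldsc(ss, scores_scaled, weights="uniform", n_blocks=50)
        i = sim["scores"].names.index("ann1")
        assert alt.tau[i] == pytest.approx(base.tau[i] / lam)
        pd.testing.assert_frame_equal(
            alt.tau_star().loc[["ann1"]], base.tau_star().loc[["ann1"]],
            atol=1e-9, rtol=1e-7)
        # enrichment value is scale-invariant (computed directly since the
        # scaled column is no longer in [0, 1])
        assert alt._enrich_value(alt.tau, i) == \
            pytest.approx(base._enrich_value(base.tau, i), rel=1e-9)


class TestDerivedMetrics:
    def test_base_enrichment_is_one(self, sim):
        res = fit_sldsc(noiseless_stats(sim), sim["scores"],
                        weights="uniform", n_blocks=50)
        enr = res.enrichment()
        assert enr.loc["base", "enrichment"] == pytest.approx(1.0, abs=1e-12)
        assert enr.loc["base", "se"] == pytest.approx(0.0, abs=1e-12)

    def test_single_annotation_all_heritability(self, sim):
        # binary annotation covering 10% of SNPs carrying all heritability
        panel = sim["panel"]
        rng = np.random.default_rng(0)
        member = np.zeros(panel.m)
        member[rng.choice(panel.m, panel.m // 10, replace=False)] = 1.0
        mat = AnnotationMatrix(panel, [
            Annotation("base", np.ones(panel.m), "binary"),
            Annotation("hot", member, "binary")])
        scores = stratified_ld_scores(sim["geno"], mat, WindowSpec("kb", 100),
                                      adjusted=False)
        tau = np.array([0.0, 0.4 / member.sum()])
        chi2 = 20000.0 * (scores.values @ tau) + 1.0
        res = fit_sldsc(SummaryStats(panel.snp_id, chi2, 20000.0, "t"),
                        scores, weights="uniform", n_blocks=50)
        e = res.enrichment().loc["hot", "enrichment"]
        frac = member.mean()
        assert e == pytest.approx(1.0 / frac, rel=1e-6)

    def test_enrichment_brute_force_oracle(self, sim):
        res = fit_sldsc(noiseless_stats(sim), sim["scores"],
                        weights="uniform", n_blocks=50)
        enr = enrichment(res, sim["mat"])
        a = sim["mat"].values()
        v = a @ res.tau            # per-SNP heritability
        h2 = v.sum()
        m = sim["panel"].m
        for i, name in enumerate(sim["mat"].names):
            if sim["mat"].kinds[i] == "continuous":
                continue
            exp = (float(a[:, i] @ v) / h2) / (a[:, i].sum() / m)
            assert abs(enr.loc[name, "enrichment"] - exp) < 1e-10

    def test_tau_star_arithmetic_oracle(self, sim):
        res = fit_sldsc(noiseless_stats(sim), sim["scores"], n_blocks=50)
        ts = res.tau_star()
        a = sim["mat"].values()
        h2 = res.h2_total
        m = sim["panel"].m
        for name in ts.index:
            i = sim["mat"].names.index(name)
            expected = res.tau[i] * a[:, i].std() / (h2 / m)
            assert abs(ts.loc[name, "tau_star"] - expected) < 1e-12

    def test_tau_star_trivial_values(self, sim):
        # tau_c = 0 for every annotation but the base -> tau*_c = 0 exactly
        tau0 = np.zeros(5)
        tau0[0] = sim["tau"][0]
        res = fit_sldsc(noiseless_stats(sim, tau=tau0), sim["scores"],
                        weights="uniform", n_blocks=50)
        np.testing.assert_allclose(res.tau_star()["tau_star"], 0.0,
                                   atol=1e-10)
        # h2 <= 0 (chi2 decreasing in LD score) -> tau* undefined
        chi2_neg = np.maximum(2.0 - 20_000.0 *
                              (sim["scores"].values @ tau0), 0.0)
        neg = fit_sldsc(SummaryStats(sim["panel"].snp_id, chi2_neg,
                                     20_000.0, "neg"),
                        sim["scores"], weights="uniform", n_blocks=50)
        assert neg.h2_total <= 0
        with pytest.raises(ValueError, match="h2"):
            neg.tau_star()
        res2 = fit_sldsc(noiseless_stats(sim), sim["scores"],
                         weights="uniform", n_blocks=50)
        # definitional unit: tau_c sd_c = h2/M  ->  tau* = 1
        i = res2.names.index("ann1")
        sd = res2.annot_sds[i]
        m = res2.m_total
        manual = res2.tau[i] * sd / (res2.h2_total / m)
        assert res2.tau_star().loc["ann1", "tau_star"] == pytest.approx(manual)

    def test_zero_variance_request_errors(self, sim):
        res = fit_sldsc(noiseless_stats(sim), sim["scores"], n_blocks=50)
        with pytest.raises(ValueError, match="zero"):
            res.tau_star(names=["base"])
        assert "base" not in res.tau_star().index

    def test_summary_renders(self, sim):
        res = fit_sldsc(noiseless_stats(sim), sim["scores"], n_blocks=50)
        text = res.summary()
        assert "h2_g" in text and "ann1" in text and "jackknife" in text


class TestWeights:
    def test_uniform_when_no_ld_no_signal(self):
        w = default_weights(np.ones(100), np.ones(100),
                            np.full(100, 1000.0), 10_000, 0.0)
        np.testing.assert_allclose(w, 1.0)

    def test_overcounting_halves_with_doubled_ld(self):
        lw = np.array([2.0, 4.0, 8.0])
        n = np.full(3, 1000.0)
        w1 = 1.0 / np.maximum(lw, 1.0)
        w2 = 1.0 / np.maximum(2 * lw, 1.0)
        np.testing.assert_allclose(w2, w1 / 2)

    def test_weighted_se_not_worse(self, sim):
        # on heteroskedastic synthetic data the default weights should give
        # smaller jackknife SEs than uniform weights for most annotations
        wins = np.zeros(sim["scores"].c)
        reps = 20
        for rep in range(reps):
            ss = gen_sumstats(sim["panel"], sim["geno"], sim["mat"],
                              sim["tau"], sim["cfg"].n_gwas, mode="summary",
                              seed=500 + rep, ldscores=sim["scores"])
            rw = fit_sldsc(ss, sim["scores"], n_blocks=100)
            ru = fit_sldsc(ss, sim["scores"], weights="uniform", n_blocks=100)
            wins += rw.tau_se <= ru.tau_se
        assert np.sum(wins / reps >= 0.5) >= 4  # >= 4 of 5 annotations


class TestCalibration:
    def test_jackknife_close_to_analytic_wls(self, sim):
        ss = gen_sumstats(sim["panel"], sim["geno"], sim["mat"], sim["tau"],
                          sim["cfg"].n_gwas, mode="summary", seed=9,
                          ldscores=sim["scores"])
        res = fit_sldsc(ss, sim["scores"], weights="uniform", n_blocks=100)
        # homoskedastic OLS SE as the analytic reference
        x = np.column_stack([ss.n[:, None] * sim["scores"].values,
                             np.ones(len(ss))])
        resid = ss.chi2 - x @ np.append(res.tau, res.intercept)
        sigma2 = resid @ resid / (len(ss) - x.shape[1])
        cov = sigma2 * np.linalg.inv(x.T @ x)
        analytic = np.sqrt(np.diag(cov)[:sim["scores"].c])
        ratio = res.tau_se / analytic
        assert np.all(ratio > 1 / 1.5) and np.all(ratio < 1.5)

    def test_coverage_of_jackknife_intervals(self, sim):
        reps = 100
        covered = np.zeros(sim["scores"].c)
        intercept_ok = 0
        for rep in range(reps):
            ss = gen_sumstats(sim["panel"], sim["geno"], sim["mat"],
                              sim["tau"], sim["cfg"].n_gwas, mode="summary",
                              seed=1000 + rep, ldscores=sim["scores"])
            res = fit_sldsc(ss, sim["scores"], n_blocks=100)
            covered += (np.abs(res.tau - sim["tau"]) <= 1.96 * res.tau_se)
            intercept_ok += abs(res.intercept - 1.0) <= 4 * res.intercept_se
        assert np.all(covered / reps >= 0.85)
        assert intercept_ok / reps >= 0.95
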