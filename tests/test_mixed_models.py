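"""REML engine, genetic-parameter statistics, adjusted means and Wald tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import clonegs as cg
from clonegs.mixed_models import VarComponent, dummies


def one_way(y, groups):
    Z, levels = dummies(pd.Series(groups))
    comps = [VarComponent("group", Z, levels=levels),
             VarComponent("residual", np.eye(len(y)), levels=None)]
    return cg.fit_reml(np.asarray(y, float), np.ones((len(y), 1)), comps,
                       fixed_names=["mu"])


class TestREMLEngine:
    def test_balanced_one_way_matches_anova(self):
        # groups {1,2} and {3,4}: MSB = 4, MSW = 0.5 -> sigma_g = 1.75
        fit = one_way([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert fit.varcomps["group"] == pytest.approx(1.75, abs=1e-8)
        assert fit.varcomps["residual"] == pytest.approx(0.5, abs=1e-8)

    def test_balanced_anova_random_data(self, rng):
        g = np.repeat(np.arange(8), 5)
        y = rng.normal(0, 1, 40) + rng.normal(0, 1.5, 8)[g]
        fit = one_way(y, [f"g{i}" for i in g])
        gm = np.array([y[g == i].mean() for i in range(8)])
        msb = 5 * np.sum((gm - y.mean()) ** 2) / 7
        msw = sum(np.sum((y[g == i] - gm[i]) ** 2) for i in range(8)) / (40 - 8)
        sg = max((msb - msw) / 5, 0)
        assert fit.varcomps["group"] == pytest.approx(sg, abs=1e-7)
        assert fit.varcomps["residual"] == pytest.approx(msw, abs=1e-7)

    def test_constraint_invariance(self, rng):
        """Reference-level vs sum-to-zero coding leave REML unchanged."""
        g = np.repeat(np.arange(4), 6)
        block = np.tile(np.arange(3), 8)
        y = rng.normal(0, 1, 24) + [0.0, 1.0, 2.0, 0.5][0] + 0.4 * block
        Zg, lg = dummies(pd.Series([f"g{i}" for i in g]))
        comps = lambda: [VarComponent("group", Zg, levels=lg),
                         VarComponent("residual", np.eye(24), levels=None)]
        Xb, _ = dummies(pd.Series([f"b{i}" for i in block]))
        X_ref = np.column_stack([np.ones(24), Xb[:, 1:]])
        X_sum = np.column_stack([np.ones(24), Xb[:, :-1] - Xb[:, -1:]])
        f1 = cg.fit_reml(y, X_ref, comps())
        f2 = cg.fit_reml(y, X_sum, comps())
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        for k in f1.varcomps:
            assert f1.varcomps[k] == pytest.approx(f2.varcomps[k], abs=1e-6)

    def test_recovery_all_components_one(self):
        """Parameters near truth when every variance component is 1."""
        cfg = cg.SimConfig(n_parents=20, progeny_per_cross=10, n_markers=400,
                           n_lgs=4, n_qtl=50, h2=1 / 6, family_frac=1 / 6,
                           clone_frac=1 / 6, bed_frac=1 / 6, plot_frac=1 / 6,
                           seed=21)
        b = cg.simulate_trials(cfg)
        m, _ = cg.qc_filter(b.trial_markers())
        Ag = cg.bend_psd(cg.grm_yang(m, complete_case=False))
        gp = cg.single_trial_analysis(b.trial_data, "trait", A=Ag)
        for name in ("bed", "plot", "additive", "family", "clone", "residual"):
            est = gp.varcomps[name]
            se = gp.fit.varcomp_se[name]
            assert abs(est - 1 / 6) <= max(3 * se, 0.05), name

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError):
            one_way([2.0, 2.0, 2.0, 2.0], list("aabb"))


class TestHeritabilityStats:
    def test_all_ones_r1(self):
        comps = dict(bed=1, plot=1, additive=1, family=1, clone=1, residual=1)
        st = cg.heritability_stats(comps, r=1.0)
        assert st["h2"] == pytest.approx(1 / 6)
        assert st["H2"] == pytest.approx(1 / 2)
        assert st["hc2"] == pytest.approx(1 / 6)

    def test_all_ones_r4_literal(self):
        comps = dict(bed=1, plot=1, additive=1, family=1, clone=1, residual=1)
        st = cg.heritability_stats(comps, r=4.0)
        assert st["hc2"] == pytest.approx(1 / 5.25)

    def test_clone_mean_mode_divides_design_terms(self):
        comps = dict(bed=1, plot=1, additive=1, family=1, clone=1, residual=1)
        st = cg.heritability_stats(comps, r=4.0, hc2_mode="clone_mean")
        assert st["hc2"] == pytest.approx(1 / (0.25 + 0.25 + 3 + 0.25))

    def test_h2_below_H2_and_in_range(self, sim_single, sim_single_grm):
        gp = cg.single_trial_analysis(sim_single.trial_data, "trait",
                                      A=sim_single_grm)
        assert 0.0 <= gp.h2 <= gp.H2 <= 1.0

    def test_recovery_of_awt_like_h2(self, sim_single, sim_single_grm):
        """Simulated target h2 = 0.38 recovered within 2 SE."""
        gp = cg.single_trial_analysis(sim_single.trial_data, "trait",
                                      A=sim_single_grm)
        assert abs(gp.h2 - 0.38) <= 2 * gp.h2_se

    def test_zero_total_variance_raises(self):
        comps = dict(bed=0, plot=0, additive=0, family=0, clone=0, residual=0)
        with pytest.raises(ZeroDivisionError):
            cg.heritability_stats(comps, r=1.0)


class TestCombined:
    def test_type_b_recovery(self, sim_pair):
        m, _ = cg.qc_filter(sim_pair.trial_markers())
        Ag = cg.bend_psd(cg.grm_yang(m, complete_case=False))
        cp = cg.combined_trial_analysis(sim_pair.trial_data, "trait", A=Ag)
        assert abs(cp.type_b - 0.75) <= 2 * cp.type_b_se
        assert 0.0 <= cp.type_b <= 1.0

    def test_requires_two_trials(self, sim_single):
        with pytest.raises(ValueError):
            cg.combined_trial_analysis(sim_single.trial_data, "trait")


class TestAdjustedMeans:
    def two_plot_data(self, values):
        return cg.TrialData(pd.DataFrame({
            "trial": "T1", "rep": ["R1", "R2"], "bed": "B1", "plot": "P1",
            "genotype": "g1", "family": "f1", "trait": values}))

    def test_single_genotype_mean(self):
        am = cg.adjusted_means(self.two_plot_data([10.0, 12.0]), "trait")
        assert am.values["g1"] == pytest.approx(11.0, abs=1e-6)

    def test_balanced_no_design_variance_equals_raw_means(self, rng):
        genos = [f"g{i}" for i in range(10)]
        rows = []
        means = dict(zip(genos, rng.normal(0, 2, 10)))
        for rep in ("R1", "R2", "R3"):
            for g in genos:
                rows.append(("T1", rep, "B1", "P1", g, "f", means[g]
                             + rng.normal(0, 0.3)))
        data = cg.TrialData(pd.DataFrame(
            rows, columns=["trial", "rep", "bed", "plot", "genotype",
                           "family", "trait"]))
        am = cg.adjusted_means(data, "trait")
        raw = data.df.groupby("genotype")["trait"].mean()
        for g in genos:
            assert am.values[g] == pytest.approx(raw[g], abs=0.02)

    def test_matches_direct_gls_solve(self, rng):
        """Unbalanced toy set: adjusted means equal the GLS oracle at the
        fit's converged variance components."""
        rows = []
        bed_eff = {"B1": 1.0, "B2": -1.0}
        genos = [f"g{i}" for i in range(5)]
        truth = dict(zip(genos, rng.normal(0, 1, 5)))
        k = 0
        for g in genos:
            n_obs = 2 if g != "g0" else 3      # unbalanced
            for _ in range(n_obs):
                bed = "B1" if (k % 3) else "B2"
                rows.append(("T1", "R1", bed, f"P{k}", g, "f",
                             truth[g] + bed_eff[bed] + rng.normal(0, 0.2)))
                k += 1
        data = cg.TrialData(pd.DataFrame(
            rows, columns=["trial", "rep", "bed", "plot", "genotype",
                           "family", "trait"]))
        am = cg.adjusted_means(data, "trait")
        df = data.df
        Zg, lg = dummies(df["genotype"])
        Zb, _ = dummies(df["rep"].astype(str) + ":" + df["bed"].astype(str))
        Zr, _ = dummies(df["rep"])
        Zp, _ = dummies(df["rep"].astype(str) + ":" + df["bed"].astype(str)
                        + ":" + df["plot"].astype(str))
        vc = am.fit.varcomps
        V = (vc["bed"] * Zb @ Zb.T + vc["rep"] * Zr @ Zr.T
             + vc["plot"] * Zp @ Zp.T + vc["residual"] * np.eye(len(df)))
        y = df["trait"].to_numpy()
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(Zg.T @ Vi @ Zg, Zg.T @ Vi @ y)
        np.testing.assert_allclose(am.values.loc[lg].to_numpy(), beta,
                                   atol=1e-6)


class TestWald:
    def fit_with_cov(self, rng, beta=0.0, n=40):
        w = rng.normal(0, 1, n)
        y = 1.0 + beta * w + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), w - w.mean()])
        comps = [VarComponent("residual", np.eye(n), levels=None)]
        return cg.fit_reml(y, X, comps, fixed_names=["intercept", "weight"])

    def test_zero_effect_dropped(self):
        fit = cg.REMLResult(
            varcomps={}, varcomp_se={}, varcomp_cov=pd.DataFrame(),
            boundary={}, loglik=0.0, converged=True, n_iter=1,
            beta=pd.Series({"w": 0.0}),
            beta_cov=pd.DataFrame([[1.0]], index=["w"], columns=["w"]),
            blups={})
        res = cg.wald_covariate(fit, "w")
        assert res["wald"] == 0.0 and not res["keep"]

    def test_boundary_z_kept(self):
        se = 0.5
        fit = cg.REMLResult(
            varcomps={}, varcomp_se={}, varcomp_cov=pd.DataFrame(),
            boundary={}, loglik=0.0, converged=True, n_iter=1,
            beta=pd.Series({"w": 1.959963985 * se}),
            beta_cov=pd.DataFrame([[se ** 2]], index=["w"], columns=["w"]),
            blups={})
        res = cg.wald_covariate(fit, "w")
        assert res["p"] == pytest.approx(0.05, abs=1e-6)
        assert res["keep"]

    def test_type_one_error_rate(self, rng):
        """Null covariate rejected at ~5% over repeated simulated fits."""
        n_reps, rejections = 400, 0
        for _ in range(n_reps):
            fit = self.fit_with_cov(rng, beta=0.0)
            rejections += cg.wald_covariate(fit, "weight")["keep"]
        rate = rejections / n_reps
        mc = 2 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= mc + 0.01
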