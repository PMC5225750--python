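"""Folds, predictive ability, prediction accuracy, selection efficiency and
summary tables."""

import numpy as np
import pandas as pd
import pytest

import clonegs as cg

from conftest import random_marker_matrix


class TestFolds:
    def test_even_partition(self):
        ids = [f"g{i}" for i in range(10)]
        folds = cg.make_folds(ids, k=5, seed=1)
        sizes = pd.Series(folds).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]
        assert set(folds) == set(ids)

    def test_uneven_partition(self):
        folds = cg.make_folds([f"g{i}" for i in range(11)], k=5, seed=1)
        sizes = sorted(pd.Series(folds).value_counts(), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_deterministic_under_seed(self):
        ids = [f"g{i}" for i in range(23)]
        assert cg.make_folds(ids, seed=4) == cg.make_folds(ids, seed=4)

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            cg.make_folds(["a", "b"], k=5)


class TestPredictiveAbility:
    def test_perfect_and_inverse(self):
        y = np.array([1.0, 2.0, 3.0])
        assert cg.predictive_ability(y, y) == pytest.approx(1.0)
        assert cg.predictive_ability(y, y[::-1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r = cg.predictive_ability(np.array([1.0, 2, 3, 4]),
                                  np.array([1.0, 1, 2, 2]))
        assert r == pytest.approx(2 / np.sqrt(5), abs=1e-9)   # 0.894...

    def test_affine_invariance(self, rng):
        y = rng.normal(size=20)
        g = rng.normal(size=20)
        r1 = cg.predictive_ability(y, g)
        r2 = cg.predictive_ability(2.5 * y + 3, 0.1 * g - 7)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            cg.predictive_ability(np.ones(5), np.arange(5.0))


class TestPredictionAccuracy:
    def test_sqrt_convention(self):
        pacc, flagged = cg.prediction_accuracy(0.4, 0.25)
        assert pacc == pytest.approx(0.8)
        assert not flagged

    def test_hc2_one_identity(self):
        pacc, _ = cg.prediction_accuracy(0.33, 1.0)
        assert pacc == pytest.approx(0.33)

    def test_flagging_above_one(self):
        pacc, flagged = cg.prediction_accuracy(0.36, 0.16)
        assert pacc == pytest.approx(0.9) and not flagged
        pacc, flagged = cg.prediction_accuracy(0.5, 0.16)
        assert pacc == pytest.approx(1.25) and flagged

    def test_literal_convention_available(self):
        pacc, _ = cg.prediction_accuracy(0.4, 0.25, sqrt_scaling=False)
        assert pacc == pytest.approx(1.6)

    def test_invalid_hc2(self):
        with pytest.raises(ValueError):
            cg.prediction_accuracy(0.4, 0.0)


class TestSelectionEfficiency:
    def series(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_identical_rankings_100(self, rng):
        comp = self.series(rng.normal(size=20))
        assert cg.selection_efficiency(comp, comp, 0.10) == pytest.approx(100.0)

    def test_forced_arithmetic_example(self):
        comp = self.series([10.0, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        inc = self.series([0.0] * 10)
        inc["g2"] = 1.0          # picks the individual with complete value 8
        eff = cg.selection_efficiency(inc, comp, 0.10)
        assert eff == pytest.approx(100 * (8 - 5.5) / (10 - 5.5))

    def test_random_ranking_zero_expectation(self, rng):
        comp = self.series(rng.normal(size=50))
        effs = []
        for _ in range(1000):
            inc = pd.Series(rng.permutation(50).astype(float),
                            index=comp.index)
            effs.append(cg.selection_efficiency(inc, comp, 0.10))
        assert abs(np.mean(effs)) < 5.0

    def test_never_exceeds_100(self, rng):
        comp = self.series(rng.normal(size=30))
        for _ in range(50):
            inc = pd.Series(rng.normal(size=30), index=comp.index)
            assert cg.selection_efficiency(inc, comp, 0.10) <= 100.0 + 1e-9

    def test_whole_population_guard(self, rng):
        comp = self.series(rng.normal(size=10))
        inc = self.series(rng.normal(size=10))
        assert cg.selection_efficiency(inc, comp, 1.0) == 100.0

    def test_empty_selection_rejected(self, rng):
        comp = self.series(rng.normal(size=5))
        with pytest.raises(ValueError):
            cg.selection_efficiency(comp, comp, 0.05)


class TestSummaryTable:
    TABLE = pd.DataFrame(
        {"PBLUP": [0.549], "GBLUP": [0.606], "BayesB": [0.610],
         "BayesC": [0.603], "BRR": [0.601], "BL": [0.594], "RKHS": [0.636]},
        index=["AWT"])

    def test_gs_mean_excludes_pblup(self):
        out = cg.methods_summary_table(self.TABLE)
        assert out.loc["AWT", "Mean"] == pytest.approx(0.608, abs=5e-4)

    def test_single_method_identity(self):
        df = pd.DataFrame({"GBLUP": [0.4, 0.6]}, index=["t1", "t2"])
        out = cg.methods_summary_table(df)
        assert (out.loc[["t1", "t2"], "Mean"]
                == out.loc[["t1", "t2"], "GBLUP"]).all()

    def test_missing_cells_reported(self):
        df = self.TABLE.copy()
        df.loc["AWT", "BL"] = np.nan
        with pytest.raises(ValueError, match="AWT"):
            cg.methods_summary_table(df)


class TestCrossValidate:
    def make_panel(self, rng, n=60, p=150, h2=0.5):
        m = random_marker_matrix(rng, n, p)
        g = (m.dosages - m.dosages.mean(0)) @ rng.normal(0, 1, p)
        g = g / g.std() * np.sqrt(h2)
        y = pd.Series(g + rng.normal(0, np.sqrt(1 - h2), n),
                      index=m.individual_ids)
        return m, y

    def test_pure_noise_pa_near_zero(self, rng):
        m, _ = self.make_panel(rng)
        y = pd.Series(rng.normal(size=60), index=m.individual_ids)
        res = cg.cross_validate(y, m, "GBLUP", k=5, seed=2)
        assert abs(res.pa) < 2 / np.sqrt(60) + 0.15

    def test_heritable_trait_predicted(self, sim_single, sim_single_qc):
        """CV predictive ability is substantial for a heritable trait in a
        structured breeding population (clonal-mean response)."""
        df = sim_single.trial_data.df
        y = df.groupby("genotype")["trait"].mean()
        m = sim_single_qc.subset_individuals(list(y.index))
        res = cg.cross_validate(y, m, "GBLUP", k=5, seed=2, hc2=0.6)
        assert res.pa > 0.3
        assert res.pacc == pytest.approx(res.pa / np.sqrt(0.6))

    def test_deterministic(self, rng):
        m, y = self.make_panel(rng)
        r1 = cg.cross_validate(y, m, "GBLUP", k=4, seed=3)
        r2 = cg.cross_validate(y, m, "GBLUP", k=4, seed=3)
        assert r1.pa == r2.pa

    def test_pooled_and_per_fold_reported(self, rng):
        m, y = self.make_panel(rng)
        res = cg.cross_validate(y, m, "GBLUP", k=5, seed=1)
        assert len(res.per_fold_pa) == 5
        assert res.predictions.notna().all()

    def test_unknown_method(self, rng):
        m, y = self.make_panel(rng, n=30, p=40)
        with pytest.raises((ValueError, RuntimeError)):
            cg.cross_validate(y, m, "SUPERBLUP", seed=0)


class TestTrueValidate:
    def test_self_validation_equals_in_sample_fit(self, rng):
        m = random_marker_matrix(rng, 50, 120)
        g = (m.dosages - m.dosages.mean(0)) @ rng.normal(0, 1, 120)
        y = pd.Series(g / g.std() + rng.normal(0, 1, 50),
                      index=m.individual_ids)
        res = cg.true_validate(y, y, m, "GBLUP", seed=0)
        kern = cg.bend_psd(cg.grm_yang(m, complete_case=False))
        fit = cg.fit_kernel_blup(y, kern)
        expected = cg.predictive_ability(y, fit.gebv.loc[y.index])
        assert res.pa == pytest.approx(expected, abs=1e-9)
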