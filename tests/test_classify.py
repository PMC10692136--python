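"""Penalized smooths, threshold search, bimodality, hysteresis, fate labels."""

import numpy as np
import pandas as pd
import pytest

from lakeews import classify as cl
from lakeews import synthetic_lakes as sl
from tests.conftest import yearly_dataset


class TestPenalizedSmooth:
    x = np.arange(30.0)

    def test_linear_data_shrinks_to_ols_line(self):
        y = 2 * self.x + 1
        fit = cl.fit_penalized_smooth(y, self.x)
        assert fit.edf == pytest.approx(1.0, abs=0.1)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-6)

    def test_constant_data(self):
        fit = cl.fit_penalized_smooth(np.full(30, 3.0), self.x)
        assert fit.edf == pytest.approx(1.0, abs=0.1)
        assert fit.gcv == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_cubic_matches_reference_behaviour(self):
        xc = np.linspace(-1, 1, 30)
        fit = cl.fit_penalized_smooth(xc**3, xc)
        rel_mse = np.mean((fit.fitted - xc**3) ** 2) / np.mean(xc**6)
        assert rel_mse < 2e-3  # rank-6 thin-plate truncation error
        assert fit.edf == pytest.approx(5.0, abs=0.1)

    def test_too_few_observations(self):
        with pytest.raises(cl.InsufficientDataError):
            cl.fit_penalized_smooth(np.ones(5), np.arange(5.0))

    def test_gcv_identity_from_residuals(self):
        rng = np.random.default_rng(2)
        y = np.sin(self.x / 4) + 0.2 * rng.standard_normal(30)
        fit = cl.fit_penalized_smooth(y, self.x)
        rss = float(np.sum((y - fit.fitted) ** 2))
        assert fit.gcv == pytest.approx(
            len(y) * rss / (len(y) - fit.model_dof) ** 2, abs=1e-10
        )

    def test_confidence_band_covers_fitted(self):
        rng = np.random.default_rng(3)
        y = self.x * 0.1 + rng.standard_normal(30)
        fit = cl.fit_penalized_smooth(y, self.x)
        lo, hi = fit.ci_band(self.x)
        assert (lo < fit.fitted).all() and (fit.fitted < hi).all()


class TestThresholdSmooth:
    def test_step_breakpoint_between_observations_10_and_11(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        y = np.r_[np.zeros(10), np.full(10, 5.0)] + 0.01 * rng.standard_normal(20)
        fit = cl.fit_threshold_smooth(y, x)
        assert fit is not None
        assert fit.breakpoint == pytest.approx(9.5)  # midpoint of x10, x11 (1-based)

    def test_linear_series_fails_the_edf_gate(self):
        x = np.arange(30.0)
        assert cl.fit_threshold_smooth(2 * x, x) is None

    def test_each_segment_has_at_least_four_observations(self):
        rng = np.random.default_rng(1)
        x = np.arange(20.0)
        y = np.r_[np.zeros(10), np.full(10, 5.0)] + 0.01 * rng.standard_normal(20)
        fit = cl.fit_threshold_smooth(y, x)
        assert fit.left.n >= 4 and fit.right.n >= 4

    def test_selection_prefers_lower_gcv_and_gam_on_tie(self):
        x = np.arange(30.0)
        gam = cl.fit_penalized_smooth(np.sin(x / 3), x)
        tgam = cl.fit_threshold_smooth(np.sin(x / 3), x, gam=gam)
        assert tgam is not None
        chosen = cl.select_smooth_model(gam, tgam)
        assert chosen is (tgam if tgam.gcv < gam.gcv else gam)
        # exact tie → the continuous model wins (parsimony)
        tied = cl.ThresholdFit(
            breakpoint=10.5, left=gam, right=gam, gcv=gam.gcv, n=30
        )
        assert cl.select_smooth_model(gam, tied) is gam
        assert cl.select_smooth_model(gam, None) is gam


class TestDriverPCA:
    def test_single_varying_driver_gives_its_zscores(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "temperature": np.full(20, 15.0),
                "nitrate": np.full(20, 100.0),
                "phosphorus": rng.uniform(10, 50, 20),
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            res = cl.driver_principal_component(df)
        z = (df["phosphorus"] - df["phosphorus"].mean()) / df["phosphorus"].std()
        np.testing.assert_allclose(res.scores.to_numpy(), z.to_numpy(), atol=1e-10)
        assert res.loadings["phosphorus"] > 0

    def test_two_perfectly_correlated_drivers(self):
        t = np.linspace(0, 1, 15)
        df = pd.DataFrame(
            {"nitrate": 3 * t + 1, "phosphorus": 5 * t - 2}
        )
        res = cl.driver_principal_component(df)
        assert res.variance_explained == pytest.approx(1.0)

    def test_independent_drivers_variance_explained_matches_eigen_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.standard_normal((1000, 3)),
            columns=["temperature", "nitrate", "phosphorus"],
        )
        res = cl.driver_principal_component(df)
        corr = np.corrcoef(
            ((df - df.mean()) / df.std()).to_numpy(), rowvar=False
        )
        oracle = np.linalg.eigvalsh(corr)[-1] / 3.0
        assert res.variance_explained == pytest.approx(oracle, abs=1e-6)
        assert res.variance_explained == pytest.approx(1 / 3, abs=0.05)


class TestBimodality:
    def test_threshold_rule(self):
        # clearly bimodal two-point mixture
        v = np.r_[np.zeros(50), np.ones(50)] + 0.01 * np.random.default_rng(0).standard_normal(100)
        res = cl.bimodality_coefficient(v)
        assert res.bc > 0.5 and res.is_bimodal

    def test_uniform_limit(self):
        v = np.random.default_rng(1).uniform(size=10_000)
        assert cl.bimodality_coefficient(v).bc == pytest.approx(5 / 9, abs=0.02)

    def test_normal_limit(self):
        v = np.random.default_rng(2).standard_normal(10_000)
        assert cl.bimodality_coefficient(v).bc == pytest.approx(1 / 3, abs=0.02)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cl.bimodality_coefficient([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cl.bimodality_coefficient(np.ones(10))


class TestHysteresis:
    def _segment(self, x, y):
        return cl.fit_penalized_smooth(y, x, max_knots=3, min_n=4)

    def test_overlapping_dual_states_detected(self):
        rng = np.random.default_rng(6)
        x_left = np.linspace(-2, 0.5, 15)
        x_right = np.linspace(0, 2, 15)
        left = self._segment(x_left, 10 + 0.1 * rng.standard_normal(15))
        right = self._segment(x_right, 2 + 0.1 * rng.standard_normal(15))
        fit = cl.ThresholdFit(breakpoint=0.0, left=left, right=right, gcv=1.0, n=30)
        assert cl.detect_hysteresis(fit)

    def test_disjoint_driver_ranges_are_not_hysteresis(self):
        rng = np.random.default_rng(7)
        left = self._segment(np.linspace(-2, -0.5, 15), 10 + 0.1 * rng.standard_normal(15))
        right = self._segment(np.linspace(0.5, 2, 15), 2 + 0.1 * rng.standard_normal(15))
        fit = cl.ThresholdFit(breakpoint=0.0, left=left, right=right, gcv=1.0, n=30)
        assert not cl.detect_hysteresis(fit)

    def test_continuous_smooth_is_never_hysteretic(self):
        fit = cl.fit_penalized_smooth(np.sin(np.arange(30.0)), np.arange(30.0))
        assert not cl.detect_hysteresis(fit)

    def test_same_state_in_overlap_is_not_hysteresis(self):
        rng = np.random.default_rng(8)
        left = self._segment(np.linspace(-2, 0.5, 15), 5 + 0.3 * rng.standard_normal(15))
        right = self._segment(np.linspace(0, 2, 15), 5 + 0.3 * rng.standard_normal(15))
        fit = cl.ThresholdFit(breakpoint=0.0, left=left, right=right, gcv=1.0, n=30)
        assert not cl.detect_hysteresis(fit)


class TestFateDecision:
    def test_fold_lake_is_critical(self, fold_lake):
        fate = cl.classify_dataset(yearly_dataset(fold_lake))
        assert fate.mechanism == "critical_transition"
        assert fate.is_critical
        assert fate.transition_time is not None
        truth = fold_lake.truth["phytoplankton"].shift_time
        assert abs(fate.transition_time - truth) <= 3

    def test_stationary_lake_is_no_shift(self, stationary_lake):
        fate = cl.classify_dataset(yearly_dataset(stationary_lake))
        assert fate.mechanism == "no_shift"
        assert not fate.is_critical
        assert fate.transition_time is None

    def test_step_lake_is_abrupt_nonbifurcation(self):
        lake = sl.make_lake("step", sl.MechanismSpec("step_change", seed=11))
        fate = cl.classify_dataset(yearly_dataset(lake))
        assert fate.mechanism == "abrupt_nonbifurcation"

    def test_decision_tree_negative_branch(self):
        x = np.arange(30.0)
        flat = cl.fit_penalized_smooth(0.01 * x, x)  # trendless: edf ≈ 1
        bim = cl.bimodality_coefficient(np.random.default_rng(1).standard_normal(40))
        fate = cl.classify_fate(flat, flat, bim, hysteresis=False)
        assert fate.mechanism == "no_shift"
        assert fate.transition_time is None


class TestTrimming:
    def _matrix(self, n, yearly=True):
        idx = (
            pd.RangeIndex(1975, 1975 + n)
            if yearly
            else pd.period_range("1975-01", periods=n, freq="M")
        )
        return pd.DataFrame({"a": np.arange(n, dtype=float)}, index=idx)

    def _fate(self, t):
        return cl.FateLabel(
            mechanism="critical_transition" if t else "no_shift",
            transition_time=t,
            evidence={},
        )

    def test_no_transition_keeps_85_percent(self):
        res = cl.trim_for_assessment(self._matrix(100), {"p": self._fate(None)})
        assert len(res.matrix) == 85
        assert not res.too_short

    def test_any_transition_truncates_all_series_before_it(self):
        fates = {"zoo": self._fate(1998), "phyto": self._fate(None)}
        res = cl.trim_for_assessment(self._matrix(41), fates)  # 1975..2015
        assert res.matrix.index.max() == 1997

    def test_monthly_series_trimmed_on_year(self):
        fates = {"zoo": self._fate(1976)}
        res = cl.trim_for_assessment(self._matrix(36, yearly=False), fates)
        assert res.matrix.index.max().year == 1975

    def test_early_transition_flags_too_short(self):
        with pytest.warns(UserWarning, match="flagged"):
            res = cl.trim_for_assessment(self._matrix(40), {"p": self._fate(1976)})
        assert res.too_short
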