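"""Window engines, Kendall trend statistics, warning rules."""

import numpy as np
import pandas as pd
import pytest

from lakeews import assessment as asmt
from lakeews.assessment import AssessmentConfig


CFG = AssessmentConfig(n_permutations=200)


class TestRolling:
    def test_window_count_at_half_fraction(self):
        rng = np.random.default_rng(0)
        tr = asmt.rolling_assessment(rng.standard_normal(40), "ar1", CFG)
        assert tr.window_length == 20
        assert len(tr.values) == 21

    def test_constant_series_sd_zero_and_tau_missing(self):
        tr = asmt.rolling_assessment(np.ones(40), "SD", CFG)
        assert np.allclose(tr.values, 0.0)
        assert np.isnan(tr.tau)

    def test_increasing_indicator_forces_tau_one(self):
        # geometric amplitude growth → every window has strictly larger SD
        t = np.arange(60)
        x = (-1.0) ** t * 1.2**t
        tr = asmt.rolling_assessment(x, "SD", CFG)
        assert (np.diff(tr.values) > 0).all()
        assert tr.tau == pytest.approx(1.0)

    def test_too_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="window"):
            asmt.rolling_assessment(np.arange(6.0), "ar1", CFG)

    def test_windowed_values_match_from_scratch_recomputation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        tr = asmt.rolling_assessment(x, "ar1", CFG)
        for i, v in enumerate(tr.values):
            w = x[i : i + tr.window_length]
            oracle = np.corrcoef(w[:-1], w[1:])[0, 1]
            assert v == pytest.approx(oracle, abs=1e-12)

    def test_multivariate_rolling_window(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        tr = asmt.rolling_assessment(X, "meanAR", CFG)
        assert len(tr.values) == 21


class TestTrendTau:
    def test_brute_force_pair_enumeration_fixture(self):
        # pairs of {1,3,2} against time: 2 concordant, 1 discordant → 1/3
        assert asmt.trend_tau([1, 3, 2], [1, 2, 3]) == pytest.approx(1 / 3)

    def test_monotone_limits(self):
        v = np.arange(10.0)
        assert asmt.trend_tau(v[::-1], v) == pytest.approx(-1.0)
        assert asmt.trend_tau(v, v) == pytest.approx(1.0)

    def test_all_ties_is_missing(self):
        assert np.isnan(asmt.trend_tau(np.ones(10), np.arange(10)))

    def test_fewer_than_three_pairs_is_missing(self):
        assert np.isnan(asmt.trend_tau([1.0, 2.0], [0, 1]))


class TestPermutationWarning:
    def test_negative_trend_never_warns(self):
        t = np.arange(60.0)
        x = np.sin(t) * (60 - t)  # shrinking variance → negative tau
        warning, tr = asmt.permutation_warning(x, "SD", CFG)
        assert tr.tau < 0
        assert not warning

    def test_strong_positive_trend_warns(self):
        t = np.arange(60.0)
        x = np.sin(t) * (1 + t)
        warning, tr = asmt.permutation_warning(x, "SD", CFG)
        assert warning

    def test_observed_tau_at_the_percentile_counts_as_warning(self):
        # the decision rule is tau > 0 and tau >= 95th percentile (inclusive)
        t = np.arange(60.0)
        x = np.sin(t) * (1 + t)
        _, tr = asmt.permutation_warning(x, "SD", CFG)
        crit = np.quantile(tr.null_taus[np.isfinite(tr.null_taus)], 0.95)
        assert tr.tau >= crit

    def test_reproducible_null(self):
        x = np.random.default_rng(4).standard_normal(50)
        _, a = asmt.permutation_warning(x, "ar1", CFG)
        _, b = asmt.permutation_warning(x, "ar1", CFG)
        np.testing.assert_array_equal(a.null_taus, b.null_taus)


class TestExpanding:
    def test_hand_standardization_fixture(self):
        # raw indicator {1,2,3} at t=3: (3 − 2)/1 = 1
        raw = np.array([1.0, 2.0, 3.0])
        std = asmt._running_standardize(raw)
        assert std[2] == pytest.approx(1.0, abs=1e-12)

    def test_burn_in_half_start_position(self):
        x = np.random.default_rng(5).standard_normal(40)
        tr = asmt.expanding_assessment(x, "ar1", CFG)
        first = np.where(np.isfinite(tr.standardized))[0][0] + 1  # 1-based
        assert first == 21

    def test_constant_indicator_history_is_all_missing(self):
        tr = asmt.expanding_assessment(np.ones(40), "SD", CFG)
        assert not np.isfinite(tr.standardized).any()

    def test_prefix_causality(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(60)
        full = asmt.expanding_assessment(x, "SD", CFG)
        prefix = asmt.expanding_assessment(x[:50], "SD", CFG)
        # raw values are causal: extending the series never changes them
        np.testing.assert_allclose(full.raw[:50], prefix.raw, atol=1e-12)

    def test_composite_sums_member_standardizations(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40).cumsum()
        comp = asmt.expanding_assessment(x, "ar1+SD", CFG)
        a = asmt.expanding_assessment(x, "ar1", CFG)
        b = asmt.expanding_assessment(x, "SD", CFG)
        both = np.isfinite(comp.standardized)
        np.testing.assert_allclose(
            comp.standardized[both],
            (a.standardized + b.standardized)[both],
            atol=1e-10,
        )


class TestExceedanceWarning:
    def _trace(self, std):
        std = np.asarray(std, dtype=float)
        finite = np.isfinite(std)
        ex = np.zeros(len(std), dtype=bool)
        ex[finite] = std[finite] > 2.0
        return asmt.ExpandingTrace(
            times=np.arange(1, len(std) + 1),
            raw=std,
            standardized=std,
            exceedances=ex,
            burn_in_end=0,
        )

    def test_two_nonconsecutive_exceedances_warn(self):
        std = np.zeros(30)
        std[24], std[30 - 1] = 2.5, 2.5
        assert asmt.exceedance_warning(self._trace(std), CFG)

    def test_single_exceedance_does_not_warn(self):
        std = np.zeros(30)
        std[24] = 2.5
        assert not asmt.exceedance_warning(self._trace(std), CFG)

    def test_all_missing_does_not_warn(self):
        assert not asmt.exceedance_warning(self._trace(np.full(30, np.nan)), CFG)

    def test_consecutive_variant_is_stricter(self):
        std = np.zeros(30)
        std[10], std[20] = 2.5, 2.5
        strict = AssessmentConfig(n_permutations=10, consecutive=True)
        assert not asmt.exceedance_warning(self._trace(std), strict)
        std[11] = 2.5
        assert asmt.exceedance_warning(self._trace(std), strict)


class TestCriticalSlowingDown:
    def test_autocorrelation_rises_before_fold_collapse_not_at_stationarity(self):
        """Median rolling ar1 trend over 50 replicates is positive on
        pre-transition fold segments and centred near zero on stationary
        runs — the qualitative signature the indicators exist to detect."""
        from lakeews import synthetic_lakes as sl

        cfg = AssessmentConfig()
        fold_taus, flat_taus = [], []
        for s in range(50):
            traj = sl.simulate_mechanism(sl.MechanismSpec("fold_bifurcation", seed=s))
            pre = traj.state[traj.time < traj.truth.shift_time]
            fold_taus.append(asmt.rolling_assessment(pre, "ar1", cfg).tau)
            flat = sl.simulate_mechanism(sl.MechanismSpec("stationary", seed=s))
            flat_taus.append(asmt.rolling_assessment(flat.state, "ar1", cfg).tau)
        assert np.median(fold_taus) > 0
        assert abs(np.median(flat_taus)) < 0.2


class TestCommunityAssessment:
    def test_tidy_table_schema_and_single_multivariate_warning(self):
        rng = np.random.default_rng(8)
        idx = pd.RangeIndex(1980, 2020)
        mat = pd.DataFrame(
            rng.uniform(1, 5, (40, 3)), index=idx, columns=["a", "b", "c"]
        )
        table = asmt.assess_community(
            mat,
            lake="L",
            trophic_level="phytoplankton",
            resolution="yearly",
            config=AssessmentConfig(n_permutations=50),
            uni_indicators=("ar1",),
            multi_indicators=("meanAR",),
            composites=(),
        )
        multi = table[table["method"].str.startswith("multi")]
        # exactly one warning row per (indicator, method) at community level
        assert len(multi) == 2
        assert set(multi["series"]) == {"community"}
        uni = table[table["method"] == "uni_rolling"]
        assert len(uni) == 3  # one per genus series
        assert set(table["warning"]) <= {0, 1}
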