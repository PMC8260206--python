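"""Clonality, depth filtering, detection sensitivity and the clock."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import glandphylo as gp
from glandphylo.burden import (
    DepthProfile,
    LowSensitivityError,
    UndefinedClonalityError,
)


class TestClonality:
    def test_uniform_vafs_return_that_vaf(self):
        assert gp.estimate_clonality([0.5, 0.5, 0.5]) == 0.5

    def test_median_of_three(self):
        assert gp.estimate_clonality([0.1, 0.2, 0.3]) == pytest.approx(0.2)

    def test_empty_calls_undefined(self):
        with pytest.raises(UndefinedClonalityError):
            gp.estimate_clonality([])


class TestMinDepth:
    @pytest.mark.parametrize(
        "c,expected",
        [(0.5, 8), (0.1, 40), (1.0, 4), (0.25, 16), (0.2, 20), (1 / 3, 12)],
    )
    def test_depth_rule(self, c, expected):
        """d = ceil(4/c): clonal samples need 8x, polyclonal (c=0.1) 40x."""
        assert gp.min_depth_for_clonality(c) == expected

    @pytest.mark.parametrize("c", [0.0, -0.1, 1.5])
    def test_domain_errors(self, c):
        with pytest.raises(ValueError):
            gp.min_depth_for_clonality(c)


class TestSampleFilter:
    def test_uniform_depth_50_passes_at_c_01(self):
        prof = DepthProfile.from_depths(np.full(200, 50))
        assert gp.sample_passes_filter(prof, 0.1)

    def test_uniform_depth_30_fails_at_c_01(self):
        prof = DepthProfile.from_depths(np.full(200, 30))
        assert not gp.sample_passes_filter(prof, 0.1)

    def test_missing_profile_errors(self):
        with pytest.raises(ValueError):
            gp.sample_passes_filter(None, 0.5)

    def test_cohort_of_409_with_127_low_coverage_keeps_282(self):
        """A cohort where 127 of 409 depth profiles cannot support their
        clonality estimates leaves 282 samples for the regression."""
        profiles = [(DepthProfile.from_depths(np.full(50, 50)), 0.5)] * 282
        profiles += [(DepthProfile.from_depths(np.full(50, 30)), 0.1)] * 127
        passed = sum(gp.sample_passes_filter(p, c) for p, c in profiles)
        assert passed == 282
        assert round(100 * (409 - passed) / 409) == 31


class TestDetectionSensitivity:
    def test_zero_vaf_is_never_detected(self):
        assert gp.detection_sensitivity(30, 0.0) == 0.0

    def test_exact_tail_depth8_vaf_half(self):
        # 1 - sum_{k<=3} C(8,k)/2^8 = 163/256
        assert gp.detection_sensitivity(8, 0.5) == pytest.approx(
            163 / 256, abs=1e-12
        )

    def test_vaf_above_diploid_bound_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            s = gp.detection_sensitivity(100, 0.9)
        assert s == pytest.approx(gp.detection_sensitivity(100, 0.5))

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            gp.detection_sensitivity(-1, 0.2)
        with pytest.raises(ValueError):
            gp.detection_sensitivity(10, -0.2)

    @pytest.mark.parametrize("depth", [4, 11, 25, 42, 60])
    @pytest.mark.parametrize("vaf", [0.05, 0.17, 0.3, 0.5])
    def test_matches_bruteforce_binomial_enumeration(self, depth, vaf):
        tail = sum(
            math.comb(depth, k) * vaf**k * (1 - vaf) ** (depth - k)
            for k in range(4, depth + 1)
        )
        assert gp.detection_sensitivity(depth, vaf) == pytest.approx(
            tail, abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(
        depth=st.integers(min_value=0, max_value=120),
        vaf=st.floats(min_value=0.0, max_value=0.49),
    )
    def test_monotone_in_depth_and_vaf(self, depth, vaf):
        s = gp.detection_sensitivity(depth, vaf)
        assert gp.detection_sensitivity(depth + 1, vaf) >= s - 1e-12
        assert gp.detection_sensitivity(depth, vaf + 0.01) >= s - 1e-12

    def test_fitted_glm_tracks_binomial_tail(self, rng):
        model = gp.train_sensitivity_glm(rng, n=8000)
        grid_d = np.array([15, 25, 35, 45])
        grid_v = np.array([0.1, 0.2, 0.3, 0.45])
        for d in grid_d:
            for v in grid_v:
                exact = gp.detection_sensitivity(int(d), float(v))
                glm = gp.detection_sensitivity(int(d), float(v), model)
                assert abs(glm - exact) < 0.15


class TestCorrectBurden:
    def test_full_sensitivity_is_identity(self):
        assert gp.correct_burden(500, 1.0) == 500

    def test_half_sensitivity_doubles(self):
        assert gp.correct_burden(100, 0.5) == 200

    def test_tiny_sensitivity_refused(self):
        with pytest.raises(LowSensitivityError):
            gp.correct_burden(100, 0.04)

    def test_correction_unbiased_under_censoring(self, rng):
        """Detection censoring then correction recovers the true burden
        within 5% on average (depth ~30, clonality 0.3)."""
        true_n, c = 800, 0.3
        profile = DepthProfile.poisson(30)
        s = gp.sample_sensitivity(profile, c)
        ratios = []
        for _ in range(100):
            depth = rng.poisson(30, size=true_n)
            alt = rng.binomial(depth, c)
            b_r = int((alt >= 4).sum())
            ratios.append(gp.correct_burden(b_r, s) / true_n)
        assert 0.95 <= np.mean(ratios) <= 1.05


class TestClock:
    @staticmethod
    def _table(ages, burdens, donors=None):
        if donors is None:
            donors = [f"D{i % 4}" for i in range(len(ages))]
        return pd.DataFrame({"age": ages, "b_c": burdens, "donor": donors})

    def test_noise_free_line_recovered_exactly(self):
        ages = np.repeat([25.0, 40.0, 55.0, 70.0], 5)
        fit = gp.fit_clock(self._table(ages, 133 + 16.4 * ages))
        assert fit.slope == pytest.approx(16.4, abs=1e-6)
        assert fit.intercept == pytest.approx(133.0, abs=1e-6)

    def test_mixed_model_ci_covers_generative_slope(self):
        cov = 0
        for seed in range(12):
            tab = gp.simulate_clock_cohort(seed=seed)
            fit = gp.fit_clock(tab)
            cov += fit.slope_ci[0] <= 16.4 <= fit.slope_ci[1]
        assert cov >= 10

    def test_permuted_ages_cover_zero(self, rng):
        tab = gp.simulate_clock_cohort(seed=5)
        tab["age"] = rng.permutation(tab["age"].to_numpy())
        fit = gp.fit_clock(tab)
        assert fit.slope_ci[0] <= 0 <= fit.slope_ci[1]

    def test_single_age_is_rank_deficient(self):
        with pytest.raises(gp.burden.ClockError):
            gp.fit_clock(self._table([50.0] * 6, np.arange(6.0)))

    def test_single_donor_falls_back_to_ols(self):
        ages = np.array([30.0, 40, 50, 60, 70, 80])
        with pytest.warns(UserWarning):
            fit = gp.fit_clock(
                self._table(ages, 100 + 10 * ages + np.sin(ages), ["D0"] * 6)
            )
        assert fit.method == "ols"
        assert fit.slope == pytest.approx(10.0, rel=0.05)

    def test_round_trip_identity_on_fitted_values(self):
        ages = np.repeat([25.0, 40.0, 55.0, 70.0], 3)
        fit = gp.fit_clock(self._table(ages, 133 + 16.4 * ages))
        for a in (20.0, 47.3, 71.0):
            back = gp.clock_age(float(fit.predict(a)), fit.intercept, fit.slope)
            assert back.years == pytest.approx(a, abs=1e-6)


class TestClockAge:
    def test_burden_at_intercept_is_age_zero(self):
        assert gp.clock_age(130, 130, 16.4).years == 0.0

    def test_puberty_bracket_from_burden_300_400(self):
        """Burdens of 300-400 mutations map to ages ~10-17 with the
        fitted intercept ~130 and rate 16.4."""
        assert gp.clock_age(300, 130, 16.4).floor == 10
        assert gp.clock_age(400, 130, 16.4).ceil == 17
        assert gp.age_bracket(300, 400, 130, 16.4) == (10, 17)

    def test_negative_age_clamps_with_flag(self):
        res = gp.clock_age(50, 130, 16.4)
        assert res.years == 0.0 and res.clamped

    def test_nonpositive_rate_errors(self):
        with pytest.raises(ValueError):
            gp.clock_age(300, 130, 0.0)


class TestEstimateBurdens:
    def test_reported_calls_and_inclusion(self, rng):
        depth = np.full((200, 2), 40)
        alt = rng.binomial(depth, 0.4)
        vm = gp.VafMatrix.from_arrays(alt, depth)
        tab = gp.estimate_burdens(vm)
        assert set(tab.columns) >= {"sample_id", "b_r", "c", "s", "b_c", "included"}
        assert tab["included"].all()
        assert (tab["b_c"] >= tab["b_r"]).all()
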