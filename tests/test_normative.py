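"""Kernel-regression normative curves and z-scores against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import normdev
from normdev import (
    CohortConfig,
    ExtrapolationError,
    NormativeCurve,
    cv_score,
    fit_normative,
    gaussian_kernel,
    generate_cohort,
    nw_mean,
    nw_sd,
    oracle_curves,
    select_bandwidth,
    zscore,
    zscores_controls_loo,
    zscores_patients,
)
from normdev.normative import select_bandwidths_shared


def brute_nw(x, ages, values, h):
    """Independent scalar-loop NW mean and SD (the textbook double sum)."""
    num = den = 0.0
    for xi, yi in zip(ages, values):
        w = np.exp(-0.5 * ((x - xi) / h) ** 2) / np.sqrt(2 * np.pi)
        num += yi * w
        den += w
    m = num / den
    var = 0.0
    for xi, yi in zip(ages, values):
        w = np.exp(-0.5 * ((x - xi) / h) ** 2) / np.sqrt(2 * np.pi)
        var += (yi - m) ** 2 * w
    return m, np.sqrt(var / den)


def brute_cv(h, ages, values):
    """O(n^2) leave-one-out CV error with explicit loops."""
    n = len(ages)
    total = 0.0
    for j in range(n):
        num = den = 0.0
        for i in range(n):
            if i == j:
                continue
            w = np.exp(-0.5 * ((ages[j] - ages[i]) / h) ** 2)
            num += values[i] * w
            den += w
        pred = num / den if den > 0 else (sum(values) - values[j]) / (n - 1)
        total += (values[j] - pred) ** 2
    return total / n


class TestGaussianKernel:
    def test_closed_form_at_zero(self):
        assert gaussian_kernel(0.0) == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-15)

    def test_symmetry_and_peak(self):
        assert gaussian_kernel(1.0) == gaussian_kernel(-1.0)
        assert gaussian_kernel(0.0) > gaussian_kernel(0.5) > gaussian_kernel(3.0) > 0

    def test_value_at_three(self):
        # frozen from an exact symbolic evaluation of exp(-9/2)/sqrt(2*pi)
        assert gaussian_kernel(3.0) == pytest.approx(0.00443184841194, abs=1e-12)


def curve(ages, values, h):
    return NormativeCurve("roi", "FA", "M", np.asarray(ages, float),
                          np.asarray(values, float), h)


class TestNWEstimator:
    @pytest.mark.parametrize("h", [0.5, 2.0, 25.0])
    def test_midpoint_of_two_points(self, h):
        c = curve([20.0, 40.0], [0.4, 0.6], h)
        assert nw_mean(30.0, c) == pytest.approx(0.5, abs=1e-12)
        assert nw_sd(30.0, c) == pytest.approx(0.1, abs=1e-12)

    def test_huge_bandwidth_gives_global_moments(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(10, 60, 25)
        values = rng.normal(0.5, 0.05, 25)
        c = curve(ages, values, 1e6)
        assert nw_mean(33.0, c) == pytest.approx(values.mean(), abs=1e-8)
        assert nw_sd(33.0, c) == pytest.approx(values.std(ddof=0), rel=1e-6)

    def test_three_point_loop_oracle(self):
        ages, values, h, x = [20.0, 30.0, 50.0], [0.40, 0.50, 0.45], 5.0, 25.0
        m_ref, sd_ref = brute_nw(x, ages, values, h)
        c = curve(ages, values, h)
        assert nw_mean(x, c) == pytest.approx(m_ref, abs=1e-12)
        assert nw_sd(x, c) == pytest.approx(sd_ref, abs=1e-12)

    def test_identical_values_hit_sd_floor(self):
        c = curve([20.0, 30.0, 40.0], [0.5, 0.5, 0.5], 5.0)
        assert nw_sd(25.0, c) == c.sd_floor

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.0, 80.0),
        h=st.floats(0.3, 60.0),
        data=st.lists(
            st.tuples(st.floats(8.0, 70.0), st.floats(0.01, 0.99)),
            min_size=2, max_size=15,
        ),
    )
    def test_mean_convexity_and_sd_floor(self, x, h, data):
        ages, values = map(np.asarray, zip(*data))
        c = curve(ages, values, h)
        m = nw_mean(x, c)
        assert values.min() - 1e-9 <= m <= values.max() + 1e-9
        assert nw_sd(x, c) >= c.sd_floor


class TestCrossValidation:
    def test_constant_values_give_zero_cv(self):
        ages = np.linspace(10, 60, 9)
        for h in (0.5, 5.0, 50.0):
            assert cv_score(h, ages, np.full(9, 0.37)) == pytest.approx(0.0, abs=1e-18)

    def test_two_point_closed_form(self):
        for h in (1.0, 7.0, 30.0):
            assert cv_score(h, [20.0, 40.0], [0.4, 0.6]) == pytest.approx(0.04)

    def test_matches_brute_force_double_loop(self, rng):
        ages = rng.uniform(8, 70, 20)
        values = rng.normal(0.5, 0.03, 20)
        for h in (0.7, 5.0, 18.0):
            assert cv_score(h, ages, values) == pytest.approx(
                brute_cv(h, ages, values), abs=1e-12
            )

    def test_isolated_point_uses_loo_mean_fallback(self):
        ages = np.array([10.0, 11.0, 3000.0])
        values = np.array([0.4, 0.6, 0.9])
        # at h=0.5 the isolated point has zero LOO weight -> fallback term
        expected = ((0.4 - 0.6) ** 2 + (0.6 - 0.4) ** 2 + (0.9 - 0.5) ** 2) / 3
        assert cv_score(0.5, ages, values) == pytest.approx(expected, abs=1e-12)


class TestBandwidthSelection:
    def test_singleton_grid(self, rng):
        ages = rng.uniform(8, 70, 10)
        values = rng.normal(0.5, 0.02, 10)
        assert select_bandwidth(ages, values, [3.7]) == 3.7

    def test_constant_signal_prefers_heaviest_smoothing(self, rng):
        # constant mean + noise: LOO error decreases toward the global mean
        ages = rng.uniform(8, 70, 60)
        values = rng.normal(0.5, 0.02, 60)
        grid = np.array([0.5, 2.0, 10.0, 50.0, 200.0])
        h = select_bandwidth(ages, values, grid)
        assert h >= 50.0

    def test_selected_h_is_argmin_over_grid(self, rng):
        ages = rng.uniform(8, 70, 30)
        values = 0.4 + 0.002 * ages + rng.normal(0, 0.02, 30)
        grid = np.logspace(-0.3, 1.7, 12)
        h = select_bandwidth(ages, values, grid)
        best = min(cv_score(g, ages, values) for g in grid)
        assert cv_score(h, ages, values) == pytest.approx(best, rel=1e-12)

    def test_shared_selection_equals_per_column(self, rng):
        ages = rng.uniform(8, 70, 40)
        V = 0.5 + rng.normal(0, 0.03, (40, 4))
        grid = np.logspace(-0.3, 1.6, 10)
        shared = select_bandwidths_shared(ages, V, grid)
        singles = [select_bandwidth(ages, V[:, j], grid) for j in range(4)]
        np.testing.assert_allclose(shared, singles)


class TestFitNormative:
    def test_empty_stratum_errors(self):
        cfg = CohortConfig(n_controls=20, n_patients=5, seed=2,
                           male_fraction_controls=1.0)
        cohort = generate_cohort(cfg)
        with pytest.raises(ValueError, match="F"):
            fit_normative(cohort, "Fmajor", "FA", "F")

    def test_reference_set_is_sex_matched_controls(self, small_cohort):
        c = fit_normative(small_cohort, "Fminor", "FAt", "F", grid=[5.0])
        ids = small_cohort.ids(group="control", sex="F")
        assert len(c.ref_ages) == len(ids)
        np.testing.assert_allclose(
            np.sort(c.ref_values),
            np.sort(small_cohort.values_for("FAt", "Fminor", ids)),
        )

    def test_stored_bandwidth_matches_selection(self, small_cohort):
        grid = np.array([1.0, 4.0, 16.0])
        c = fit_normative(small_cohort, "Fornix", "FW", "M", grid=grid)
        ids = small_cohort.ids(group="control", sex="M")
        h = select_bandwidth(
            small_cohort.ages_for(ids),
            small_cohort.values_for("FW", "Fornix", ids), grid,
        )
        assert c.bandwidth == h


class TestZScores:
    def test_zero_when_value_on_curve(self):
        c = curve([20.0, 40.0], [0.4, 0.6], 10.0)
        assert zscore(30.0, "M", 0.5, c) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula(self):
        # m=0.5, sd=0.1 at the midpoint of a symmetric two-point reference
        c = curve([20.0, 40.0], [0.4, 0.6], 10.0)
        assert zscore(30.0, "M", 0.3, c) == pytest.approx(-2.0, abs=1e-10)

    def test_truncation_at_ten(self):
        c = curve([20.0, 40.0], [0.4, 0.6], 10.0)
        assert zscore(30.0, "M", -5.0, c) == -10.0
        assert zscore(30.0, "M", 5.0, c) == 10.0

    def test_sex_mismatch_rejected(self):
        c = curve([20.0, 40.0], [0.4, 0.6], 10.0)
        with pytest.raises(ValueError, match="sex"):
            zscore(30.0, "F", 0.5, c)

    def test_patient_matrix_matches_elementwise_zscore(self, small_cohort):
        curves = normdev.fit_all_curves(small_cohort, "FA", grid=[2.0, 8.0, 32.0])
        Z = zscores_patients(small_cohort, curves, "FA")
        pat = small_cohort.subjects[small_cohort.subjects["group"] == "patient"]
        assert Z.shape == (len(pat), 18)
        for _, row in pat.iloc[[0, 7, -1]].iterrows():
            for roi in ("Fmajor", "Tract11", "WM-skeleton"):
                expected = zscore(
                    row["age"], row["sex"],
                    float(small_cohort.measures["FA"].loc[row["id"], roi]),
                    curves[(roi, row["sex"])],
                )
                assert Z.loc[row["id"], roi] == pytest.approx(expected, abs=1e-12)

    def test_loo_small_stratum_matches_refit_oracle(self):
        cfg = CohortConfig(n_controls=14, n_patients=3, seed=6,
                           male_fraction_controls=0.5)
        cohort = generate_cohort(cfg)
        grid = [4.0]
        Z = zscores_controls_loo(cohort, "FA", grid=grid)
        for sex in ("M", "F"):
            ids = list(cohort.ids(group="control", sex=sex))
            ages = cohort.ages_for(pd.Index(ids))
            for held_out in ids:
                others = [i for i in ids if i != held_out]
                ref = NormativeCurve(
                    "Fmajor", "FA", sex,
                    cohort.ages_for(pd.Index(others)),
                    cohort.values_for("FA", "Fmajor", pd.Index(others)),
                    grid[0],
                )
                expected = zscore(
                    float(ages[ids.index(held_out)]), sex,
                    float(cohort.measures["FA"].loc[held_out, "Fmajor"]), ref,
                )
                assert Z.loc[held_out, "Fmajor"] == pytest.approx(expected, abs=1e-10)

    def test_loo_stratum_too_small_errors(self):
        cfg = CohortConfig(n_controls=5, n_patients=3, seed=1,
                           male_fraction_controls=0.4)
        with pytest.raises(ValueError, match="leave-one-out"):
            zscores_controls_loo(generate_cohort(cfg), "FA", grid=[5.0])


def test_parameter_recovery_against_oracle_curves():
    """Fitted normative means track the generative curves over the core ages."""
    cfg = CohortConfig(n_controls=400, n_patients=1, seed=0)
    cohort = generate_cohort(cfg)
    curves = normdev.fit_all_curves(cohort, "FA")
    oc = oracle_curves(cfg)
    ages = np.linspace(16, 55, 100)
    for roi in ("Fmajor", "Tract08", "WM-skeleton"):
        for sex in ("M", "F"):
            m, _ = curves[(roi, sex)].evaluate(ages)
            rmse = np.sqrt(np.mean((m - oc.mean(roi, "FA", sex, ages)) ** 2))
            assert rmse < 0.5 * cfg.noise_sd["FA"]


def test_extrapolation_error_on_degenerate_reference():
    c = curve([np.inf, np.inf], [0.4, 0.6], 1.0)
    with pytest.raises(ExtrapolationError):
        nw_mean(30.0, c)
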