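"""Mean center, standard distance, SD classes and TLL mapping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lesionvario import (
    GridSpec,
    MNI_GRID,
    SyntheticSpec,
    calibrate_tll,
    fit_all,
    make_pattern,
    mean_center,
    sd_quartile_thresholds,
    standard_distance,
    summarize,
    tll_from_sill,
)
from lesionvario.models import VariogramModelFit
from lesionvario.summary import classify_sd


def fits_from(a_values, c_values):
    return [
        VariogramModelFit(axis, a, c, 1.0, 10, True)
        for axis, a, c in zip("XYZ", a_values, c_values)
    ]


class TestMeanCenter:
    def test_identical_points(self):
        assert mean_center([(2.0, -7.0)] * 3) == (2.0, -7.0)

    def test_collinear_points(self):
        assert mean_center([(0, 0), (1, 0), (2, 0)]) == (1.0, 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mean_center([(0, 0), (np.nan, 0), (1, 1)])

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            mean_center([(0, 0), (1, 1)])


class TestStandardDistance:
    def test_coincident_points_give_exact_zero(self):
        assert standard_distance([(1.3, -6.2)] * 3) == 0.0

    def test_hand_computed_case(self):
        # points (0,0),(3,0),(0,0): mean 1, deviations 1,2,1 ->
        # sqrt((1+4+1)/3 + 0) = sqrt(2)
        assert standard_distance([(0, 0), (3, 0), (0, 0)]) == pytest.approx(np.sqrt(2.0))

    @given(
        pts=st.lists(
            st.tuples(st.floats(-10, 10), st.floats(-10, 10)), min_size=3, max_size=3
        ),
        shift=st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
    )
    def test_permutation_and_shift_invariance(self, pts, shift):
        sd = standard_distance(pts)
        assert standard_distance([pts[2], pts[0], pts[1]]) == pytest.approx(sd, abs=1e-12)
        shifted = [(x + shift[0], y + shift[1]) for x, y in pts]
        assert standard_distance(shifted) == pytest.approx(sd, abs=1e-9)

    def test_textbook_oracle_on_random_triples(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            pts = rng.normal(size=(3, 2)) * 3.0
            mx = sum(p[0] for p in pts) / 3.0
            my = sum(p[1] for p in pts) / 3.0
            sd_ref = np.sqrt(
                sum((p[0] - mx) ** 2 for p in pts) / 3.0
                + sum((p[1] - my) ** 2 for p in pts) / 3.0
            )
            assert mean_center(pts) == pytest.approx((mx, my), abs=1e-12)
            assert standard_distance(pts) == pytest.approx(sd_ref, abs=1e-12)


class TestSummarize:
    def test_isotropic_fits_give_zero_sd(self):
        fits = fits_from([4.0, 4.0, 4.0], [0.01, 0.01, 0.01])
        s = summarize(fits, MNI_GRID, "iso", sd_thresholds=(0.05, 0.15, 0.3))
        assert s.sd == 0.0
        assert s.sd_class == 1

    def test_log_space_mean_of_mixed_ranges(self):
        fits = fits_from([2.0, 4.0, 4.0], [0.01, 0.01, 0.01])
        s = summarize(fits, MNI_GRID, "mix")
        assert s.mean_ln_a == pytest.approx((np.log(2) + 2 * np.log(4)) / 3)
        assert s.sd > 0

    def test_non_converged_fit_withheld(self):
        fits = fits_from([2.0, 4.0, 4.0], [0.01, 0.01, 0.01])
        bad = VariogramModelFit("Z", 4.0, 0.01, 0.5, 10, False)
        with pytest.raises(ValueError, match="non-converged"):
            summarize([fits[0], fits[1], bad], MNI_GRID, "bad")

    def test_realistic_patterns_fall_inside_plot_limits(self):
        for seed in (1, 2):
            mask = make_pattern(SyntheticSpec(n_lesions=20, radius_mm=3.0, seed=seed))
            s = summarize(fit_all(mask), mask.grid)
            assert 0.0 <= s.mean_ln_a <= 3.0
            assert -12.0 <= s.mean_ln_c <= -3.0

    def test_anisotropic_sd_exceeds_isotropic_sd(self):
        stretch = tuple(np.array([1.0, 1.0, 3.0]) / 3.0 ** (1.0 / 3.0))
        iso = make_pattern(
            SyntheticSpec(n_lesions=12, radius_mm=3.0, seed=17, snap_centers=True,
                          min_separation_mm=16.5)
        )
        ani = make_pattern(
            SyntheticSpec(n_lesions=12, radius_mm=3.0, stretch=stretch, seed=17,
                          snap_centers=True, min_separation_mm=16.5)
        )
        sd_iso = summarize(fit_all(iso), iso.grid).sd
        sd_ani = summarize(fit_all(ani), ani.grid).sd
        assert sd_ani > sd_iso


class TestTll:
    def test_zero_sill_maps_to_zero(self):
        assert tll_from_sill(0.0, MNI_GRID) == 0.0

    def test_negative_sill_rejected(self):
        with pytest.raises(ValueError):
            tll_from_sill(-0.1, MNI_GRID)

    def test_analytic_estimate_within_fifteen_percent(self):
        mask = make_pattern(SyntheticSpec(n_lesions=40, radius_mm=3.0, seed=23))
        assert mask.lesion_fraction <= 0.01
        c_bar = float(np.mean([f.c for f in fit_all(mask)]))
        est = tll_from_sill(c_bar, mask.grid)
        assert est == pytest.approx(mask.volume_mm3, rel=0.15)

    def test_cohort_calibration_is_nearly_linear(self, cohort_results):
        (slope, intercept), r2 = calibrate_tll(
            [r["mean_sill"] for r in cohort_results],
            [r["volume"] for r in cohort_results],
        )
        assert r2 > 0.99
        assert slope > 0
        # calibrated mapping honors the regression line
        c0 = cohort_results[0]["mean_sill"]
        assert tll_from_sill(c0, MNI_GRID, (slope, intercept)) == pytest.approx(
            slope * c0 + intercept
        )


class TestSdClasses:
    def test_quartile_thresholds_split_batch(self):
        sds = np.linspace(0.0, 0.4, 20)
        t = sd_quartile_thresholds(sds)
        classes = [classify_sd(s, t) for s in sds]
        assert set(classes) == {1, 2, 3, 4}

    def test_class_is_monotone_in_sd(self):
        t = (0.05, 0.15, 0.3)
        assert [classify_sd(s, t) for s in (0.0, 0.1, 0.2, 0.5)] == [1, 2, 3, 4]
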