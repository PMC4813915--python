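"""Scale statistics, ratios, pollution indices and sensitivity fits."""

import numpy as np
import pytest

from ricescale import (delta, find_characteristic_scale, generate_field_plots,
                       normalize_delta, pollution_index, pollution_table,
                       ratio_series, sensitivity_fit, window_stats)
from ricescale.synthetic_data import FieldPlotSample


def stack_of(values, n_days=3):
    """Daily stack repeating a spatial field (plateau conditions)."""
    field = np.asarray(values, dtype=float)
    return np.broadcast_to(field, (n_days,) + field.shape).copy()


class TestWindowStats:
    def test_constant_field(self):
        s = stack_of([[10.0, 10.0]])
        doy = np.array([221, 222, 223])
        assert window_stats(s, doy, (221, 236), "mean") == 10.0
        assert window_stats(s, doy, (221, 236), "sd") == 0.0
        assert window_stats(s, doy, (221, 236), "min") == 10.0
        assert window_stats(s, doy, (221, 236), "max") == 10.0

    def test_two_pixel_population_sd(self):
        s = stack_of([[10.0, 20.0]])
        doy = np.array([221, 222, 223])
        assert window_stats(s, doy, (221, 236), "mean") == 15.0
        assert window_stats(s, doy, (221, 236), "sd") == 5.0

    def test_single_day_window_equals_daily_statistic(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(50, 150, (5, 4, 4))
        doy = np.arange(220, 225)
        assert window_stats(s, doy, (222, 222), "mean") == \
            pytest.approx(s[2].mean(), abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty window"):
            window_stats(stack_of([[1.0]]), np.array([100, 101, 102]),
                         (221, 236))


class TestDelta:
    @pytest.mark.parametrize("wi,w8,expected", [
        (110.0, 100.0, 0.10), (100.0, 100.0, 0.0), (80.0, 100.0, 0.20)])
    def test_absolute_relative_change(self, wi, w8, expected):
        assert delta(wi, w8) == pytest.approx(expected, abs=1e-12)

    def test_zero_base_rejected(self):
        with pytest.raises(ValueError):
            delta(1.0, 0.0)

    def test_normalization(self):
        assert np.allclose(normalize_delta([0, 0.05, 0.10]), [0, 50, 100])
        assert np.allclose(normalize_delta([0.2, 0.2, 0.2]), [100, 100, 100])
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1, 6)
        assert normalize_delta(d).max() == pytest.approx(100.0, abs=1e-12)

    def test_all_zero_profile_maps_to_zero(self):
        assert np.all(normalize_delta([0.0, 0.0, 0.0]) == 0.0)


class TestRatioSeries:
    def test_identical_areas_ratio_one(self):
        s = stack_of([[60.0, 80.0]], n_days=4)
        doy = np.arange(200, 204)
        recs = ratio_series(s, s, doy, 8.0)
        assert all(r.ratio == 1.0 for r in recs)

    def test_hand_ratio(self):
        a = stack_of([[60.0, 60.0]], 1)
        b = stack_of([[70.0, 90.0]], 1)
        recs = ratio_series(a, b, np.array([221]), 8.0)
        assert recs[0].ratio == pytest.approx(0.75)
        assert recs[0].m_pixels == 2 and recs[0].n_pixels == 2

    def test_scale_invariance_for_constant_fields(self):
        # block means preserve constants, so the ratio is identical at
        # any aggregation of spatially constant areas
        a1 = stack_of(np.full((4, 4), 60.0), 2)
        b1 = stack_of(np.full((4, 4), 80.0), 2)
        a2 = stack_of(np.full((2, 2), 60.0), 2)
        b2 = stack_of(np.full((2, 2), 80.0), 2)
        doy = np.array([221, 222])
        r1 = [r.ratio for r in ratio_series(a1, b1, doy, 8.0)]
        r2 = [r.ratio for r in ratio_series(a2, b2, doy, 16.0)]
        assert r1 == r2

    def test_zero_denominator_rejected(self):
        a = stack_of([[1.0]], 1)
        b = stack_of([[0.0]], 1)
        with pytest.raises(ValueError, match="denominator"):
            ratio_series(a, b, np.array([221]), 8.0)


class TestPollution:
    def test_study_area_indices_match_published_table(self):
        df = pollution_table().set_index(["area", "metal"])
        expected = {("A", "Cd"): 2.29, ("A", "Hg"): 2.55, ("A", "Pb"): 1.33,
                    ("A", "As"): 0.95, ("B", "Cd"): 1.57, ("B", "Hg"): 1.45,
                    ("B", "Pb"): 1.08, ("B", "As"): 0.96}
        for key, val in expected.items():
            assert df.loc[key, "index"] == val

    def test_equal_concentration_gives_unit_index(self):
        assert pollution_index(5.0, 5.0, "Cd").index == 1.00

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            pollution_index(1.0, 0.0, "Cd")


def make_samples(n, fn, seed=0):
    rng = np.random.default_rng(seed)
    c = rng.uniform(0.5, 5.0, n)
    return [FieldPlotSample(plot_id=i, lai=1.0, chlorophyll=1.0,
                            wrt_g=max(0.0, fn(c[i], rng)), cd=c[i], hg=0.01,
                            pb=1.0, as_conc=1.0) for i in range(n)]


class TestSensitivityFit:
    def test_exact_quadratic_recovered(self):
        samples = make_samples(50, lambda c, rng: 20 - 1.5 * c - 0.2 * c**2)
        coef, r2 = sensitivity_fit(samples, "wrt", "cd")
        assert np.allclose(coef, [20, -1.5, -0.2], atol=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_no_fit(self):
        samples = make_samples(1000,
                               lambda c, rng: 10 + rng.standard_normal())
        _, r2 = sensitivity_fit(samples, "wrt", "cd")
        assert r2 < 0.05

    def test_biomarker_sensitivity_ordering(self):
        # the generator couples root dry weight most strongly to the
        # metal dose, so its quadratic fit explains the most variance
        plots = generate_field_plots(2000, seed=4)
        _, r2_wrt = sensitivity_fit(plots, "wrt", "cd")
        _, r2_lai = sensitivity_fit(plots, "lai", "cd")
        assert r2_wrt > r2_lai > 0

    def test_rank_deficient_design_rejected(self):
        samples = make_samples(10, lambda c, rng: 1.0)
        for s in samples:
            s.cd = 2.0
        with pytest.raises(ValueError, match="rank-deficient"):
            sensitivity_fit(samples, "wrt", "cd")


class TestCharacteristicScale:
    SCALES = (8, 16, 32, 64, 128, 256)

    def test_turning_point_from_stated_profile(self):
        profile = np.array([0, 5, 8, 8, 24.7, 30])
        out = find_characteristic_scale({"mean": profile}, self.SCALES)
        assert out["turning_point_m"] == 128.0
        assert out["lower_bound_m"] == 64.0
        assert out["upper_bound_m"] == 256.0
        assert not out["flat_profile"]

    def test_flat_profile_flagged(self):
        out = find_characteristic_scale({"mean": np.zeros(6)}, self.SCALES)
        assert out["flat_profile"]
        assert out["turning_point_m"] is None

    def test_ratio_argmin_reported(self):
        out = find_characteristic_scale(
            {"mean": np.array([0, 5, 8, 8, 24.7, 30])}, self.SCALES,
            ratio_by_scale=[0.9, 0.85, 0.8, 0.75, 0.62, 0.8])
        assert out["ratio_argmin_m"] == 128.0
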