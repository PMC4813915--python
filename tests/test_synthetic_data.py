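"""Generators: weather, stress fields, scenes and field plots."""

import numpy as np
import pytest

from ricescale import (TransferFunction, generate_field_plots, generate_meteo,
                       generate_stress_field, retrieve_lai, scene_from_lai)
from ricescale.synthetic_data import (FIELD_MOMENTS, STRESS_PRESETS,
                                      field_plots_frame)


class TestMeteo:
    def test_summer_mean_in_subtropical_range(self):
        m = generate_meteo("zhuzhou", 365, seed=1)
        summer = m.slice_doy(170, 240)
        assert 24.0 <= summer.tmean_c.mean() <= 32.0

    def test_invariants(self):
        m = generate_meteo(seed=3)
        assert np.all(m.tmin_c <= m.tmax_c)
        assert np.all(m.rad_mj >= 0)
        assert np.all(np.diff(m.doy) == 1)

    def test_seeded_determinism(self):
        a, b = generate_meteo(seed=11), generate_meteo(seed=11)
        assert np.array_equal(a.tmin_c, b.tmin_c)
        assert np.array_equal(a.rad_mj, b.rad_mj)
        c = generate_meteo(seed=12)
        assert not np.array_equal(a.tmin_c, c.tmin_c)

    def test_zero_noise_is_exact_sinusoid(self):
        m = generate_meteo(seed=5, noise_sd_t=0.0, noise_sd_rad=0.0)
        dtr = m.tmax_c - m.tmin_c
        assert np.allclose(dtr, dtr[0])
        # second difference of a sampled sinusoid is proportional to itself
        t = m.tmean_c - 17.5
        assert np.allclose(np.diff(t, 2), -t[1:-1] * (
            2 * (1 - np.cos(2 * np.pi / 365))), atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="season not covered"):
            generate_meteo(n_days=200)


class TestStressField:
    def test_severe_preset_mean(self):
        sf = generate_stress_field((160, 160), "severe", seed=7)
        assert abs(sf.fcomb_grid.mean() - 0.72) <= 0.03

    def test_light_preset_mean(self):
        sf = generate_stress_field((64, 64), "light", seed=2)
        assert abs(sf.fcomb_grid.mean() - 0.90) <= 0.03

    @pytest.mark.parametrize("seed", range(100))
    def test_clamp_contract(self, seed):
        level = "severe" if seed % 2 else "light"
        sf = generate_stress_field((8, 8), level, seed=seed)
        for g in (sf.fg_grid, sf.fc_grid):
            assert g.min() >= 0.65 and g.max() <= 1.0
        assert np.array_equal(sf.fcomb_grid, sf.fg_grid * sf.fc_grid)

    def test_zero_variance_constant_field(self):
        sf = generate_stress_field((16, 16), "light", seed=0, sd=0.0)
        mu = np.sqrt(STRESS_PRESETS["light"])
        assert np.all(sf.fg_grid == mu) and np.all(sf.fc_grid == mu)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="unknown area level"):
            generate_stress_field((8, 8), "catastrophic")

    def test_seeded_determinism(self):
        a = generate_stress_field((16, 16), "severe", seed=4)
        b = generate_stress_field((16, 16), "severe", seed=4)
        assert np.array_equal(a.fg_grid, b.fg_grid)


class TestSceneFromLai:
    def test_zero_index_gives_nir_equal_green_plus_blue(self):
        # LAI equal to the transfer intercept maps to GBNDVI 0
        sc = scene_from_lai(np.full((4, 4), 1.682), doy=199)
        assert np.allclose(sc.nir, sc.green + sc.blue)

    def test_hand_inverted_index(self):
        tf = TransferFunction()
        x = tf.inverse(5.012)
        assert abs(x - np.log(5.012 / 1.682) / 3.276) < 1e-12
        assert abs(x - 0.3333) < 5e-4

    def test_noiseless_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        lai = rng.uniform(0.1, 8.0, size=(12, 12))
        back = retrieve_lai(scene_from_lai(lai, doy=199))
        assert np.max(np.abs(back.grid - lai) / lai) < 1e-9

    def test_lai_too_large_for_baselines(self):
        with pytest.raises(ValueError, match="LAI too large"):
            scene_from_lai(np.full((2, 2), 30.0), doy=199)

    def test_lai_below_representable_minimum(self):
        with pytest.raises(ValueError, match="minimum representable"):
            scene_from_lai(np.full((2, 2), 0.01), doy=199)


class TestFieldPlots:
    def test_moment_recovery_at_large_n(self):
        plots = generate_field_plots(10_000, seed=3)
        lai = np.array([p.lai for p in plots])
        wrt = np.array([p.wrt_g for p in plots])
        assert abs(lai.mean() - FIELD_MOMENTS["lai"][0]) <= 0.05
        assert abs(lai.std() - FIELD_MOMENTS["lai"][1]) <= 0.05
        assert abs(wrt.mean() - FIELD_MOMENTS["wrt_g"][0]) <= 0.2
        assert abs(wrt.std() - FIELD_MOMENTS["wrt_g"][1]) <= 0.2

    def test_negative_dose_response_correlation(self):
        plots = generate_field_plots(2000, seed=5)
        cd = np.array([p.cd for p in plots])
        wrt = np.array([p.wrt_g for p in plots])
        assert np.corrcoef(cd, wrt)[0, 1] < 0

    def test_no_noise_no_curvature_gives_identical_biomarkers(self):
        plots = generate_field_plots(50, {"b1": 0.0, "b2": 0.0}, seed=1,
                                     noise_sd=0.0)
        assert len({p.lai for p in plots}) == 1
        assert len({p.wrt_g for p in plots}) == 1

    def test_all_nonnegative_and_deterministic(self):
        a = generate_field_plots(200, seed=9)
        b = generate_field_plots(200, seed=9)
        df = field_plots_frame(a)
        assert (df.drop(columns="plot_id") >= 0).all().all()
        assert field_plots_frame(b).equals(df)

    def test_minimum_plots(self):
        with pytest.raises(ValueError):
            generate_field_plots(1)
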