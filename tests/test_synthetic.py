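"""Scene simulator: signatures, stress dynamics, layout, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from resistweed.indices import compute_index
from resistweed.synthetic import (
    CLASS_IDS,
    DENSITY_SEEDS_PER_M2,
    SceneConfig,
    apply_stress,
    default_signature_table,
    default_trajectory_table,
    simulate_scene,
    simulate_time_series,
    stressed_signature,
)

BANDS = {"B": 0, "G": 1, "R": 2, "RE": 3, "NIR": 4}


def zero_sd(sigs):
    return {k: replace(v, sd_reflectance=(0.0,) * 5) for k, v in sigs.items()}


class TestSignatures:
    def test_soil_lacks_red_edge_jump(self):
        soil = default_signature_table()["soil"]
        assert soil.mean[BANDS["NIR"]] / soil.mean[BANDS["R"]] < 2

    def test_vegetation_has_red_edge_jump(self):
        sigs = default_signature_table()
        for name, sig in sigs.items():
            if name == "soil":
                continue
            assert sig.mean[BANDS["NIR"]] / sig.mean[BANDS["R"]] > 3, name

    @pytest.mark.parametrize("species", ["barnyardgrass", "velvetleaf"])
    def test_resistant_biotype_band_ordering(self, species):
        sigs = default_signature_table()
        s, r = sigs[f"{species}_S"].mean, sigs[f"{species}_R"].mean
        for b in ("B", "G", "R"):
            assert r[BANDS[b]] <= s[BANDS[b]]
        for b in ("RE", "NIR"):
            assert r[BANDS[b]] >= s[BANDS[b]]

    def test_resistant_re_nir_greater_under_early_stress(self):
        for biotype in ("S", "R"):
            pass
        s2 = stressed_signature("barnyardgrass_S", 2)
        r2 = stressed_signature("barnyardgrass_R", 2)
        assert r2.mean[BANDS["RE"]] > s2.mean[BANDS["RE"]]
        assert r2.mean[BANDS["NIR"]] > s2.mean[BANDS["NIR"]]

    def test_velvetleaf_brighter_than_barnyardgrass_in_visible(self):
        sigs = default_signature_table()
        for suffix in ("S", "R"):
            vl = sigs[f"velvetleaf_{suffix}"].mean
            bg = sigs[f"barnyardgrass_{suffix}"].mean
            for b in ("B", "G", "R"):
                assert vl[BANDS[b]] > bg[BANDS[b]]

    def test_out_of_range_signature_rejected(self):
        from resistweed.synthetic import SpectralSignature

        with pytest.raises(ValueError):
            SpectralSignature("x", (1.2, 0.1, 0.1, 0.1, 0.1), (0.0,) * 5)


class TestStress:
    def test_day_zero_is_identity(self):
        sigs = default_signature_table()
        trajs = default_trajectory_table()
        out = apply_stress(sigs["barnyardgrass_S"], trajs["barnyardgrass_S"], 0)
        assert np.allclose(out.mean, sigs["barnyardgrass_S"].mean)

    def test_susceptible_nir_r_ratio_degrades_by_day_14(self):
        day0 = stressed_signature("barnyardgrass_S", 0)
        day14 = stressed_signature("barnyardgrass_S", 14)
        ratio = lambda s: s.mean[BANDS["NIR"]] / s.mean[BANDS["R"]]
        assert ratio(day14) < ratio(day0)

    def test_resistant_recovers_after_watershed(self):
        day5 = stressed_signature("barnyardgrass_R", 5)
        day14 = stressed_signature("barnyardgrass_R", 14)
        ratio = lambda s: s.mean[BANDS["NIR"]] / s.mean[BANDS["R"]]
        assert ratio(day14) >= ratio(day5)

    def test_susceptible_monotone_degradation(self):
        traj = default_trajectory_table()["barnyardgrass_S"]
        fractions = [traj.stress_fraction(d) for d in range(15)]
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_resistant_rate_strictly_smaller_and_reverses(self):
        trajs = default_trajectory_table()
        assert trajs["barnyardgrass_R"].decline_rate < trajs["barnyardgrass_S"].decline_rate
        r = trajs["barnyardgrass_R"]
        peak = r.stress_fraction(r.recovery_day)
        assert r.stress_fraction(r.recovery_day + 3) < peak

    def test_biotype_divergence_non_decreasing_days_0_to_8(self):
        trajs = default_trajectory_table()
        for species in ("barnyardgrass", "velvetleaf"):
            div = [
                trajs[f"{species}_S"].stress_fraction(d)
                - trajs[f"{species}_R"].stress_fraction(d)
                for d in range(9)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(div, div[1:])), species

    def test_unknown_class_is_named_in_error(self):
        with pytest.raises(KeyError, match="ragweed"):
            stressed_signature("ragweed", 2)


class TestSimulateScene:
    def test_same_seed_bit_identical(self, small_scene_config):
        ms1, rgb1, t1 = simulate_scene(small_scene_config)
        ms2, rgb2, t2 = simulate_scene(small_scene_config)
        assert np.array_equal(ms1.values, ms2.values)
        assert np.array_equal(rgb1.values, rgb2.values)
        assert np.array_equal(t1.class_mask, t2.class_mask)
        assert t1.block_table.equals(t2.block_table)

    def test_different_seed_differs(self, small_scene_config):
        other = replace(small_scene_config, seed=small_scene_config.seed + 1)
        ms1, _, _ = simulate_scene(small_scene_config)
        ms2, _, _ = simulate_scene(other)
        assert not np.array_equal(ms1.values, ms2.values)

    def test_geometry_contract(self, small_scene_config):
        ms, rgb, truth = simulate_scene(small_scene_config)
        assert ms.n_bands == 5 and rgb.n_bands == 3
        assert truth.class_mask.shape == ms.shape
        ratio = small_scene_config.ms_gsd / small_scene_config.rgb_gsd
        assert rgb.shape[0] == pytest.approx(ms.shape[0] * ratio, abs=1)
        assert rgb.shape[1] == pytest.approx(ms.shape[1] * ratio, abs=1)
        # shared world origin
        assert ms.transform.c == rgb.transform.c
        assert ms.transform.f == pytest.approx(rgb.transform.f, abs=ms.gsd)

    def test_weed_count_matches_density_within_poisson_tolerance(self):
        cfg = SceneConfig(seed=42, density="low", plot_width_m=5.0,
                          plot_height_m=3.0, ms_gsd=2.0, rgb_gsd=1.0)
        _, _, truth = simulate_scene(cfg)
        expected = DENSITY_SEEDS_PER_M2["low"] * 15.0
        n = int(truth.block_table["n_plants"].sum())
        assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_noiseless_single_class_pixels_equal_mean(self):
        cfg = SceneConfig(
            seed=0, density="low", plot_width_m=2.0, plot_height_m=2.0,
            ms_gsd=2.0, rgb_gsd=1.0, noise_sd=0.0, brightness_cv=0.0,
            block_brightness_cv=0.0, rgb_brightness_cv=0.0, rgb_chroma_cv=0.0,
            signatures=zero_sd(default_signature_table()),
        )
        ms, _, truth = simulate_scene(cfg, day=0)
        soil = default_signature_table()["soil"].mean
        soil_pixels = truth.class_mask == CLASS_IDS["soil"]
        for b in range(5):
            vals = ms.values[b][soil_pixels]
            assert np.allclose(vals, soil[b])

    def test_distributional_fidelity_of_class_means(self):
        cfg = SceneConfig(seed=9, density="moderate", plot_width_m=3.0,
                          plot_height_m=3.0, ms_gsd=1.0, rgb_gsd=0.5,
                          brightness_cv=0.0, block_brightness_cv=0.0)
        ms, _, truth = simulate_scene(cfg, day=0)
        soil_sig = default_signature_table()["soil"]
        sel = truth.class_mask == CLASS_IDS["soil"]
        n = sel.sum()
        assert n >= 10_000
        for b in range(5):
            sd = np.hypot(soil_sig.sd[b], cfg.noise_sd)
            sample_mean = ms.values[b][sel].mean()
            assert abs(sample_mean - soil_sig.mean[b]) < 3 * sd / np.sqrt(n)

    def test_resistance_mask_only_on_weed_pixels(self, small_scene_config):
        _, _, truth = simulate_scene(small_scene_config)
        weed_ids = [CLASS_IDS[c] for c in
                    ("barnyardgrass_S", "barnyardgrass_R", "velvetleaf_S", "velvetleaf_R")]
        on_weed = np.isin(truth.class_mask, weed_ids)
        assert np.all(truth.resistance_mask[~on_weed] == -1)
        assert np.all(truth.resistance_mask[on_weed] >= 0)

    def test_block_death_fractions_in_unit_interval(self, small_scene_config):
        _, _, truth = simulate_scene(small_scene_config)
        assert truth.block_table["death_fraction_day14"].between(0, 1).all()

    def test_too_small_extent_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_scene(SceneConfig(plot_width_m=0.05, plot_height_m=0.05,
                                       ms_gsd=2.0, rgb_gsd=1.0))

    def test_wsri_biotype_ordering_all_days_1_to_8(self):
        cfg = SceneConfig(seed=21, density="moderate", plot_width_m=3.0,
                          plot_height_m=2.0, ms_gsd=2.0, rgb_gsd=1.0)
        for day in (1, 2, 4, 5, 6, 7, 8):
            ms, _, truth = simulate_scene(cfg, day=day)
            wsri = compute_index(ms, "WSRI").values[0]
            r = wsri[truth.resistance_mask == 1]
            s = wsri[truth.resistance_mask == 0]
            assert np.nanmean(r) > np.nanmean(s), f"day {day}"


class TestTimeSeries:
    def test_singleton_equals_single_scene(self, small_scene_config):
        series = simulate_time_series(small_scene_config, [0])
        ms_direct, _, _ = simulate_scene(small_scene_config, day=0)
        assert np.array_equal(series[0][0].values, ms_direct.values)

    def test_layout_fixed_spectra_evolve(self, small_scene_config):
        series = simulate_time_series(small_scene_config, [2, 8])
        (_, _, t2), (_, _, t8) = series
        assert np.array_equal(t2.class_mask, t8.class_mask)
        assert not np.array_equal(series[0][0].values, series[1][0].values)

    def test_duplicate_days_rejected(self, small_scene_config):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_time_series(small_scene_config, [2, 2])

    def test_off_schedule_day_rejected(self, small_scene_config):
        with pytest.raises(ValueError, match="schedule"):
            simulate_time_series(small_scene_config, [3])

    def test_susceptible_ndvi_declines_resistant_less(self, small_scene_config):
        series = simulate_time_series(small_scene_config, [2, 8])
        declines = {}
        for biotype_code, name in ((0, "S"), (1, "R")):
            means = []
            for ms, _, truth in series:
                ndvi = compute_index(ms, "NDVI").values[0]
                means.append(np.nanmean(ndvi[truth.resistance_mask == biotype_code]))
            declines[name] = means[0] - means[1]
        assert declines["S"] > 0
        assert declines["R"] < declines["S"]
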