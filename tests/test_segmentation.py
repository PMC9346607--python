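"""Otsu thresholding, GLCM textures, species SVM, confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from resistweed.indices import compute_index
from resistweed.segmentation import (
    TEXTURE_FEATURE_NAMES,
    classify_species,
    confusion,
    otsu_threshold,
    pixel_feature_table,
    texture_features,
    train_species_svm,
    vegetation_mask,
)
from resistweed.synthetic import CLASS_IDS, SceneConfig, simulate_scene


def brute_force_otsu(values, nbins=256):
    """Independent exhaustive scan of between-class variance over bins.

    Returns (threshold, variance_at_threshold); ties keep the lower cut.
    """
    values = np.asarray(values, float)
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = None, -1.0
    variances = np.full(nbins - 1, -np.inf)
    for t in range(nbins - 1):
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2 / (w0 + w1) ** 2
        variances[t] = v
        if v > best_v:  # strict improvement keeps the lower cut on ties
            best_v, best_t = v, t
    return centers[best_t], best_v, centers, variances


class TestOtsu:
    def test_bimodal_threshold_lies_between_modes(self, rng):
        sample = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
        thr = otsu_threshold(sample)
        assert 0.2 < thr < 0.8

    def test_equals_brute_force_on_random_samples(self, rng):
        for _ in range(100):
            kind = rng.integers(0, 3)
            if kind == 0:
                sample = rng.normal(0.5, 0.2, 400)
            elif kind == 1:
                sample = np.concatenate(
                    [rng.normal(0.2, 0.05, 300), rng.normal(0.7, 0.1, 200)]
                )
            else:
                sample = rng.uniform(-2, 5, 300)
            ours = otsu_threshold(sample)
            thr_bf, v_max, centers, variances = brute_force_otsu(sample)
            v_ours = variances[int(np.argmin(np.abs(centers[:-1] - ours)))]
            # the returned cut achieves the exhaustive-scan maximum, and
            # exact ties resolve toward the lower threshold
            assert v_ours == pytest.approx(v_max, rel=1e-9, abs=1e-15)
            binw = centers[1] - centers[0]
            assert ours <= thr_bf + binw / 2

    def test_agrees_with_reference_implementation(self, rng):
        sample = np.concatenate([rng.normal(0.2, 0.05, 500), rng.normal(0.75, 0.08, 400)])
        ours = otsu_threshold(sample)
        ref = skimage_otsu(sample, nbins=256)
        # same histogram granularity: thresholds within one bin width
        binw = (sample.max() - sample.min()) / 256
        assert abs(ours - ref) <= binw + 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full(100, 0.4))

    def test_scene_soil_vegetation_split(self, small_scene_config):
        from dataclasses import replace as dreplace

        from resistweed.synthetic import default_signature_table

        sigs = {k: dreplace(v, sd_reflectance=(0.0,) * 5)
                for k, v in default_signature_table().items()}
        cfg = SceneConfig(
            seed=3, density="moderate", plot_width_m=2.0, plot_height_m=2.0,
            ms_gsd=2.0, rgb_gsd=1.0, noise_sd=0.0, brightness_cv=0.0,
            block_brightness_cv=0.0, rgb_brightness_cv=0.0, rgb_chroma_cv=0.0,
            signatures=sigs,
        )
        ms, _, truth = simulate_scene(cfg, day=0)
        mask = vegetation_mask(ms, "NDVI")
        veg_truth = truth.class_mask > 0
        agreement = (mask == veg_truth).mean()
        assert agreement > 0.99

    def test_vegetation_recall_on_noiseless_scene(self, small_scene_config):
        from dataclasses import replace as dreplace

        from resistweed.synthetic import default_signature_table

        sigs = {k: dreplace(v, sd_reflectance=(0.0,) * 5)
                for k, v in default_signature_table().items()}
        cfg = SceneConfig(
            seed=4, density="low", plot_width_m=2.0, plot_height_m=2.0,
            ms_gsd=2.0, rgb_gsd=1.0, noise_sd=0.0, brightness_cv=0.0,
            block_brightness_cv=0.0, signatures=sigs,
        )
        ms, _, truth = simulate_scene(cfg, day=0)
        mask = vegetation_mask(ms, "NDVI")
        veg_truth = truth.class_mask > 0
        recall = mask[veg_truth].mean()
        assert recall > 0.95

    def test_huge_offset_empties_mask(self, reflectance_grid):
        mask = vegetation_mask(reflectance_grid, "NDVI", manual_offset=100.0)
        assert not mask.any()

    def test_mask_and_complement_partition_valid_pixels(self, reflectance_grid):
        mask = vegetation_mask(reflectance_grid, "NDVI", manual_offset=0.0)
        index = compute_index(reflectance_grid, "NDVI").values[0]
        valid = ~np.isnan(index)
        thr_mask_or_complement = mask | (~mask)
        assert np.all(thr_mask_or_complement[valid])


class TestTexture:
    def test_constant_window_degenerate(self):
        f = texture_features(np.full((5, 5), 0.3))
        feats = dict(zip(TEXTURE_FEATURE_NAMES, f))
        assert feats["glcm_contrast"] == pytest.approx(0.0)
        assert feats["glcm_energy"] == pytest.approx(1.0)
        assert feats["glcm_entropy"] == pytest.approx(0.0, abs=1e-9)

    def test_checkerboard_contrast(self):
        # hand enumeration: every axial neighbor pair differs (contrast 1
        # at 0 and 90 degrees), every diagonal pair matches (contrast 0),
        # so the 4-direction average is exactly 0.5
        cb = np.indices((5, 5)).sum(axis=0) % 2
        cb_contrast = texture_features(cb.astype(float), levels=2)[0]
        assert cb_contrast == pytest.approx(0.5)
        # and the checkerboard is the maximal binary pattern for the
        # axial (0/90 degree) directions
        import skimage.feature as skf

        def axial_contrast(img):
            glcm = skf.graycomatrix(img.astype(np.uint8), [1],
                                    [0.0, np.pi / 2], levels=2,
                                    symmetric=True, normed=True)
            return float(skf.graycoprops(glcm, "contrast").mean())

        cb_axial = axial_contrast(cb)
        rng = np.random.default_rng(0)
        for _ in range(200):
            pattern = rng.integers(0, 2, (5, 5))
            if pattern.min() == pattern.max():
                continue
            assert axial_contrast(pattern) <= cb_axial + 1e-12

    def test_rotation_invariance_of_direction_average(self, rng):
        w = rng.uniform(0, 1, (7, 7))
        f0 = texture_features(w)
        f90 = texture_features(np.rot90(w))
        assert np.allclose(f0, f90, atol=1e-10)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            texture_features(np.ones((2, 5)))


class TestSpeciesSVM:
    def separable_table(self, n=30):
        rng = np.random.default_rng(0)
        rows = []
        for label, center in (("maize", 0.2), ("barnyardgrass", 0.5), ("velvetleaf", 0.8)):
            for _ in range(n):
                feats = rng.normal(center, 0.02, 5)
                rows.append(dict(
                    B=feats[0], G=feats[1], R=feats[2], RE=feats[3], NIR=feats[4],
                    glcm_contrast=center, glcm_homogeneity=0.5, glcm_energy=0.5,
                    glcm_entropy=1.0, label=label,
                ))
        return pd.DataFrame(rows)

    def test_separable_training_is_perfect(self):
        table = self.separable_table()
        model = train_species_svm(table, seed=0)
        pred = classify_species(model, table)
        assert (pred == table["label"].to_numpy()).mean() == 1.0

    def test_single_class_rejected(self):
        table = self.separable_table()
        with pytest.raises(ValueError, match="2 classes"):
            train_species_svm(table[table.label == "maize"])

    def test_scene_species_accuracy(self):
        cfg = SceneConfig(seed=5, density="moderate", plot_width_m=2.5,
                          plot_height_m=2.5, ms_gsd=2.0, rgb_gsd=1.0)
        ms, _, truth = simulate_scene(cfg, day=0)
        species_of = {
            CLASS_IDS["maize"]: "maize",
            CLASS_IDS["barnyardgrass_S"]: "barnyardgrass",
            CLASS_IDS["barnyardgrass_R"]: "barnyardgrass",
            CLASS_IDS["velvetleaf_S"]: "velvetleaf",
            CLASS_IDS["velvetleaf_R"]: "velvetleaf",
        }
        rows, cols = np.where(np.isin(truth.class_mask, list(species_of)))
        rng = np.random.default_rng(2)
        take = rng.choice(rows.size, 900, replace=False)
        rr, cc = rows[take], cols[take]
        labels = np.array([species_of[truth.class_mask[r, c]] for r, c in zip(rr, cc)])
        table = pixel_feature_table(ms, rr, cc, labels)
        model = train_species_svm(table.iloc[:450], seed=0)
        pred = classify_species(model, table.iloc[450:])
        acc = (pred == labels[450:]).mean()
        assert acc >= 0.90

    def test_label_shuffle_gives_chance_accuracy(self):
        table = self.separable_table(n=60)
        rng = np.random.default_rng(1)
        shuffled = table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        model = train_species_svm(shuffled.iloc[::2], seed=0)
        pred = classify_species(model, shuffled.iloc[1::2])
        acc = (pred == shuffled.iloc[1::2]["label"].to_numpy()).mean()
        assert acc < 0.55  # three balanced classes: chance is 1/3


class TestConfusion:
    def test_perfect_prediction(self):
        y = ["a", "b", "a", "c"]
        rep = confusion(y, y)
        assert rep.overall_accuracy == 1.0
        assert np.trace(rep.matrix.to_numpy()) == 4

    def test_single_prediction_three_balanced_classes(self):
        y_true = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        y_pred = ["a"] * 30
        rep = confusion(y_true, y_pred)
        assert rep.overall_accuracy == pytest.approx(1 / 3)

    def test_hand_built_two_by_two(self):
        y_true = ["s"] * 50 + ["r"] * 50
        y_pred = ["s"] * 40 + ["r"] * 10 + ["s"] * 5 + ["r"] * 45
        rep = confusion(y_true, y_pred)
        assert rep.overall_accuracy == pytest.approx(0.85)
        assert rep.total == 100

    def test_total_conservation(self, rng):
        y_true = rng.integers(0, 3, 123)
        y_pred = rng.integers(0, 3, 123)
        assert confusion(y_true, y_pred).total == 123

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 2], [1, 2, 3])
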