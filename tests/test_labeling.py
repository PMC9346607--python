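"""Resistance grading, patch extraction, augmentation, and splitting."""

import numpy as np
import pandas as pd
import pytest

from resistweed.labeling import (
    Patch,
    PatchDataset,
    ResistanceLabel,
    augment_rotations,
    extract_patches,
    grade_block,
    is_resistant,
    label_block,
    load_dataset,
    save_dataset,
    split_dataset,
)
from resistweed.raster import Affine, RasterGrid


class TestGrading:
    @pytest.mark.parametrize(
        "death,expected",
        [
            (0.0, 1), (0.10, 1), (0.25, 1),
            (0.26, 2), (0.50, 2),
            (0.51, 3), (0.60, 3), (0.75, 3),
            (0.76, 4), (0.95, 4),
            (0.96, 5), (1.0, 5),
        ],
    )
    def test_level_boundaries(self, death, expected):
        assert grade_block(death) == expected

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError, match="0, 1"):
                grade_block(bad)

    def test_grading_is_monotone_step_function(self):
        fracs = np.linspace(0, 1, 400)
        levels = [grade_block(f) for f in fracs]
        assert all(a <= b for a, b in zip(levels, levels[1:]))
        assert set(levels) == {1, 2, 3, 4, 5}

    @pytest.mark.parametrize("level,expected", [(1, True), (2, True), (3, True),
                                                (4, False), (5, False)])
    def test_resistant_iff_level_at_most_three(self, level, expected):
        assert is_resistant(level) is expected

    def test_label_block_velvetleaf_survival(self):
        survivor = label_block("velvetleaf", 0.0)
        dead = label_block("velvetleaf", 1.0)
        assert survivor.is_resistant and survivor.level == 1
        assert not dead.is_resistant and dead.level == 5


def scene_rasters(gsd=0.5, size_cm=200.0):
    """A synthetic fused + RGB raster pair on a common grid."""
    n = int(size_cm / gsd)
    rng = np.random.default_rng(0)
    fused = RasterGrid(
        rng.uniform(0.05, 0.6, (5, n, n)), ("B", "G", "R", "RE", "NIR"),
        gsd=gsd, transform=Affine.north_up(0.0, size_cm, gsd),
    )
    rgb = RasterGrid(
        rng.uniform(0.05, 0.6, (3, n, n)), ("red", "green", "blue"),
        gsd=gsd, transform=Affine.north_up(0.0, size_cm, gsd),
    )
    return fused, rgb


def roi_table(rows):
    return pd.DataFrame(
        rows,
        columns=["roi_id", "species", "xmin", "ymin", "xmax", "ymax",
                 "death_fraction_day14"],
    )


class TestExtractPatches:
    def test_half_meter_roi_at_half_cm_gsd_gives_100_pixels(self):
        fused, rgb = scene_rasters(gsd=0.5)
        rois = roi_table([(0, "barnyardgrass", 50.0, 50.0, 100.0, 100.0, 0.2)])
        ds = extract_patches(fused, rgb, rois)
        assert ds.patches[0].pixel_array.shape == (4, 100, 100)

    def test_channel_order_wsri_r_g_b(self):
        fused, rgb = scene_rasters()
        rois = roi_table([(0, "barnyardgrass", 0.0, 0.0, 50.0, 50.0, 0.1)])
        ds = extract_patches(fused, rgb, rois)
        patch = ds.patches[0].pixel_array
        # channels 1..3 equal the RGB window exactly
        assert np.allclose(patch[1], rgb.band("red")[300:400, 0:100])
        assert np.allclose(patch[2], rgb.band("green")[300:400, 0:100])
        assert np.allclose(patch[3], rgb.band("blue")[300:400, 0:100])

    def test_identical_rois_give_identical_patches(self):
        fused, rgb = scene_rasters()
        rois = roi_table([
            (0, "barnyardgrass", 10.0, 10.0, 60.0, 60.0, 0.3),
            (1, "barnyardgrass", 10.0, 10.0, 60.0, 60.0, 0.3),
        ])
        ds = extract_patches(fused, rgb, rois)
        assert np.array_equal(ds.patches[0].pixel_array, ds.patches[1].pixel_array)

    def test_roi_off_raster_names_roi(self):
        fused, rgb = scene_rasters()
        rois = roi_table([(7, "barnyardgrass", 150.0, 150.0, 260.0, 260.0, 0.2)])
        with pytest.raises(ValueError, match="7"):
            extract_patches(fused, rgb, rois)

    def test_species_mask_zeroes_background(self):
        fused, rgb = scene_rasters()  # 400 x 400 px, 0.5 cm gsd, 200 cm extent
        mask = np.zeros(fused.shape, bool)
        mask[:, :100] = True  # only the left 50 cm is "target species"
        # ROI: x 0..100 cm (cols 0..200), y 150..200 cm (rows 0..100)
        rois = roi_table([(0, "barnyardgrass", 0.0, 150.0, 100.0, 200.0, 0.2)])
        ds = extract_patches(fused, rgb, rois, species_mask=mask)
        patch = ds.patches[0].pixel_array
        assert patch.shape == (4, 100, 200)
        assert np.all(patch[:, :, 100:] == 0.0)
        assert np.any(patch[:, :, :100] != 0.0)


def toy_dataset(n_rois, size=8):
    rng = np.random.default_rng(0)
    patches = [
        Patch(
            pixel_array=rng.uniform(0, 1, (4, size, size)),
            label=ResistanceLabel("barnyardgrass", 2, True),
            roi_id=i,
            roi=(0.0, 0.0, 1.0, 1.0),
        )
        for i in range(n_rois)
    ]
    return PatchDataset(patches, dict(day=2, density="low"))


class TestAugmentation:
    def test_barnyardgrass_observation_arithmetic(self):
        # 1,750 block observations -> 7,000 after the four rotations
        ds = augment_rotations(toy_dataset(1750, size=4))
        assert len(ds) == 7000

    def test_velvetleaf_observation_arithmetic(self):
        # 480 plant observations -> 1,920 after the four rotations
        ds = augment_rotations(toy_dataset(480, size=4))
        assert len(ds) == 1920

    def test_rotating_twice_by_180_restores_original(self):
        ds = toy_dataset(3)
        aug = augment_rotations(ds)
        originals = {p.roi_id: p.pixel_array for p in ds.patches}
        for p in aug.patches:
            if p.rotation == 180:
                twice = np.rot90(p.pixel_array, k=-2, axes=(1, 2))
                assert np.array_equal(twice, originals[p.roi_id])

    def test_rotation_recorded_and_split_inherited(self):
        ds = split_dataset(toy_dataset(10), ratio=0.8, seed=0)
        aug = augment_rotations(ds)
        assert sorted({p.rotation for p in aug.patches}) == [0, 90, 180, 270]
        by_roi = {}
        for p in aug.patches:
            by_roi.setdefault(p.roi_id, set()).add(p.split)
        assert all(len(splits) == 1 for splits in by_roi.values())

    def test_non_square_patch_rejected(self):
        p = Patch(np.zeros((4, 8, 9)), ResistanceLabel("barnyardgrass", 1, True),
                  0, (0, 0, 1, 1))
        with pytest.raises(ValueError, match="square"):
            augment_rotations(PatchDataset([p]))


class TestSplit:
    def test_ratio_arithmetic(self):
        ds = split_dataset(toy_dataset(1000), ratio=0.8, seed=1)
        index = ds.index_frame()
        assert (index.split == "train").sum() == 800
        assert (index.split == "val").sum() == 200

    def test_deterministic_given_seed(self):
        a = split_dataset(toy_dataset(50), seed=3).index_frame()
        b = split_dataset(toy_dataset(50), seed=3).index_frame()
        assert a.equals(b)

    def test_partitions_are_disjoint_by_roi(self):
        ds = split_dataset(toy_dataset(40), seed=2)
        train = {p.roi_id for p in ds.patches if p.split == "train"}
        val = {p.roi_id for p in ds.patches if p.split == "val"}
        assert not train & val

    def test_split_after_augmentation_rejected(self):
        aug = augment_rotations(toy_dataset(5))
        with pytest.raises(ValueError, match="before"):
            split_dataset(aug)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            split_dataset(toy_dataset(5), ratio=1.5)


class TestRoiLoading:
    def test_csv_and_geojson_agree(self, tmp_path):
        import json

        from resistweed.labeling import load_rois

        table = roi_table([(3, "barnyardgrass", 10.0, 20.0, 60.0, 70.0, 0.4)])
        table.to_csv(tmp_path / "rois.csv", index=False)
        geojson = {
            "type": "FeatureCollection",
            "features": [{
                "type": "Feature",
                "properties": {"roi_id": 3, "species": "barnyardgrass",
                               "death_fraction_day14": 0.4},
                "geometry": {"type": "Polygon",
                             "coordinates": [[[10.0, 20.0], [60.0, 20.0],
                                              [60.0, 70.0], [10.0, 70.0],
                                              [10.0, 20.0]]]},
            }],
        }
        (tmp_path / "rois.geojson").write_text(json.dumps(geojson))
        a = load_rois(tmp_path / "rois.csv")
        b = load_rois(tmp_path / "rois.geojson")
        assert a[["roi_id", "xmin", "ymin", "xmax", "ymax"]].equals(
            b[["roi_id", "xmin", "ymin", "xmax", "ymax"]]
        )


class TestSerialization:
    def test_save_load_round_trip_preserves_channels(self, tmp_path):
        ds = augment_rotations(split_dataset(toy_dataset(6), seed=0))
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert len(back) == len(ds)
        for a, b in zip(ds.patches, back.patches):
            assert np.allclose(a.pixel_array, b.pixel_array, atol=1e-6)
            assert a.label == b.label
            assert a.rotation == b.rotation
            assert a.split == b.split
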