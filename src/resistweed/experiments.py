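"""Desk-scale synthetic experiments: scene -> fused patches -> classifier.

Convenience drivers that chain the pipeline stages in memory (no file I/O)
to produce labeled patch datasets per acquisition day and density, for the
per-day / per-density / per-feature-type evaluation grids.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fusion import FusionConfig, _resample_to_shape, build_pan, gs_sharpen
from .labeling import PatchDataset, extract_patches, rois_from_blocks
from .synthetic import CLASS_IDS, SceneConfig, simulate_scene

__all__ = ["scene_patch_dataset", "day_series_datasets"]


def scene_patch_dataset(
    config: SceneConfig,
    day: int,
    species: str = "barnyardgrass",
    patch_size: int | None = 48,
    roi_size_cm: float = 48.0,
    n_scenes: int = 1,
    sharpen: bool = True,
) -> PatchDataset:
    """Simulate scene(s), sharpen, and cut labeled weed patches.

    Pools fixed-size block ROIs (``roi_size_cm`` squares centered on each
    block, the equal-rectangle survey protocol) of ``species`` across
    ``n_scenes`` independent scene layouts (seeds ``config.seed ..
    config.seed + n_scenes - 1``) into one unsplit, unaugmented dataset
    whose provenance records day and density. Patches keep their native
    pixel window unless ``patch_size`` forces a resize. ROI ids are made
    unique across scenes.
    """
    fcfg = FusionConfig()
    patches = []
    roi_offset = 0
    for s in range(n_scenes):
        cfg = replace(config, seed=config.seed + s)
        ms, rgb, truth = simulate_scene(cfg, day=day)
        if sharpen:
            fused = gs_sharpen(ms, build_pan(rgb, fcfg), fcfg)
        else:
            from .fusion import resample

            fused = resample(ms, rgb.gsd)
        # patches are cut from the segmentation image: only pixels of the
        # target species survive (soil, maize, the other weed are zeroed)
        from .raster import RasterGrid

        cls = RasterGrid(truth.class_mask.astype(np.float64)[None], ("class_id",),
                         ms.gsd, ms.transform, "DN")
        cls_fine = _resample_to_shape(cls, fused.shape, fused.gsd, "nearest").values[0]
        target_ids = [CLASS_IDS[f"{species}_S"], CLASS_IDS[f"{species}_R"]]
        species_mask = np.isin(cls_fine.astype(int), target_ids)
        w, h = fused.extent_cm()
        rois = rois_from_blocks(
            truth.block_table, species=species,
            roi_size_cm=roi_size_cm, extent_cm=(w, h),
        )
        ds = extract_patches(
            fused, rgb, rois, day=day, density=cfg.density, patch_size=patch_size,
            species_mask=species_mask,
        )
        for p in ds.patches:
            p.roi_id += roi_offset
        roi_offset += int(rois["roi_id"].max()) + 1 if len(rois) else 0
        patches.extend(ds.patches)
    return PatchDataset(
        patches,
        dict(day=day, density=config.density, patch_size=patch_size,
             n_scenes=n_scenes, seed=config.seed),
    )


def day_series_datasets(
    config: SceneConfig,
    days: tuple[int, ...] = (2, 4, 6, 8),
    species: str = "barnyardgrass",
    patch_size: int | None = 48,
    roi_size_cm: float = 48.0,
    n_scenes: int = 1,
) -> dict[int, PatchDataset]:
    """One patch dataset per acquisition day over the same scene layouts."""
    return {
        d: scene_patch_dataset(config, d, species=species, patch_size=patch_size,
                               roi_size_cm=roi_size_cm, n_scenes=n_scenes)
        for d in days
    }
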