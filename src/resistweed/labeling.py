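"""Resistance grading and patch-dataset construction.

Barnyardgrass grows in dense aggregated blocks, so resistance is graded at
block level from the fraction of plants dead 14 days after application:

=====  ==================
level  death fraction
=====  ==================
1      [0, 0.25]
2      (0.25, 0.50]
3      (0.50, 0.75]
4      (0.75, 0.95]
5      (0.95, 1]  (entirely dead block)
=====  ==================

Blocks at level <= 3 are *resistant* (they exceed the weed-control
threshold). Velvetleaf grows as separable individuals and is labeled per
plant directly from day-14 survival.

Patches are 4-band stacks ordered (WSRI, R, G, B): the WSRI channel from
the sharpened multispectral product and the RGB channels from the
high-resolution camera, cut from ~0.5 m x 0.5 m regions of interest
(~100 x 100 pixels at the fused GSD). Datasets are split 8:2 into train and
validation *by ROI before augmentation*, then augmented by the four
clockwise rotations (0/90/180/270 degrees), so no rotated copy of a
training region can leak into validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .indices import compute_index
from .raster import RasterGrid

__all__ = [
    "ResistanceLabel",
    "Patch",
    "PatchDataset",
    "grade_block",
    "is_resistant",
    "label_block",
    "extract_patches",
    "augment_rotations",
    "split_dataset",
    "load_rois",
    "rois_from_blocks",
    "save_dataset",
    "load_dataset",
]

#: Grading-scale upper boundaries (level i covers up to _LEVEL_BOUNDS[i-1]).
_LEVEL_BOUNDS = (0.25, 0.50, 0.75, 0.95, 1.0)

#: Channel order of the 4-band patch stack.
PATCH_CHANNELS = ("WSRI", "R", "G", "B")

#: WSRI channel clip range applied before stacking.
WSRI_CLIP = (-1.0, 3.0)


def grade_block(death_fraction: float) -> int:
    """Resistance level (1-5) of a barnyardgrass block from its day-14
    death fraction. Intervals are upper-closed: level 1 = [0, 0.25],
    2 = (0.25, 0.50], 3 = (0.50, 0.75], 4 = (0.75, 0.95], 5 = (0.95, 1]."""
    f = float(death_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"death fraction must lie in [0, 1], got {f}")
    for level, bound in enumerate(_LEVEL_BOUNDS, start=1):
        if f <= bound:
            return level
    return 5  # unreachable


@dataclass(frozen=True)
class ResistanceLabel:
    """Resistance call for one block (barnyardgrass) or plant (velvetleaf)."""

    species: str
    level: int  # 1-5 for barnyardgrass; 1 (survived) or 5 (dead) for velvetleaf
    is_resistant: bool

    def __post_init__(self) -> None:
        if self.species not in ("barnyardgrass", "velvetleaf"):
            raise ValueError(f"unknown species {self.species!r}")
        if not 1 <= self.level <= 5:
            raise ValueError(f"level must be 1-5, got {self.level}")


def is_resistant(label: ResistanceLabel | int, species: str = "barnyardgrass") -> bool:
    """Resistance rule: level <= 3 is resistant.

    Accepts a :class:`ResistanceLabel` or a bare level with a species.
    For velvetleaf the per-plant survival labeling maps survivors to level 1
    and dead plants to level 5, so the same rule applies.
    """
    level = label.level if isinstance(label, ResistanceLabel) else int(label)
    if not 1 <= level <= 5:
        raise ValueError(f"level must be 1-5, got {level}")
    return level <= 3


def label_block(species: str, death_fraction: float) -> ResistanceLabel:
    """Grade and label a block from its day-14 death fraction.

    Velvetleaf is labeled per plant from survival (death fraction 0 or 1 in
    practice); any fraction is accepted and graded on the same scale.
    """
    level = grade_block(death_fraction)
    return ResistanceLabel(species=species, level=level, is_resistant=level <= 3)


@dataclass
class Patch:
    """One labeled 4-band (WSRI, R, G, B) image patch."""

    pixel_array: np.ndarray  # (4, H, W)
    label: ResistanceLabel
    roi_id: int
    roi: tuple[float, float, float, float]  # world cm, (xmin, ymin, xmax, ymax)
    rotation: int = 0  # clockwise degrees: 0 / 90 / 180 / 270
    split: str | None = None  # train | val | test_area

    def __post_init__(self) -> None:
        if self.pixel_array.ndim != 3 or self.pixel_array.shape[0] != 4:
            raise ValueError(f"patch must be (4, H, W), got {self.pixel_array.shape}")
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError(f"rotation must be one of 0/90/180/270, got {self.rotation}")


@dataclass
class PatchDataset:
    """A collection of patches plus provenance (scene, day, density, seed)."""

    patches: list[Patch]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def augmented(self) -> bool:
        return any(p.rotation != 0 for p in self.patches)

    def subset(self, split: str) -> "PatchDataset":
        return PatchDataset(
            [p for p in self.patches if p.split == split], dict(self.provenance)
        )

    def roi_ids(self) -> list[int]:
        return sorted({p.roi_id for p in self.patches})

    def index_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                patch_id=i,
                roi_id=p.roi_id,
                species=p.label.species,
                level=p.label.level,
                resistant=p.label.is_resistant,
                rotation=p.rotation,
                split=p.split,
            )
            for i, p in enumerate(self.patches)
        ]
        return pd.DataFrame(rows)


def load_rois(path) -> pd.DataFrame:
    """Load an ROI table from CSV or GeoJSON.

    CSV needs the columns roi_id, species, xmin, ymin, xmax, ymax,
    death_fraction_day14 (world cm). GeoJSON features carry roi_id,
    species and death_fraction_day14 in ``properties`` and a polygon
    geometry whose bounding box becomes the rectangle.
    """
    import json as _json

    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    with open(path) as fh:
        data = _json.load(fh)
    rows = []
    for feature in data.get("features", []):
        props = feature.get("properties", {})
        coords = np.asarray(feature["geometry"]["coordinates"][0], float)
        rows.append(
            dict(
                roi_id=int(props["roi_id"]),
                species=props["species"],
                xmin=float(coords[:, 0].min()),
                ymin=float(coords[:, 1].min()),
                xmax=float(coords[:, 0].max()),
                ymax=float(coords[:, 1].max()),
                death_fraction_day14=float(props["death_fraction_day14"]),
            )
        )
    return pd.DataFrame(rows)


def rois_from_blocks(
    block_table: pd.DataFrame,
    species: str | None = None,
    min_size_cm: float = 20.0,
    roi_size_cm: float | None = None,
    extent_cm: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Turn the simulator's block table into an ROI table with labels.

    By default each ROI is the block's bounding box, grown symmetrically to
    at least ``min_size_cm``. With ``roi_size_cm`` every ROI is a fixed
    square of that side centered on the block — the survey protocol of
    drawing equal ~0.5 m rectangles — shifted inward to stay inside
    ``extent_cm`` (width, height) if given. Columns: roi_id, species,
    xmin, ymin, xmax, ymax, death_fraction_day14.
    """
    df = block_table.copy()
    if species is not None:
        df = df[df["species"] == species]
    out = []
    for _, row in df.iterrows():
        xmin, ymin, xmax, ymax = row["xmin"], row["ymin"], row["xmax"], row["ymax"]
        if roi_size_cm is not None:
            cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
            half = roi_size_cm / 2
            if extent_cm is not None:
                cx = min(max(cx, half), extent_cm[0] - half)
                cy = min(max(cy, half), extent_cm[1] - half)
            xmin, xmax = cx - half, cx + half
            ymin, ymax = cy - half, cy + half
        else:
            w, h = xmax - xmin, ymax - ymin
            if w < min_size_cm:
                cx = (xmin + xmax) / 2
                xmin, xmax = cx - min_size_cm / 2, cx + min_size_cm / 2
            if h < min_size_cm:
                cy = (ymin + ymax) / 2
                ymin, ymax = cy - min_size_cm / 2, cy + min_size_cm / 2
        out.append(
            dict(
                roi_id=int(row["block_id"]),
                species=row["species"],
                xmin=xmin,
                ymin=ymin,
                xmax=xmax,
                ymax=ymax,
                death_fraction_day14=row["death_fraction_day14"],
            )
        )
    return pd.DataFrame(out)


def _window_from_roi(
    grid: RasterGrid, roi: tuple[float, float, float, float]
) -> tuple[int, int, int, int]:
    """Half-open pixel window (r0, r1, c0, c1) of a world-cm rectangle."""
    xmin, ymin, xmax, ymax = roi
    r0, c0 = grid.transform.rowcol(xmin, ymax)  # top-left
    r1, c1 = grid.transform.rowcol(xmax, ymin)  # bottom-right
    r0, c0 = int(np.floor(round(r0, 9))), int(np.floor(round(c0, 9)))
    r1, c1 = int(np.ceil(round(r1, 9))), int(np.ceil(round(c1, 9)))
    rows, cols = grid.shape
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols or r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"ROI {roi} maps to pixel window [{r0}:{r1}, {c0}:{c1}] outside "
            f"the {rows}x{cols} raster"
        )
    return r0, r1, c0, c1


def _resize_stack(stack: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    out = np.empty((stack.shape[0], size, size), dtype=np.float64)
    for i in range(stack.shape[0]):
        plane = stack[i]
        nan = np.isnan(plane)
        filled = np.where(nan, np.nanmean(plane) if not nan.all() else 0.0, plane)
        out[i] = resize(filled, (size, size), order=1, mode="edge",
                        anti_aliasing=plane.shape[0] > size, preserve_range=True)
    return out


def extract_patches(
    fused: RasterGrid,
    rgb: RasterGrid,
    rois: pd.DataFrame,
    day: int | None = None,
    density: str | None = None,
    patch_size: int | None = None,
    species_mask: np.ndarray | None = None,
) -> PatchDataset:
    """Cut labeled 4-band (WSRI, R, G, B) patches from a sharpened scene.

    ``fused`` is the 5-band pan-sharpened raster (WSRI is computed from
    it); ``rgb`` the co-registered RGB raster at the same resolution.
    ``rois`` needs columns roi_id, species, xmin/ymin/xmax/ymax (world cm)
    and death_fraction_day14. If ``patch_size`` is given every patch is
    resampled to that square size; otherwise patches keep their native
    pixel window (and must then be square for rotation augmentation).
    RGB channels are reflectance in [0, 1]; the WSRI channel is clipped to
    [-1, 3] before stacking.

    ``species_mask`` (bool, fused grid) restricts patches to the segmented
    target species: patches are cut from the segmentation image, so soil,
    crop and other species are zeroed out in all four channels. Without it
    crop pixels — spectrally indistinguishable from healthy resistant
    weed — remain in every patch.
    """
    required = {"roi_id", "species", "xmin", "ymin", "xmax", "ymax", "death_fraction_day14"}
    missing = required - set(rois.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    if fused.shape != rgb.shape:
        raise ValueError(
            f"fused {fused.shape} and RGB {rgb.shape} rasters must share a grid"
        )
    wsri = compute_index(fused, "WSRI").values[0]
    wsri = np.clip(wsri, *WSRI_CLIP)
    red, green, blue = (rgb.band(r) for r in ("red", "green", "blue"))
    stack_full = np.stack([wsri, red, green, blue])
    stack_full = np.where(np.isnan(stack_full), 0.0, stack_full)
    if species_mask is not None:
        if species_mask.shape != fused.shape:
            raise ValueError(
                f"species_mask shape {species_mask.shape} does not match "
                f"raster shape {fused.shape}"
            )
        stack_full = stack_full * species_mask.astype(np.float64)[None]

    patches: list[Patch] = []
    for _, row in rois.iterrows():
        roi = (float(row["xmin"]), float(row["ymin"]), float(row["xmax"]), float(row["ymax"]))
        try:
            r0, r1, c0, c1 = _window_from_roi(fused, roi)
        except ValueError as exc:
            raise ValueError(f"ROI {int(row['roi_id'])}: {exc}") from exc
        sub = stack_full[:, r0:r1, c0:c1]
        if patch_size is not None:
            sub = _resize_stack(sub, patch_size)
        label = label_block(str(row["species"]), float(row["death_fraction_day14"]))
        patches.append(
            Patch(pixel_array=sub.copy(), label=label, roi_id=int(row["roi_id"]), roi=roi)
        )
    provenance = dict(day=day, density=density, n_rois=len(patches), patch_size=patch_size)
    return PatchDataset(patches, provenance)


def split_dataset(dataset: PatchDataset, ratio: float = 0.8, seed: int = 0) -> PatchDataset:
    """Randomly partition ROIs into train/validation at ``ratio``.

    Must run *before* rotation augmentation (augmented input raises), so
    that all rotated copies of one ROI inherit one split.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if dataset.augmented:
        raise ValueError("split must happen before rotation augmentation")
    roi_ids = dataset.roi_ids()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(roi_ids)
    n_train = int(round(ratio * len(perm)))
    train_ids = set(int(i) for i in perm[:n_train])
    patches = [
        replace(p, split="train" if p.roi_id in train_ids else "val")
        for p in dataset.patches
    ]
    prov = dict(dataset.provenance)
    prov.update(split_ratio=ratio, split_seed=seed)
    return PatchDataset(patches, prov)


def _rot_cw(arr: np.ndarray, k90: int) -> np.ndarray:
    """Rotate a (C, H, W) stack clockwise by k90 * 90 degrees."""
    return np.rot90(arr, k=-k90, axes=(1, 2))


def augment_rotations(dataset: PatchDataset) -> PatchDataset:
    """Four clockwise rotations (0, 90, 180, 270 degrees) of every patch.

    Output has exactly 4x the patches; labels and split membership are
    inherited; non-square patches raise.
    """
    out: list[Patch] = []
    for p in dataset.patches:
        if p.pixel_array.shape[1] != p.pixel_array.shape[2]:
            raise ValueError(
                f"ROI {p.roi_id}: rotation augmentation needs square patches, "
                f"got {p.pixel_array.shape[1:]}"
            )
        for k, deg in enumerate((0, 90, 180, 270)):
            out.append(
                replace(
                    p,
                    pixel_array=np.ascontiguousarray(_rot_cw(p.pixel_array, k)),
                    rotation=deg,
                )
            )
    prov = dict(dataset.provenance)
    prov["augmented"] = True
    return PatchDataset(out, prov)


# -- serialization ---------------------------------------------------------


def save_dataset(dataset: PatchDataset, out_dir) -> Path:
    """Write patches as multiband TIFFs plus an index CSV; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = dataset.index_frame()
    index["file"] = [f"patch_{i:06d}.tif" for i in range(len(dataset.patches))]
    rois = pd.DataFrame([p.roi for p in dataset.patches],
                        columns=["xmin", "ymin", "xmax", "ymax"])
    index = pd.concat([index, rois], axis=1)
    for fname, p in zip(index["file"], dataset.patches):
        tifffile.imwrite(out_dir / fname, p.pixel_array.astype(np.float32),
                         photometric="minisblack", planarconfig="separate")
    index.to_csv(out_dir / "index.csv", index=False)
    pd.Series(dataset.provenance, dtype=object).to_json(out_dir / "provenance.json")
    return out_dir


def load_dataset(in_dir) -> PatchDataset:
    """Load a dataset written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "index.csv")
    patches = []
    for _, row in index.iterrows():
        arr = tifffile.imread(in_dir / row["file"]).astype(np.float64)
        label = ResistanceLabel(
            species=row["species"], level=int(row["level"]),
            is_resistant=bool(row["resistant"]),
        )
        split = row["split"] if isinstance(row["split"], str) else None
        patches.append(
            Patch(
                pixel_array=arr,
                label=label,
                roi_id=int(row["roi_id"]),
                roi=(row["xmin"], row["ymin"], row["xmax"], row["ymax"]),
                rotation=int(row["rotation"]),
                split=split,
            )
        )
    prov_path = in_dir / "provenance.json"
    provenance = {}
    if prov_path.exists():
        provenance = pd.read_json(prov_path, typ="series").to_dict()
    return PatchDataset(patches, provenance)
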