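"""Gram-Schmidt pan-sharpening of multispectral imagery with an RGB pan band.

The multispectral sensor carries the spectral signal but little texture; the
RGB camera has roughly twice the spatial resolution. GS pan-sharpening
injects the RGB detail into the 5-band stack:

1. build a simulated low-resolution panchromatic band as a weighted linear
   combination of the multispectral bands (weights over the visible bands
   only, because the RGB camera senses only the visible range);
2. upsample the multispectral stack to the pan grid;
3. Gram-Schmidt orthogonalize the (simulated pan, B, G, R, RE, NIR) stack,
   mean-removed, with the simulated pan as the first component;
4. match the high-resolution pan band to the simulated pan (mean/sd
   standardization) and substitute it for the first GS component;
5. invert the GS transform to recover 5 sharpened bands at pan resolution.

Substituting a pan identical to the simulated pan is an exact identity, and
degrading the fused product back to the multispectral grid reproduces the
input spectra (Wald consistency) — both are tested properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .raster import Affine, RasterGrid

__all__ = [
    "FusionConfig",
    "build_pan",
    "resample",
    "degrade_to",
    "gs_sharpen",
    "spectral_fidelity",
]


@dataclass(frozen=True)
class FusionConfig:
    """Weights defining the simulated and high-resolution pan bands.

    ``sim_pan_weights`` spans (B, G, R, RE, NIR) and defaults to uniform
    over the visible bands with zero on red-edge/NIR; ``pan_source_weights``
    spans the RGB camera channels (red, green, blue). Both must be
    non-negative and sum to 1.
    """

    sim_pan_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3, 0.0, 0.0)
    pan_source_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    resampling: str = "bilinear"

    def __post_init__(self) -> None:
        for name, w in (("sim_pan_weights", self.sim_pan_weights),
                        ("pan_source_weights", self.pan_source_weights)):
            arr = np.asarray(w, float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            if not np.isclose(arr.sum(), 1.0):
                raise ValueError(f"{name} must sum to 1, got {arr.sum()}")
        if self.resampling not in ("bilinear", "nearest", "cubic"):
            raise ValueError(f"unknown resampling kernel {self.resampling!r}")


_RESAMPLE_ORDER = {"nearest": 0, "bilinear": 1, "cubic": 3}


def build_pan(rgb: RasterGrid, config: FusionConfig | None = None) -> RasterGrid:
    """Weighted sum of the RGB channels: the high-resolution pan band."""
    config = config or FusionConfig()
    if rgb.n_bands != 3:
        raise ValueError(f"pan source must have 3 bands, got {rgb.n_bands}")
    w = np.asarray(config.pan_source_weights, float)
    pan = np.tensordot(w, rgb.values, axes=1)
    return RasterGrid(
        values=pan[None],
        band_roles=("pan",),
        gsd=rgb.gsd,
        transform=rgb.transform,
        value_kind=rgb.value_kind,
        nodata=rgb.nodata,
    )


def resample(grid: RasterGrid, target_gsd: float, method: str = "bilinear") -> RasterGrid:
    """Resample to a new ground sampling distance (bilinear by default)."""
    if target_gsd <= 0:
        raise ValueError("target_gsd must be > 0")
    if target_gsd == grid.gsd:
        return grid.copy_with(values=grid.values.copy())
    width, height = grid.extent_cm()
    rows = int(round(height / target_gsd))
    cols = int(round(width / target_gsd))
    return _resample_to_shape(grid, (rows, cols), target_gsd, method)


def _resample_to_shape(
    grid: RasterGrid, shape: tuple[int, int], target_gsd: float, method: str = "bilinear"
) -> RasterGrid:
    order = _RESAMPLE_ORDER[method]
    out = np.empty((grid.n_bands,) + shape, dtype=np.float64)
    downsampling = shape[0] < grid.shape[0]
    for i in range(grid.n_bands):
        out[i] = resize(
            grid.values[i].astype(np.float64),
            shape,
            order=order,
            mode="edge",
            anti_aliasing=downsampling and order > 0,
            preserve_range=True,
        )
    t = grid.transform
    sx = target_gsd if t.a >= 0 else -target_gsd
    sy = -target_gsd if t.e <= 0 else target_gsd
    new_transform = Affine(sx, t.b, t.c, t.d, sy, t.f)
    if grid.value_kind == "reflectance":
        out = np.clip(out, 0.0, 1.0)
    return RasterGrid(
        values=out,
        band_roles=grid.band_roles,
        gsd=target_gsd,
        transform=new_transform,
        value_kind=grid.value_kind,
        nodata=grid.nodata,
    )


def degrade_to(grid: RasterGrid, reference: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Degrade a fine raster to exactly the grid of a coarser reference.

    When the fine grid is an exact integer multiple of the reference grid
    the degradation is the exact block mean (the natural sensor model for
    a consistency check); otherwise an anti-aliased resize is used.
    """
    (gr, gc), (rr, rc) = grid.shape, reference.shape
    if gr % rr == 0 and gc % rc == 0 and (gr // rr == gc // rc) and gr // rr > 1:
        k = gr // rr
        vals = grid.values.reshape(grid.n_bands, rr, k, rc, k).mean(axis=(2, 4))
        t = reference.transform
        return RasterGrid(
            values=vals,
            band_roles=grid.band_roles,
            gsd=reference.gsd,
            transform=t,
            value_kind=grid.value_kind,
            nodata=grid.nodata,
        )
    return _resample_to_shape(grid, reference.shape, reference.gsd, method)


def _simulated_pan(ms: RasterGrid, config: FusionConfig) -> np.ndarray:
    w = np.asarray(config.sim_pan_weights, float)
    if w.size != ms.n_bands:
        raise ValueError(
            f"sim_pan_weights has {w.size} entries for a {ms.n_bands}-band raster"
        )
    return np.tensordot(w, ms.values, axes=1)


def gs_sharpen(
    ms: RasterGrid, pan: RasterGrid, config: FusionConfig | None = None
) -> RasterGrid:
    """Gram-Schmidt pan-sharpen the multispectral raster to pan resolution.

    ``pan`` is a single-band raster covering the same ground extent at a
    resolution at least as fine as the multispectral raster. Returns a
    5-band raster at pan resolution with the band roles preserved.
    """
    config = config or FusionConfig()
    if pan.n_bands != 1:
        raise ValueError("pan must be single-band")
    ms_w, ms_h = ms.extent_cm()
    pan_w, pan_h = pan.extent_cm()
    if abs(ms_w - pan_w) > ms.gsd / 2 or abs(ms_h - pan_h) > ms.gsd / 2:
        raise ValueError(
            f"extent mismatch beyond half a pixel: ms {ms_w:.1f}x{ms_h:.1f} cm "
            f"vs pan {pan_w:.1f}x{pan_h:.1f} cm"
        )
    if pan.gsd > ms.gsd:
        raise ValueError("pan resolution must be at least as fine as the multispectral")

    # 1-2. upsample MS to the pan grid; simulated pan on that grid
    ms_up = _resample_to_shape(ms, pan.shape, pan.gsd, config.resampling)
    sim_pan = _simulated_pan(ms_up, config)
    if float(np.nanstd(sim_pan)) == 0.0:
        raise ValueError("simulated pan band has zero variance; cannot sharpen")

    valid = ms_up.valid_mask() & pan.valid_mask()
    if not valid.any():
        raise ValueError("no valid overlapping pixels")

    # 3. Gram-Schmidt with the simulated pan as the first component.
    # Components are kept as full-resolution images; inner products run
    # over valid pixels only.
    bands = [sim_pan] + [ms_up.values[i] for i in range(ms_up.n_bands)]
    means = [float(np.mean(b[valid])) for b in bands]
    centered = [b - m for b, m in zip(bands, means)]

    gs: list[np.ndarray] = []
    coeffs: list[list[float]] = []  # projection coefficients onto earlier GS comps
    for k, bk in enumerate(centered):
        ck: list[float] = []
        res = bk.copy()
        for j in range(k):
            denom = float(np.sum(gs[j][valid] * gs[j][valid]))
            phi = float(np.sum(bk[valid] * gs[j][valid])) / denom if denom > 0 else 0.0
            ck.append(phi)
            res = res - phi * gs[j]
        gs.append(res)
        coeffs.append(ck)

    # 4. histogram-match (mean/sd) the high-res pan to the simulated pan
    pan_img = pan.values[0].astype(np.float64)
    p_mean, p_sd = float(np.mean(pan_img[valid])), float(np.std(pan_img[valid]))
    s_sd = float(np.std(sim_pan[valid]))
    if p_sd == 0:
        raise ValueError("pan band has zero variance; cannot histogram-match")
    matched = (pan_img - p_mean) * (s_sd / p_sd) + means[0]
    gs_sub = [matched - means[0]] + gs[1:]

    # 5. inverse GS transform with the substituted first component
    out = np.empty((ms.n_bands,) + pan.shape, dtype=np.float64)
    for k in range(1, len(gs_sub)):
        recon = gs_sub[k].copy()
        for j, phi in enumerate(coeffs[k]):
            recon += phi * gs_sub[j]
        out[k - 1] = recon + means[k]

    nodata_fill = ms.nodata
    if ms.value_kind == "reflectance":
        out = np.clip(out, 0.0, 1.0)
    out[:, ~valid] = nodata_fill
    return RasterGrid(
        values=out,
        band_roles=ms.band_roles,
        gsd=pan.gsd,
        transform=pan.transform,
        value_kind=ms.value_kind,
        nodata=ms.nodata,
    )


def spectral_fidelity(fused: RasterGrid, original_ms: RasterGrid) -> pd.DataFrame:
    """Wald-style consistency check: degrade the fused product to the
    original multispectral grid and report per-band Pearson correlation and
    RMSE against the original."""
    if fused.band_roles != original_ms.band_roles:
        raise ValueError("band roles differ between fused and original rasters")
    degraded = degrade_to(fused, original_ms)
    valid = degraded.valid_mask() & original_ms.valid_mask()
    rows = []
    for i, role in enumerate(original_ms.band_roles):
        a = degraded.values[i][valid]
        b = original_ms.values[i][valid]
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            corr = float("nan")
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        rows.append(dict(band=role, correlation=corr, rmse=rmse))
    return pd.DataFrame(rows)
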