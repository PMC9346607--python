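"""Empirical-line radiometric calibration.

Converts raw sensor digital numbers (DN) to surface reflectance with the
empirical line method: for every band, ordinary least squares of the known
reflectance of reference targets on their measured DN gives a gain and an
offset, and ``reflectance = gain * DN + offset`` is applied pixel-wise,
clipped to [0, 1].

A single reference target gives a degenerate line, so the fit requires at
least two distinct DN levels per band (e.g. the calibration carpet plus a
dark reading). A gain-only fallback (offset fixed at 0) is available for
single-panel field campaigns via ``allow_single_level=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "CalibrationPanel",
    "LineFit",
    "empirical_line_fit",
    "apply_calibration",
    "to_digital_numbers",
    "read_panel_csv",
]


@dataclass(frozen=True)
class LineFit:
    """Per-band empirical line: reflectance = gain * DN + offset."""

    gain: float
    offset: float


@dataclass
class CalibrationPanel:
    """Reference-target samples: rows of (band_role, mean_DN, known_reflectance)."""

    samples: pd.DataFrame  # columns: band, dn, reflectance

    def __post_init__(self) -> None:
        required = {"band", "dn", "reflectance"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        refl = self.samples["reflectance"].to_numpy(float)
        if np.any((refl < 0) | (refl > 1)):
            raise ValueError("known reflectance values must lie in [0, 1]")

    def bands(self) -> list[str]:
        return list(dict.fromkeys(self.samples["band"]))


def read_panel_csv(path) -> CalibrationPanel:
    """Load a panel sample table from CSV (columns: band, dn, reflectance)."""
    return CalibrationPanel(pd.read_csv(path))


def empirical_line_fit(
    panel: CalibrationPanel, allow_single_level: bool = False
) -> dict[str, LineFit]:
    """Fit the per-band empirical line by OLS.

    Returns a mapping band role -> :class:`LineFit`. Raises ``ValueError``
    naming the band if any band has fewer than two distinct DN levels
    (unless ``allow_single_level``, in which case a zero-offset gain-only
    line is fitted through the origin).
    """
    fits: dict[str, LineFit] = {}
    for band, rows in panel.samples.groupby("band", sort=False):
        dn = rows["dn"].to_numpy(float)
        rho = rows["reflectance"].to_numpy(float)
        if np.unique(dn).size < 2:
            if not allow_single_level:
                raise ValueError(
                    f"band {band!r} has fewer than 2 distinct DN levels; "
                    "add a dark reading or pass allow_single_level=True"
                )
            denom = float(dn @ dn)
            if denom == 0:
                raise ValueError(f"band {band!r}: all-zero DN, gain-only fit impossible")
            fits[str(band)] = LineFit(gain=float(dn @ rho) / denom, offset=0.0)
            continue
        # OLS of reflectance on DN
        A = np.column_stack([dn, np.ones_like(dn)])
        (gain, offset), *_ = np.linalg.lstsq(A, rho, rcond=None)
        fits[str(band)] = LineFit(gain=float(gain), offset=float(offset))
    return fits


def apply_calibration(grid: RasterGrid, fits: dict[str, LineFit]) -> RasterGrid:
    """Convert a DN raster to reflectance, clipping to [0, 1].

    Nodata pixels are propagated untouched.
    """
    if grid.value_kind != "DN":
        raise ValueError(f"expected a DN raster, got value_kind={grid.value_kind!r}")
    missing = [r for r in grid.band_roles if r not in fits]
    if missing:
        raise ValueError(f"no calibration fit for band(s): {missing}")
    out = np.empty(grid.values.shape, dtype=np.float64)
    if np.isnan(grid.nodata):
        invalid = np.isnan(grid.values)
    else:
        invalid = grid.values == grid.nodata
    for i, role in enumerate(grid.band_roles):
        fit = fits[role]
        out[i] = np.clip(fit.gain * grid.values[i] + fit.offset, 0.0, 1.0)
    out[invalid] = grid.nodata
    return RasterGrid(
        values=out,
        band_roles=grid.band_roles,
        gsd=grid.gsd,
        transform=grid.transform,
        value_kind="reflectance",
        nodata=grid.nodata,
    )


def to_digital_numbers(grid: RasterGrid, fits: dict[str, LineFit]) -> RasterGrid:
    """Inverse of :func:`apply_calibration`: synthesize DN from reflectance.

    Used by the simulator so that the calibration stage has raw input to
    work on; ``apply_calibration(to_digital_numbers(g, f), f) == g`` within
    float tolerance for in-range reflectance.
    """
    if grid.value_kind != "reflectance":
        raise ValueError("expected a reflectance raster")
    missing = [r for r in grid.band_roles if r not in fits]
    if missing:
        raise ValueError(f"no calibration fit for band(s): {missing}")
    out = np.empty(grid.values.shape, dtype=np.float64)
    if np.isnan(grid.nodata):
        invalid = np.isnan(grid.values)
    else:
        invalid = grid.values == grid.nodata
    for i, role in enumerate(grid.band_roles):
        fit = fits[role]
        if fit.gain == 0:
            raise ValueError(f"band {role!r}: zero gain is not invertible")
        out[i] = (grid.values[i] - fit.offset) / fit.gain
    out[invalid] = grid.nodata
    return RasterGrid(
        values=out,
        band_roles=grid.band_roles,
        gsd=grid.gsd,
        transform=grid.transform,
        value_kind="DN",
        nodata=grid.nodata,
    )
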