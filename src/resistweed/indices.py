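"""Vegetation indices, including the weed spectral resistance index (WSRI).

The registry holds the ten band-arithmetic indices the pipeline compares:
nine established indices (DVI, MTCI, NDVI, GNDVI, NDRE, RENDVI, RVI, RERVI,
PSRI) and WSRI = (RE - R) / (RE - B), an index built to separate
herbicide-susceptible from -resistant weed canopies: its numerator tracks
the chlorophyll-linked red/red-edge contrast while the blue band in the
denominator suppresses pigment-driven interference in leaf-surface
reflectance. As a ratio of band differences it is invariant to a positive
rescaling of all bands.

Band symbols refer to the multispectral camera's blue (450 nm), green
(560 nm), red (650 nm), red-edge (730 nm) and near-infrared (840 nm) bands.
Pixels where any input band is nodata, or where a denominator's magnitude
falls below ``DENOM_EPS``, evaluate to nodata rather than being clipped —
for WSRI the denominator RE - B genuinely vanishes on soil-like spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .raster import RasterGrid

__all__ = [
    "VIDefinition",
    "VI_REGISTRY",
    "VI_ALIASES",
    "DENOM_EPS",
    "compute_index",
    "index_summary",
    "separability_test",
    "significance_stars",
]

#: Denominator guard (reflectance units) below which an index is nodata.
DENOM_EPS = 1e-6


@dataclass(frozen=True)
class VIDefinition:
    """A named band-arithmetic vegetation index."""

    name: str
    expression: str
    func: Callable[..., np.ndarray]
    valid_range: tuple[float, float]


def _guard(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.where(np.abs(den) < DENOM_EPS, np.nan, num / np.where(den == 0, 1, den))
    out[np.abs(den) < DENOM_EPS] = np.nan
    return out


_DEFS = [
    ("DVI", "NIR - R", lambda B, G, R, RE, NIR: NIR - R, (-1.0, 1.0)),
    ("MTCI", "(NIR - RE) / (RE - R)", lambda B, G, R, RE, NIR: _guard(NIR - RE, RE - R),
     (-np.inf, np.inf)),
    ("NDVI", "(NIR - R) / (NIR + R)", lambda B, G, R, RE, NIR: _guard(NIR - R, NIR + R),
     (-1.0, 1.0)),
    ("GNDVI", "(NIR - G) / (NIR + G)", lambda B, G, R, RE, NIR: _guard(NIR - G, NIR + G),
     (-1.0, 1.0)),
    ("NDRE", "(NIR - RE) / (NIR + RE)", lambda B, G, R, RE, NIR: _guard(NIR - RE, NIR + RE),
     (-1.0, 1.0)),
    ("RENDVI", "(RE - R) / (RE + R)", lambda B, G, R, RE, NIR: _guard(RE - R, RE + R),
     (-1.0, 1.0)),
    ("RVI", "NIR / R", lambda B, G, R, RE, NIR: _guard(NIR, R), (0.0, np.inf)),
    ("RERVI", "NIR / RE", lambda B, G, R, RE, NIR: _guard(NIR, RE), (0.0, np.inf)),
    ("PSRI", "(R - G) / NIR", lambda B, G, R, RE, NIR: _guard(R - G, NIR),
     (-np.inf, np.inf)),
    ("WSRI", "(RE - R) / (RE - B)", lambda B, G, R, RE, NIR: _guard(RE - R, RE - B),
     (-np.inf, np.inf)),
]

#: The ten-index registry.
VI_REGISTRY: dict[str, VIDefinition] = {
    name: VIDefinition(name, expr, fn, rng) for name, expr, fn, rng in _DEFS
}

#: Alternative labels seen in the literature for registry entries.
VI_ALIASES: dict[str, str] = {
    "NDVI-RE": "RENDVI",
    "RVI-RE": "RERVI",
    "MCTI": "MTCI",
}


def _resolve(name: str) -> VIDefinition:
    key = VI_ALIASES.get(name, name)
    try:
        return VI_REGISTRY[key]
    except KeyError:
        raise ValueError(
            f"unknown index {name!r}; valid names: {sorted(VI_REGISTRY)}"
        ) from None


def compute_index(grid: RasterGrid, name: str) -> RasterGrid:
    """Pixel-wise evaluation of a registry index on a 5-band reflectance raster."""
    if grid.value_kind != "reflectance":
        raise ValueError("indices are defined on reflectance rasters")
    definition = _resolve(name)
    required = ("B", "G", "R", "RE", "NIR")
    missing = [r for r in required if r not in grid.band_roles]
    if missing:
        raise ValueError(f"raster lacks band role(s) {missing}")
    bands = {r: grid.band(r).astype(np.float64) for r in required}
    with np.errstate(divide="ignore", invalid="ignore"):
        out = definition.func(**bands)
    invalid = ~grid.valid_mask()
    out = np.where(invalid, np.nan, out)
    return RasterGrid(
        values=out[None],
        band_roles=(definition.name,),
        gsd=grid.gsd,
        transform=grid.transform,
        value_kind="DN",  # index values are unbounded band arithmetic, not reflectance
        nodata=float("nan"),
    )


def index_summary(grid: RasterGrid, mask: np.ndarray | None = None) -> dict[str, float]:
    """Distribution statistics (mean, sd, quartiles, n) of an index raster.

    ``mask`` selects pixels (True = keep); nodata pixels are always dropped.
    Raises on an empty selection.
    """
    vals = grid.values[0]
    keep = ~np.isnan(vals)
    if mask is not None:
        if mask.shape != vals.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match raster shape {vals.shape}"
            )
        keep &= mask.astype(bool)
    sample = vals[keep]
    if sample.size == 0:
        raise ValueError("no valid pixels selected")
    q25, q50, q75 = np.percentile(sample, [25, 50, 75])
    return {
        "mean": float(sample.mean()),
        "sd": float(sample.std(ddof=1)) if sample.size > 1 else 0.0,
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "n": int(sample.size),
    }


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def separability_test(
    values_s: np.ndarray, values_r: np.ndarray
) -> tuple[float, float, str]:
    """Welch two-sample t-test between susceptible and resistant samples.

    Returns ``(t, p, stars)``; both samples need at least two observations.
    """
    values_s = np.asarray(values_s, float)
    values_r = np.asarray(values_r, float)
    values_s = values_s[~np.isnan(values_s)]
    values_r = values_r[~np.isnan(values_r)]
    if values_s.size < 2 or values_r.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    t, p = stats.ttest_ind(values_s, values_r, equal_var=False)
    if np.isnan(p):  # both samples constant and equal
        t, p = 0.0, 1.0
    return float(t), float(p), significance_stars(float(p))
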