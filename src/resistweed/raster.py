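"""Georeferenced raster container and GeoTIFF I/O.

A :class:`RasterGrid` holds a band-major pixel array together with the band
bookkeeping the rest of the pipeline relies on: which physical band each
plane is (blue .. near-infrared, or an RGB camera's channels), the ground
sampling distance, an affine pixel->world geotransform, whether values are
raw digital numbers or reflectance, and the nodata sentinel.

Files are plain (Geo)TIFFs written through :mod:`tifffile`; the geotransform
is stored in the standard GeoTIFF ModelPixelScale / ModelTiepoint tags, the
nodata value in the GDAL_NODATA tag, and the remaining bookkeeping as a JSON
ImageDescription, so round trips are bit exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Affine",
    "RasterGrid",
    "MS_BAND_ROLES",
    "RGB_BAND_ROLES",
    "BAND_CENTERS_NM",
    "read_raster",
    "write_raster",
]

#: Logical multispectral band order used everywhere in the package,
#: in order of center wavelength.
MS_BAND_ROLES: tuple[str, ...] = ("B", "G", "R", "RE", "NIR")

#: RGB camera channel order.
RGB_BAND_ROLES: tuple[str, ...] = ("red", "green", "blue")

#: Band center wavelengths (nm) for the multispectral camera.
BAND_CENTERS_NM: tuple[int, ...] = (450, 560, 650, 730, 840)

# GeoTIFF / GDAL tag codes used for round-tripping georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Affine:
    """Affine pixel->world map: ``x = a*col + b*row + c``, ``y = d*col + e*row + f``.

    North-up rasters have ``b = d = 0``, ``a > 0`` and ``e < 0`` (world y
    decreases as row index grows). Units are whatever the scene uses;
    this package works in centimetres.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, origin_x: float, origin_y: float, pixel_size: float) -> "Affine":
        return cls(pixel_size, 0.0, origin_x, 0.0, -pixel_size, origin_y)

    def xy(self, row: float, col: float) -> tuple[float, float]:
        """World coordinates of a (row, col) pixel index (pixel corner)."""
        return (
            self.a * col + self.b * row + self.c,
            self.d * col + self.e * row + self.f,
        )

    def rowcol(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (row, col) of a world point; inverse of :meth:`xy`."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("singular geotransform")
        dx, dy = x - self.c, y - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return row, col

    def to_coeffs(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


@dataclass
class RasterGrid:
    """Multi-band raster with band roles, GSD and georeferencing.

    Parameters
    ----------
    values
        ``(bands, rows, cols)`` float array; digital numbers or reflectance.
    band_roles
        One label per band, e.g. ``("B", "G", "R", "RE", "NIR")``.
    gsd
        Ground sampling distance in cm per pixel (> 0).
    transform
        Affine pixel->world geotransform (world units: cm).
    value_kind
        ``"DN"`` or ``"reflectance"``. Reflectance values must lie in
        [0, 1] wherever they are not nodata.
    nodata
        Sentinel for missing pixels (default NaN).
    """

    values: np.ndarray
    band_roles: tuple[str, ...]
    gsd: float
    transform: Affine = field(default=None)  # type: ignore[assignment]
    value_kind: str = "reflectance"
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError(f"values must be (bands, rows, cols), got shape {self.values.shape}")
        self.band_roles = tuple(self.band_roles)
        if len(self.band_roles) != self.values.shape[0]:
            raise ValueError(
                f"band_roles has {len(self.band_roles)} entries but the array "
                f"has {self.values.shape[0]} bands"
            )
        if self.gsd <= 0:
            raise ValueError("gsd must be > 0")
        if self.value_kind not in ("DN", "reflectance"):
            raise ValueError(f"value_kind must be 'DN' or 'reflectance', got {self.value_kind!r}")
        if self.transform is None:
            self.transform = Affine.north_up(0.0, self.shape[0] * self.gsd, self.gsd)
        if self.value_kind == "reflectance":
            valid = self.valid_mask()
            v = self.values[:, valid] if valid.ndim == 2 else self.values
            if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
                raise ValueError("reflectance values must lie in [0, 1] (or equal nodata)")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the grid."""
        return self.values.shape[1:]

    def band(self, role: str) -> np.ndarray:
        """2-D array of the band with the given role."""
        try:
            i = self.band_roles.index(role)
        except ValueError:
            raise KeyError(f"no band with role {role!r}; available: {self.band_roles}") from None
        return self.values[i]

    def valid_mask(self) -> np.ndarray:
        """Boolean (rows, cols) mask of pixels valid in *every* band."""
        if np.isnan(self.nodata):
            return ~np.isnan(self.values).any(axis=0)
        return ~(self.values == self.nodata).any(axis=0)

    def copy_with(self, **kwargs) -> "RasterGrid":
        out = replace(self, **kwargs) if kwargs else replace(self)
        return out

    def extent_cm(self) -> tuple[float, float]:
        """(width, height) of the footprint in world units (cm)."""
        rows, cols = self.shape
        return cols * self.gsd, rows * self.gsd


# -- I/O -------------------------------------------------------------------


def write_raster(grid: RasterGrid, path) -> None:
    """Write a :class:`RasterGrid` as a GeoTIFF (band-sequential pages)."""
    path = Path(path)
    meta = {
        "band_roles": list(grid.band_roles),
        "gsd": grid.gsd,
        "value_kind": grid.value_kind,
        "geotransform": grid.transform.to_coeffs(),
        "nodata": None if np.isnan(grid.nodata) else grid.nodata,
    }
    t = grid.transform
    origin_x, origin_y = t.c, t.f
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, origin_x, origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(
        path,
        grid.values,
        photometric="minisblack",
        planarconfig="separate" if grid.n_bands > 1 else None,
        description=json.dumps(meta),
        extratags=extratags,
    )


def read_raster(path, band_roles: tuple[str, ...] | None = None) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_raster`.

    ``band_roles`` may be passed to declare the expected roles; a mismatch
    with the file's band count raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        page = tif.pages[0]
        desc = page.description
    if values.ndim == 2:
        values = values[None]
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path} lacks the JSON raster metadata this package writes") from exc
    roles = tuple(meta["band_roles"])
    if band_roles is not None and tuple(band_roles) != roles:
        raise ValueError(
            f"{path}: declared band roles {tuple(band_roles)} do not match "
            f"stored roles {roles}"
        )
    if len(roles) != values.shape[0]:
        raise ValueError(
            f"{path}: file has {values.shape[0]} bands but metadata declares {len(roles)}"
        )
    stored_nodata = meta.get("nodata")
    nodata = float("nan") if stored_nodata is None else float(stored_nodata)
    gt = meta["geotransform"]
    return RasterGrid(
        values=values,
        band_roles=roles,
        gsd=float(meta["gsd"]),
        transform=Affine(*gt),
        value_kind=meta["value_kind"],
        nodata=nodata,
    )
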