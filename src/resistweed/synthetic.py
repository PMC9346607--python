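"""Synthetic UAV scene simulator with per-pixel ground truth.

Generates co-registered multispectral (5-band) + RGB scene pairs of a maize
field infested with two weeds — barnyardgrass (*Echinochloa crus-galli*, a
clustered grass) and velvetleaf (*Abutilon theophrasti*, a broadleaf growing
as separable individuals) — each present as herbicide-susceptible and
-resistant biotypes. Every scene carries exact per-pixel class and
resistance masks plus a per-block table of true day-14 death fractions, so
the whole downstream pipeline (calibration, fusion, indices, segmentation,
grading, classification) can be exercised and scored without field imagery.

The spectral model is deliberately simple and ordinal:

* each class has a 5-band mean reflectance signature (B, G, R, RE, NIR at
  450/560/650/730/840 nm) obeying the structure observed in real canopies —
  vegetation shows the red-edge jump (NIR/R > 3), soil does not; resistant
  biotypes sit slightly below susceptible ones in the visible bands and
  above them in red-edge/NIR; velvetleaf is brighter than barnyardgrass in
  the visible range;
* herbicide stress moves a signature linearly toward the soil signature
  with a per-class daily rate; susceptible biotypes degrade fast and
  monotonically, resistant biotypes degrade slowly and reverse (recover)
  after their recovery day — 4 days after application for barnyardgrass,
  later for velvetleaf;
* pixels are drawn independently per band from a normal around the
  (stress-adjusted) class mean with total standard deviation
  ``sqrt(sd_band**2 + noise_sd**2)``, clipped to [0, 1].

Spatial structure: maize in rows at 0.6 m spacing; barnyardgrass as
clustered blobs (a Thomas/Matérn-style parent-offspring process); velvetleaf
as isolated disks with a hard-core minimum spacing. Weed seeding density is
one of low/moderate/high = 40/160/320 plants per m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import MS_BAND_ROLES, RGB_BAND_ROLES, Affine, RasterGrid, write_raster

__all__ = [
    "SpectralSignature",
    "StressTrajectory",
    "SceneConfig",
    "SceneTruth",
    "CLASS_IDS",
    "CLASS_NAMES",
    "WEED_CLASSES",
    "DENSITY_SEEDS_PER_M2",
    "STUDY_DAYS",
    "default_signature_table",
    "default_trajectory_table",
    "apply_stress",
    "stressed_signature",
    "simulate_scene",
    "simulate_time_series",
    "write_scene",
]

#: Class-id encoding used in the per-pixel class mask.
CLASS_IDS: dict[str, int] = {
    "soil": 0,
    "maize": 1,
    "barnyardgrass_S": 2,
    "barnyardgrass_R": 3,
    "velvetleaf_S": 4,
    "velvetleaf_R": 5,
}
CLASS_NAMES: dict[int, str] = {v: k for k, v in CLASS_IDS.items()}
WEED_CLASSES: tuple[str, ...] = (
    "barnyardgrass_S",
    "barnyardgrass_R",
    "velvetleaf_S",
    "velvetleaf_R",
)

#: Weed seeding rates (plants per m^2) for the three density treatments.
DENSITY_SEEDS_PER_M2: dict[str, int] = {"low": 40, "moderate": 160, "high": 320}

#: Acquisition schedule in days relative to herbicide application
#: (-2 = before-application day, 0 = application day).
STUDY_DAYS: tuple[int, ...] = (-2, 0, 1, 2, 4, 5, 6, 7, 8, 10, 14)


@dataclass(frozen=True)
class SpectralSignature:
    """Per-class 5-band reflectance distribution (B, G, R, RE, NIR)."""

    class_name: str
    mean_reflectance: tuple[float, ...]
    sd_reflectance: tuple[float, ...]
    band_centers: tuple[int, ...] = (450, 560, 650, 730, 840)

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_reflectance, float)
        s = np.asarray(self.sd_reflectance, float)
        if m.shape != (5,) or s.shape != (5,):
            raise ValueError("signatures are 5-band (B, G, R, RE, NIR)")
        if np.any((m < 0) | (m > 1)):
            raise ValueError(f"{self.class_name}: mean reflectance must lie in [0, 1]")
        if np.any(s < 0):
            raise ValueError(f"{self.class_name}: sd must be >= 0")

    @property
    def mean(self) -> np.ndarray:
        return np.asarray(self.mean_reflectance, float)

    @property
    def sd(self) -> np.ndarray:
        return np.asarray(self.sd_reflectance, float)


@dataclass(frozen=True)
class StressTrajectory:
    """Herbicide-stress dynamics of one weed class.

    ``decline_rate`` is the per-day fraction by which the signature moves
    toward the soil signature after application. Susceptible biotypes have
    ``recovery_day=None`` and degrade monotonically (capped at 95% soil);
    resistant biotypes degrade until ``recovery_day`` and then relax back
    toward their unstressed signature.
    """

    class_name: str
    decline_rate: float
    recovery_day: int | None = None
    recovery_rate: float = 0.4  # exponential relaxation per day past recovery
    visible_lag_start: float = 3.0  # day visible yellowing begins
    visible_ramp_days: float = 8.0  # days for yellowing to reach full stress
    red_early_fraction: float = 0.15  # share of red response present before yellowing

    def stress_fraction(self, day: float) -> float:
        """Fraction of the way toward the soil signature at ``day``
        (the red-edge/NIR response; the visible bands lag, see
        :meth:`band_stress`)."""
        if day <= 0 or self.decline_rate == 0:
            return 0.0
        if self.recovery_day is None:
            return min(self.decline_rate * day, 0.95)
        if day <= self.recovery_day:
            return self.decline_rate * day
        peak = self.decline_rate * self.recovery_day
        return peak * math.exp(-self.recovery_rate * (day - self.recovery_day))

    def band_stress(self, day: float) -> np.ndarray:
        """Per-band stress fractions over (B, G, R, RE, NIR).

        Photosystem damage shows first in the chlorophyll-linked red-edge
        and NIR response, which carry the full stress fraction
        immediately. Red — the chlorophyll absorption band — shows a
        partial early response (``red_early_fraction``); blue and green
        discoloration (visible yellowing) only begins around
        ``visible_lag_start`` days after application and ramps up over
        ``visible_ramp_days``, with red completing alongside it.
        """
        s = self.stress_fraction(day)
        if day <= 0:
            return np.zeros(5)
        ramp = min(max((day - self.visible_lag_start) / self.visible_ramp_days, 0.0), 1.0)
        lag = s * ramp
        red = s * (self.red_early_fraction + (1.0 - self.red_early_fraction) * ramp)
        return np.array([lag, lag, red, s, s])


def default_signature_table() -> dict[str, SpectralSignature]:
    """Canonical unstressed signatures for the six scene classes.

    Absolute levels are free parameters of the simulator; what is fixed is
    the ordinal structure: the soil line is nearly flat (NIR/R ~ 1.2),
    vegetation has the red-edge jump (NIR/R > 3), resistant biotypes sit at
    or below susceptible ones in the visible bands and above them at
    red-edge/NIR, and velvetleaf is brighter than barnyardgrass in the
    visible range.
    """
    sd_soil = (0.008, 0.008, 0.009, 0.009, 0.010)
    sd_veg = (0.004, 0.005, 0.005, 0.008, 0.010)
    table = {
        "soil": SpectralSignature("soil", (0.10, 0.14, 0.18, 0.20, 0.22), sd_soil),
        "maize": SpectralSignature("maize", (0.044, 0.095, 0.046, 0.330, 0.480), sd_veg),
        "barnyardgrass_S": SpectralSignature(
            "barnyardgrass_S", (0.046, 0.085, 0.058, 0.260, 0.400), sd_veg
        ),
        "barnyardgrass_R": SpectralSignature(
            "barnyardgrass_R", (0.044, 0.082, 0.056, 0.300, 0.460), sd_veg
        ),
        "velvetleaf_S": SpectralSignature(
            "velvetleaf_S", (0.058, 0.105, 0.075, 0.330, 0.430), sd_veg
        ),
        "velvetleaf_R": SpectralSignature(
            "velvetleaf_R", (0.056, 0.102, 0.073, 0.350, 0.470), sd_veg
        ),
    }
    return table


def default_trajectory_table() -> dict[str, StressTrajectory]:
    """Stress dynamics: fast monotone decline for susceptible biotypes,
    slow decline with recovery for resistant ones (barnyardgrass recovers
    from day 4, velvetleaf — a species with a longer stress response —
    from day 7); maize is tolerant to the herbicide and soil is inert."""
    return {
        "soil": StressTrajectory("soil", 0.0),
        "maize": StressTrajectory("maize", 0.0),
        "barnyardgrass_S": StressTrajectory("barnyardgrass_S", 0.120, None),
        "barnyardgrass_R": StressTrajectory("barnyardgrass_R", 0.020, 4),
        "velvetleaf_S": StressTrajectory("velvetleaf_S", 0.100, None),
        "velvetleaf_R": StressTrajectory("velvetleaf_R", 0.020, 7),
    }


def apply_stress(
    signature: SpectralSignature,
    trajectory: StressTrajectory,
    day: float,
    soil: SpectralSignature | None = None,
) -> SpectralSignature:
    """Stress-adjusted signature at ``day`` days after application.

    Moves the mean linearly toward the soil signature by the trajectory's
    stress fraction; day 0 (and any day before application) is the identity.
    """
    if soil is None:
        soil = default_signature_table()["soil"]
    s = trajectory.band_stress(day)
    mean = (1.0 - s) * signature.mean + s * soil.mean
    return replace(signature, mean_reflectance=tuple(mean))


def stressed_signature(
    class_name: str,
    day: float,
    signatures: dict[str, SpectralSignature] | None = None,
    trajectories: dict[str, StressTrajectory] | None = None,
) -> SpectralSignature:
    """Signature of a named class at a given day; unknown names raise."""
    signatures = signatures or default_signature_table()
    trajectories = trajectories or default_trajectory_table()
    if class_name not in signatures:
        raise KeyError(
            f"unknown class {class_name!r}; known classes: {sorted(signatures)}"
        )
    return apply_stress(
        signatures[class_name], trajectories[class_name], day, soil=signatures["soil"]
    )


@dataclass
class SceneConfig:
    """Scene geometry, density treatment, sensor GSDs and noise.

    Defaults mirror the field study: 3 m x 5 m plots in rows at 0.6 m
    spacing, weed densities low/moderate/high = 40/160/320 plants m^-2, and
    multispectral/RGB ground sampling distances of 0.79/0.41 cm per pixel.
    """

    plot_rows: int = 1
    plot_cols: int = 1
    density: str = "moderate"
    ms_gsd: float = 0.79
    rgb_gsd: float = 0.41
    noise_sd: float = 0.005
    brightness_cv: float = 0.20  # per-plant multiplicative canopy variability
    block_brightness_cv: float = 0.15  # shared within a weed block (illumination)
    rgb_brightness_cv: float = 0.10  # extra per-block RGB-only variability
    rgb_chroma_cv: float = 0.20  # per-block, per-channel RGB color jitter
    # (the RGB camera is not radiometrically calibrated, so its brightness
    # and color balance carry uncorrected illumination effects — shadow
    # color, sun angle, white balance — on top of canopy variability)
    seed: int = 0
    day: int = 0
    plot_width_m: float = 5.0
    plot_height_m: float = 3.0
    row_spacing_m: float = 0.6
    velvetleaf_fraction: float = 0.15
    cluster_size: float = 20.0
    cluster_radius_m: float = 0.12
    block_spacing_m: float = 0.45
    hardcore_distance_m: float = 0.15
    resistant_fraction_bg: float = 0.447  # 3128 / 7000 resistant observations
    resistant_fraction_vl: float = 0.592  # 1136 / 1920 resistant observations
    # day-14 death-fraction ranges per block biotype; the block grade
    # (resistant = level <= 3 = death <= 0.75) follows from the draw
    death_range_resistant: tuple[float, float] = (0.05, 0.65)
    death_range_susceptible: tuple[float, float] = (0.80, 1.0)
    signatures: dict[str, SpectralSignature] = field(default_factory=default_signature_table)
    trajectories: dict[str, StressTrajectory] = field(default_factory=default_trajectory_table)

    def __post_init__(self) -> None:
        if self.density not in DENSITY_SEEDS_PER_M2:
            raise ValueError(
                f"density must be one of {sorted(DENSITY_SEEDS_PER_M2)}, got {self.density!r}"
            )
        if not (0 < self.rgb_gsd < self.ms_gsd):
            raise ValueError("rgb_gsd must be positive and smaller than ms_gsd")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def extent_cm(self) -> tuple[float, float]:
        """(width, height) of the scene footprint in cm."""
        return (
            self.plot_cols * self.plot_width_m * 100.0,
            self.plot_rows * self.plot_height_m * 100.0,
        )


@dataclass
class SceneTruth:
    """Ground truth on the multispectral grid.

    ``class_mask``: uint8 class ids (see :data:`CLASS_IDS`);
    ``resistance_mask``: int8, 1 = resistant weed pixel, 0 = susceptible
    weed pixel, -1 elsewhere; ``block_table``: one row per weed block /
    plant with world-cm bounds and the true day-14 death fraction.
    """

    class_mask: np.ndarray
    resistance_mask: np.ndarray
    block_table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.class_mask.shape != self.resistance_mask.shape:
            raise ValueError("class and resistance masks must share a shape")
        df = self.block_table
        if len(df) and not df["death_fraction_day14"].between(0, 1).all():
            raise ValueError("block death fractions must lie in [0, 1]")


# -- spatial layout --------------------------------------------------------


@dataclass
class _Plant:
    x: float  # cm
    y: float  # cm
    radius: float  # cm
    class_name: str
    block_id: int


def _build_layout(config: SceneConfig, rng: np.random.Generator):
    """Place maize, barnyardgrass clusters and velvetleaf individuals.

    Returns (plants, block_table). Spatial layout is drawn once per scene
    seed and shared across acquisition days.
    """
    width, height = config.extent_cm
    plants: list[_Plant] = []
    blocks: list[dict] = []

    # maize rows: horizontal lines at the study row spacing, plants ~25 cm apart
    row_gap = config.row_spacing_m * 100.0
    y = row_gap / 2.0
    while y < height:
        x = 12.5
        while x < width:
            plants.append(_Plant(x, y, 6.0, "maize", -1))
            x += 25.0
        y += row_gap

    area_m2 = width * height / 1e4
    rate = DENSITY_SEEDS_PER_M2[config.density]
    n_weeds = int(rng.poisson(rate * area_m2))
    n_vl = int(round(config.velvetleaf_fraction * n_weeds))
    n_bg = n_weeds - n_vl

    # barnyardgrass: Thomas-style cluster process; one block per cluster,
    # all plants in a block share a biotype (block-level resistance)
    block_id = 0
    if n_bg > 0:
        n_clusters = max(1, int(round(n_bg / config.cluster_size)))
        counts = rng.multinomial(n_bg, np.full(n_clusters, 1.0 / n_clusters))
        sigma = config.cluster_radius_m * 100.0
        # blocks are gradable units: parents keep a soft hard-core spacing
        # so neighboring blocks of opposite biotypes rarely merge
        spacing = config.block_spacing_m * 100.0
        parents: list[tuple[float, float]] = []
        tries = 0
        while len(parents) < n_clusters and tries < 80 * n_clusters:
            tries += 1
            cand = (rng.uniform(0, width), rng.uniform(0, height))
            if all((cand[0] - qx) ** 2 + (cand[1] - qy) ** 2 >= spacing**2
                   for qx, qy in parents):
                parents.append(cand)
        while len(parents) < n_clusters:  # dense fallback: accept crowding
            parents.append((rng.uniform(0, width), rng.uniform(0, height)))
        for (px, py), count in zip(parents, counts):
            if count == 0:
                continue
            resistant = rng.random() < config.resistant_fraction_bg
            xs = np.clip(px + rng.normal(0, sigma, count), 1.0, width - 1.0)
            ys = np.clip(py + rng.normal(0, sigma, count), 1.0, height - 1.0)
            death = rng.uniform(
                *(config.death_range_resistant if resistant
                  else config.death_range_susceptible)
            )
            # per-plant survival realizes the block's death fraction:
            # dying plants follow the susceptible trajectory, survivors
            # the resistant one, so boundary-grade blocks are genuinely
            # ambiguous — as graded field blocks are
            dying = rng.random(count) < death
            for x, yy, dies in zip(xs, ys, dying):
                cname = "barnyardgrass_S" if dies else "barnyardgrass_R"
                plants.append(_Plant(float(x), float(yy), 4.5, cname, block_id))
            pad = 4.0
            blocks.append(
                dict(
                    block_id=block_id,
                    species="barnyardgrass",
                    xmin=float(xs.min() - pad),
                    ymin=float(ys.min() - pad),
                    xmax=float(xs.max() + pad),
                    ymax=float(ys.max() + pad),
                    death_fraction_day14=float(death),
                    n_plants=int(count),
                    resistant=bool(resistant),
                )
            )
            block_id += 1

    # velvetleaf: hard-core point process (isolated individuals)
    if n_vl > 0:
        hc = config.hardcore_distance_m * 100.0
        accepted: list[tuple[float, float]] = []
        attempts = 0
        while len(accepted) < n_vl and attempts < 50 * n_vl:
            attempts += 1
            x, yy = rng.uniform(1, width - 1), rng.uniform(1, height - 1)
            if all((x - ax) ** 2 + (yy - ay) ** 2 >= hc * hc for ax, ay in accepted):
                accepted.append((x, yy))
        for x, yy in accepted:
            resistant = rng.random() < config.resistant_fraction_vl
            cname = "velvetleaf_R" if resistant else "velvetleaf_S"
            r = 7.0
            plants.append(_Plant(x, yy, r, cname, block_id))
            blocks.append(
                dict(
                    block_id=block_id,
                    species="velvetleaf",
                    xmin=x - r,
                    ymin=yy - r,
                    xmax=x + r,
                    ymax=yy + r,
                    death_fraction_day14=0.0 if resistant else 1.0,
                    n_plants=1,
                    resistant=bool(resistant),
                )
            )
            block_id += 1

    cols = [
        "block_id",
        "species",
        "xmin",
        "ymin",
        "xmax",
        "ymax",
        "death_fraction_day14",
        "n_plants",
        "resistant",
    ]
    block_table = pd.DataFrame(blocks, columns=cols)
    return plants, block_table


def _rasterize_classes(
    plants: list[_Plant], width: float, height: float, gsd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Paint plant disks onto class-id and plant-index grids.

    Soil is class 0 / plant index -1; weeds overprint maize where they
    overlap (weed canopy sits above the young crop).
    """
    rows = int(round(height / gsd))
    cols = int(round(width / gsd))
    mask = np.zeros((rows, cols), dtype=np.uint8)
    plant_map = np.full((rows, cols), -1, dtype=np.int32)
    for pass_weeds in (False, True):
        for pi, p in enumerate(plants):
            is_weed = p.class_name in WEED_CLASSES
            if is_weed != pass_weeds:
                continue
            r_px = p.radius / gsd
            crow = (height - p.y) / gsd
            ccol = p.x / gsd
            r0 = max(0, int(math.floor(crow - r_px)))
            r1 = min(rows, int(math.ceil(crow + r_px)) + 1)
            c0 = max(0, int(math.floor(ccol - r_px)))
            c1 = min(cols, int(math.ceil(ccol + r_px)) + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            inside = (rr + 0.5 - crow) ** 2 + (cc + 0.5 - ccol) ** 2 <= r_px**2
            mask[r0:r1, c0:c1][inside] = CLASS_IDS[p.class_name]
            plant_map[r0:r1, c0:c1][inside] = pi
    return mask, plant_map


def _render_bands(
    class_mask: np.ndarray,
    plant_map: np.ndarray,
    plant_factors: np.ndarray,
    band_indices: list[int],
    day: float,
    config: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-pixel reflectance for the requested signature bands.

    Pixel = plant brightness factor x stressed class mean + Gaussian noise
    (total sd = sqrt(band sd^2 + noise_sd^2)), clipped to [0, 1]. The
    multiplicative plant factor models canopy-scale brightness variability
    (plant size, leaf angle, micro-illumination) common to all bands —
    which ratio indices cancel but raw reflectance does not.
    """
    out = np.empty((len(band_indices),) + class_mask.shape, dtype=np.float64)
    plant_factors = np.atleast_2d(plant_factors)  # (1 or n_out_bands, n_plants)
    planted = plant_map >= 0
    factor = np.ones((plant_factors.shape[0],) + class_mask.shape)
    if plant_factors.shape[1]:
        factor[:, planted] = plant_factors[:, plant_map[planted]]
    for cid in np.unique(class_mask):
        cname = CLASS_NAMES[int(cid)]
        sig = stressed_signature(cname, day, config.signatures, config.trajectories)
        sel = class_mask == cid
        n = int(sel.sum())
        for bi, b in enumerate(band_indices):
            f = factor[min(bi, factor.shape[0] - 1)][sel]
            total_sd = math.hypot(float(sig.sd[b]), config.noise_sd)
            base = f * sig.mean[b]
            vals = base if total_sd == 0 else base + rng.normal(0.0, total_sd, n)
            out[bi][sel] = np.clip(vals, 0.0, 1.0)
    return out


def simulate_scene(
    config: SceneConfig, day: int | None = None
) -> tuple[RasterGrid, RasterGrid, SceneTruth]:
    """Simulate one co-registered multispectral + RGB scene pair.

    The spatial layout is a deterministic function of ``config.seed``; the
    spectral rendering additionally depends on the acquisition day, so a
    time series over one layout only evolves its spectra. Identical configs
    give bit-identical output.
    """
    if day is None:
        day = config.day
    width, height = config.extent_cm
    ms_rows = int(round(height / config.ms_gsd))
    ms_cols = int(round(width / config.ms_gsd))
    if ms_rows < 8 or ms_cols < 8:
        raise ValueError(
            f"scene extent {width:.0f}x{height:.0f} cm is too small to hold one "
            f"plot at ms_gsd={config.ms_gsd} (grid {ms_rows}x{ms_cols})"
        )

    layout_rng = np.random.default_rng([config.seed, 0])
    plants, block_table = _build_layout(config, layout_rng)
    # brightness is a persistent canopy property: drawn from the layout
    # stream so it is identical across acquisition days. It has a
    # per-plant component and a component shared within each weed block
    # (local illumination / soil moisture), which does not average out
    # over a block's plants.
    plant_factors = (
        np.exp(layout_rng.normal(0.0, config.brightness_cv, len(plants)))
        if config.brightness_cv > 0
        else np.ones(len(plants))
    )
    if config.block_brightness_cv > 0 and len(block_table):
        block_factors = np.exp(
            layout_rng.normal(0.0, config.block_brightness_cv, len(block_table))
        )
        for pi, p in enumerate(plants):
            if p.block_id >= 0:
                plant_factors[pi] *= block_factors[p.block_id]

    render_rng = np.random.default_rng([config.seed, 1000 + int(day) + 2])

    class_mask, plant_map = _rasterize_classes(plants, width, height, config.ms_gsd)
    ms_values = _render_bands(
        class_mask, plant_map, plant_factors, [0, 1, 2, 3, 4], day, config, render_rng
    )
    ms = RasterGrid(
        values=ms_values,
        band_roles=MS_BAND_ROLES,
        gsd=config.ms_gsd,
        transform=Affine.north_up(0.0, height, config.ms_gsd),
        value_kind="reflectance",
    )

    rgb_mask, rgb_plant_map = _rasterize_classes(plants, width, height, config.rgb_gsd)
    # RGB camera senses the visible range: channels map to the R, G, B
    # signature entries on the finer grid with independent noise. The RGB
    # sensor is not radiometrically calibrated, so an extra per-day,
    # per-block illumination factor applies to its render only.
    rgb_factors = np.tile(plant_factors, (3, 1))  # per RGB channel (R, G, B order)
    n_blocks = len(block_table)
    if n_blocks and (config.rgb_brightness_cv > 0 or config.rgb_chroma_cv > 0):
        rgb_block = np.exp(
            render_rng.normal(0.0, config.rgb_brightness_cv, n_blocks)
        )
        chroma = np.exp(render_rng.normal(0.0, config.rgb_chroma_cv, (3, n_blocks)))
        for pi, p in enumerate(plants):
            if p.block_id >= 0:
                rgb_factors[:, pi] *= rgb_block[p.block_id] * chroma[:, p.block_id]
    rgb_values = _render_bands(
        rgb_mask, rgb_plant_map, rgb_factors, [2, 1, 0], day, config, render_rng
    )
    rgb = RasterGrid(
        values=rgb_values,
        band_roles=RGB_BAND_ROLES,
        gsd=config.rgb_gsd,
        transform=Affine.north_up(0.0, height, config.rgb_gsd),
        value_kind="reflectance",
    )

    weed_ids = [CLASS_IDS[c] for c in WEED_CLASSES]
    resistant_ids = [CLASS_IDS["barnyardgrass_R"], CLASS_IDS["velvetleaf_R"]]
    resistance = np.full(class_mask.shape, -1, dtype=np.int8)
    resistance[np.isin(class_mask, weed_ids)] = 0
    resistance[np.isin(class_mask, resistant_ids)] = 1

    truth = SceneTruth(class_mask=class_mask, resistance_mask=resistance, block_table=block_table)
    return ms, rgb, truth


def simulate_time_series(
    config: SceneConfig, days: list[int], schedule: tuple[int, ...] = STUDY_DAYS
) -> list[tuple[RasterGrid, RasterGrid, SceneTruth]]:
    """One scene pair per acquisition day over a fixed spatial layout.

    ``days`` must be distinct members of the acquisition schedule.
    """
    if len(set(days)) != len(days):
        raise ValueError(f"duplicate days in {days}")
    bad = [d for d in days if d not in schedule]
    if bad:
        raise ValueError(f"days {bad} are not in the acquisition schedule {schedule}")
    return [simulate_scene(config, day=d) for d in days]


def write_scene(out_dir, ms: RasterGrid, rgb: RasterGrid, truth: SceneTruth) -> dict[str, Path]:
    """Write a scene pair plus ground truth to a directory.

    Produces ``ms.tif``, ``rgb.tif``, ``class_mask.tif``,
    ``resistance_mask.tif`` and ``blocks.csv``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ms": out_dir / "ms.tif",
        "rgb": out_dir / "rgb.tif",
        "class_mask": out_dir / "class_mask.tif",
        "resistance_mask": out_dir / "resistance_mask.tif",
        "blocks": out_dir / "blocks.csv",
    }
    write_raster(ms, paths["ms"])
    write_raster(rgb, paths["rgb"])
    mask_grid = RasterGrid(
        values=truth.class_mask.astype(np.float64)[None],
        band_roles=("class_id",),
        gsd=ms.gsd,
        transform=ms.transform,
        value_kind="DN",
    )
    write_raster(mask_grid, paths["class_mask"])
    res_grid = RasterGrid(
        values=truth.resistance_mask.astype(np.float64)[None],
        band_roles=("resistance",),
        gsd=ms.gsd,
        transform=ms.transform,
        value_kind="DN",
    )
    write_raster(res_grid, paths["resistance_mask"])
    truth.block_table.to_csv(paths["blocks"], index=False)
    return paths
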