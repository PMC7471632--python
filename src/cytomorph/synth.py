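"""Synthetic Nissl-like sections with exact ground truth.

The generator emulates the statistical structure of a Nissl-stained cortical
strip: six horizontal laminar bands of dark elliptical somata on a light
background, with per-layer and per-hemisphere-side distributions of cell
area, elongation and packing density, plus the nuisance structure a real
section carries — sub-threshold glial specks (< 25 μm²), super-threshold
staining artifacts (> 400 μm²), excluded vessels, a smooth illumination
gradient and additive noise.

Cell areas follow a lognormal law (positive support, right skew, as observed
in segmented soma populations), parameterised by the mean on the natural
scale and a coefficient of variation.  Elongation is ``AR = 1 + Gamma``.
Somata are rendered as hard (non-anti-aliased) filled ellipses so that the
true pixel area is countable, and are placed by rejection sampling so that
no two objects approach within a configurable gap.

Default parameters reproduce the published layer-by-side group means for
chimpanzee area 44: mean soma areas per layer and side, neighbour-count
densities within a 50 μm radius, and mean aspect ratios.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .image import EXCLUDED, CalibratedImage, LayerMap

SIDES = ("left", "right")
_SIDE_CODE = {"left": 0, "right": 1}

#: Radius (μm) of the neighbour-count density descriptor.
DENSITY_RADIUS_UM = 50.0
_DISK_AREA_MM2 = math.pi * (DENSITY_RADIUS_UM / 1000.0) ** 2  # ≈ 0.007854 mm²


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass
class LayerSpec:
    """Generative description of one cortical layer on one side.

    Parameters
    ----------
    layer_id : int
        Layer number 1-6 (L1 molecular ... L6 multiform).
    thickness : float
        Band thickness in μm.
    cell_count_per_mm2 : float
        Areal density of soma centroids.  Use
        :func:`count_density_from_neighbors` to derive it from a mean
        neighbour count within 50 μm.
    area_mean : float
        Mean soma area in μm² (lognormal location on the natural scale).
    area_cv : float
        Coefficient of variation of soma area (unitless).
    ar_mean : float
        Mean aspect ratio (major/minor axis), ≥ 1.
    intensity_mean : float
        Stain darkness: how far below the local background, in intensity
        units on [0, 1], a soma's pixels sit before noise.
    """

    layer_id: int
    thickness: float
    cell_count_per_mm2: float
    area_mean: float
    area_cv: float = 0.6
    ar_mean: float = 1.5
    intensity_mean: float = 0.45

    def __post_init__(self) -> None:
        if self.layer_id not in (1, 2, 3, 4, 5, 6):
            raise ConfigError(f"layer_id must be 1..6, got {self.layer_id}")
        if not self.thickness > 0:
            raise ConfigError("thickness must be > 0")
        if self.cell_count_per_mm2 < 0:
            raise ConfigError("cell_count_per_mm2 must be >= 0")
        if not self.area_mean > 0:
            raise ConfigError("area_mean must be > 0")
        if self.area_cv < 0:
            raise ConfigError("area_cv must be >= 0")
        if self.ar_mean < 1:
            raise ConfigError("ar_mean must be >= 1")

    @property
    def neighbor_mean(self) -> float:
        """Expected neighbour count within 50 μm implied by the density."""
        return self.cell_count_per_mm2 * _DISK_AREA_MM2


def count_density_from_neighbors(neighbor_mean: float) -> float:
    """Convert a mean neighbour count within 50 μm to cells per mm²."""
    return neighbor_mean / _DISK_AREA_MM2


@dataclasses.dataclass
class SynthConfig:
    """Full configuration of a synthetic study.

    One config describes both hemispheres; :func:`generate_section` renders
    one side of it.  ``gap_um`` is the minimum boundary-to-boundary distance
    enforced between rendered objects so that somata never merge into one
    connected component; set ``allow_overlap`` to exercise clumped tissue.
    """

    layers_left: list[LayerSpec]
    layers_right: list[LayerSpec]
    microns_per_pixel: float = 0.5
    strip_width: float = 400.0
    background_level: float = 0.85
    gradient_amplitude: float = 0.1
    noise_sd: float = 0.03
    n_glial_specks: int = 40
    n_large_artifacts: int = 3
    n_vessels: int = 1
    seed: int = 0
    gap_um: float = 1.5
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ConfigError("microns_per_pixel must be > 0")
        if not self.strip_width > 0:
            raise ConfigError("strip_width must be > 0")
        for specs in (self.layers_left, self.layers_right):
            if len(specs) != 6:
                raise ConfigError("exactly 6 layer specs required per side")
            if [s.layer_id for s in specs] != [1, 2, 3, 4, 5, 6]:
                raise ConfigError("layer specs must be ordered L1..L6")
        if not 0 <= self.background_level <= 1:
            raise ConfigError("background_level must lie in [0, 1]")

    def layers(self, side: str) -> list[LayerSpec]:
        if side not in SIDES:
            raise ConfigError(f"side must be one of {SIDES}, got {side!r}")
        return self.layers_left if side == "left" else self.layers_right


# Published layer-by-side group means for chimpanzee area 44 used as the
# generator's default study conditions: soma area (μm²), mean neighbour
# count within 50 μm, and mean aspect ratio, for layers L1..L6.
AREA_MEANS_UM2 = {
    "left": (82.9, 77.5, 111.0, 85.7, 110.0, 107.0),
    "right": (80.6, 93.8, 115.0, 91.8, 119.0, 110.0),
}
NEIGHBOR_MEANS = {
    "left": (12.4, 18.2, 16.1, 17.6, 15.7, 14.5),
    "right": (22.1, 18.4, 16.8, 16.6, 14.8, 14.6),
}
AR_MEANS = (1.4, 1.5, 1.5, 1.5, 1.5, 1.55)
# CVs reproduce the reported interquartile spread of gated soma areas:
# wider in the pyramidal layers (L3, L5, L6) than the granular ones.
AREA_CVS = (0.55, 0.55, 0.65, 0.55, 0.65, 0.65)
LAYER_THICKNESS_UM = (220.0, 180.0, 620.0, 150.0, 420.0, 500.0)


def default_layer_specs(side: str) -> list[LayerSpec]:
    """Layer specs parameterised from the published group means."""
    if side not in SIDES:
        raise ConfigError(f"side must be one of {SIDES}, got {side!r}")
    return [
        LayerSpec(
            layer_id=i + 1,
            thickness=LAYER_THICKNESS_UM[i],
            cell_count_per_mm2=count_density_from_neighbors(NEIGHBOR_MEANS[side][i]),
            area_mean=AREA_MEANS_UM2[side][i],
            area_cv=AREA_CVS[i],
            ar_mean=AR_MEANS[i],
        )
        for i in range(6)
    ]


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The default study conditions: both sides from the published means."""
    return SynthConfig(
        layers_left=default_layer_specs("left"),
        layers_right=default_layer_specs("right"),
        seed=seed,
        **overrides,
    )


def asymmetry_config(seed: int = 0, max_other_gap: float = 4.0, **overrides) -> SynthConfig:
    """Study conditions isolating the L2 asymmetry as the dominant interaction.

    The published layer-by-side soma-area means, with every side gap outside
    L2 capped at ``max_other_gap`` μm² (the right-side mean is pulled toward
    the left one where needed) so that the layer x side interaction is
    carried by the large L2 gap (77.5 left vs 93.8 right μm²).
    """
    left = default_layer_specs("left")
    right = default_layer_specs("right")
    for i in range(6):
        if i == 1:  # L2 keeps its full published gap
            continue
        lo, hi = left[i].area_mean, right[i].area_mean
        if abs(hi - lo) > max_other_gap:
            right[i] = dataclasses.replace(
                right[i], area_mean=lo + math.copysign(max_other_gap, hi - lo)
            )
    return SynthConfig(layers_left=left, layers_right=right, seed=seed, **overrides)


def uniform_config(
    seed: int = 0,
    area_mean: float = 95.0,
    area_cv: float = 0.6,
    ar_mean: float = 1.5,
    neighbor_mean: float = 16.0,
    **overrides,
) -> SynthConfig:
    """A null configuration: every layer on every side shares one law.

    Used for type-I-error calibration of the downstream ANOVA, where no
    layer, side or interaction effect truly exists.
    """
    def specs() -> list[LayerSpec]:
        return [
            LayerSpec(
                layer_id=i + 1,
                thickness=LAYER_THICKNESS_UM[i],
                cell_count_per_mm2=count_density_from_neighbors(neighbor_mean),
                area_mean=area_mean,
                area_cv=area_cv,
                ar_mean=ar_mean,
            )
            for i in range(6)
        ]

    return SynthConfig(layers_left=specs(), layers_right=specs(), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# sampling primitives

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of log-area for a given natural-scale mean and CV."""
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _sample_areas(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    mu, sigma = _lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size=n)


def _sample_ars(rng: np.random.Generator, n: int, ar_mean: float) -> np.ndarray:
    # AR - 1 ~ Gamma(shape 4): mean ar_mean, elongation CV 0.5, support > 1.
    if ar_mean <= 1.0:
        return np.ones(n)
    return 1.0 + rng.gamma(4.0, (ar_mean - 1.0) / 4.0, size=n)


def _axes_from_area_ar(area: float, ar: float) -> tuple[float, float]:
    """Semi-axes (a, b) of an ellipse with given area and a/b ratio."""
    b = math.sqrt(area / (math.pi * ar))
    return b * ar, b


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _ellipse_pixels(
    cx: float, cy: float, a: float, b: float, theta: float,
    mpp: float, shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixel centers inside the ellipse (hard mask)."""
    ct, st = math.cos(theta), math.sin(theta)
    ex = math.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = math.sqrt((a * st) ** 2 + (b * ct) ** 2)
    c0 = max(0, int(math.floor((cx - ex) / mpp)))
    c1 = min(shape[1] - 1, int(math.ceil((cx + ex) / mpp)))
    r0 = max(0, int(math.floor((cy - ey) / mpp)))
    r1 = min(shape[0] - 1, int(math.ceil((cy + ey) / mpp)))
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    dx = cols[None, :] * mpp - cx
    dy = rows[:, None] * mpp - cy
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


class _Canvas:
    """Occupancy-tracked raster onto which ellipses are placed and painted."""

    def __init__(self, shape: tuple[int, int], mpp: float, gap_um: float,
                 allow_overlap: bool, rng: np.random.Generator):
        self.shape = shape
        self.mpp = mpp
        self.gap = gap_um
        self.allow_overlap = allow_overlap
        self.rng = rng
        self.occupied = np.zeros(shape, dtype=bool)
        self.darkness = np.zeros(shape, dtype=np.float64)

    def try_place(
        self, a: float, b: float, theta: float,
        x_range: tuple[float, float], y_range: tuple[float, float],
        contrast: float, max_attempts: int = 200,
    ) -> tuple[float, float] | None:
        """Place one ellipse of semi-axes (a, b) at orientation theta.

        The center is drawn uniformly from the admissible box that keeps the
        whole ellipse inside ``x_range`` x ``y_range``; a candidate is
        accepted when its footprint, expanded by the configured gap, is free.
        Returns the center (μm) or None after ``max_attempts`` rejections.
        """
        ct, st = math.cos(theta), math.sin(theta)
        ex = math.sqrt((a * ct) ** 2 + (b * st) ** 2)
        ey = math.sqrt((a * st) ** 2 + (b * ct) ** 2)
        x0, x1 = x_range[0] + ex, x_range[1] - ex
        y0, y1 = y_range[0] + ey, y_range[1] - ey
        if x1 <= x0 or y1 <= y0:
            return None  # object does not fit in the band
        for _ in range(max_attempts):
            cx = self.rng.uniform(x0, x1)
            cy = self.rng.uniform(y0, y1)
            if not self.allow_overlap:
                rr, cc = _ellipse_pixels(
                    cx, cy, a + self.gap, b + self.gap, theta, self.mpp, self.shape
                )
                if self.occupied[rr, cc].any():
                    continue
            rr, cc = _ellipse_pixels(cx, cy, a, b, theta, self.mpp, self.shape)
            if rr.size == 0:
                continue
            self.occupied[rr, cc] = True
            self.darkness[rr, cc] = np.maximum(self.darkness[rr, cc], contrast)
            return cx, cy
        return None


def _band_edges_px(specs: list[LayerSpec], mpp: float) -> list[tuple[int, int]]:
    """Pixel row span [r0, r1) of each layer band, stacked top to bottom."""
    edges = []
    top_um = 0.0
    for spec in specs:
        r0 = int(round(top_um / mpp))
        r1 = int(round((top_um + spec.thickness) / mpp))
        edges.append((r0, r1))
        top_um += spec.thickness
    return edges


def generate_section(
    config: SynthConfig, side: str
) -> tuple[CalibratedImage, LayerMap, pd.DataFrame]:
    """Render one synthetic section of the given hemisphere side.

    Returns the calibrated image, the aligned layer map, and the ground
    truth table with one row per rendered soma: centroid (μm), analytic
    area (μm²), major/minor axis lengths (μm) and orientation (radians).
    Identical ``(config, side)`` always yields bit-identical outputs.
    """
    specs = config.layers(side)
    mpp = config.microns_per_pixel
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _SIDE_CODE[side]])
    )

    bands = _band_edges_px(specs, mpp)
    height_px = bands[-1][1]
    width_px = max(1, int(round(config.strip_width / mpp)))
    shape = (height_px, width_px)

    labels = np.zeros(shape, dtype=np.uint8)
    for spec, (r0, r1) in zip(specs, bands):
        labels[r0:r1, :] = spec.layer_id

    canvas = _Canvas(shape, mpp, config.gap_um, config.allow_overlap, rng)
    strip_x = (0.0, width_px * mpp)

    # Vessels first: excluded regions that nothing else may invade.
    for _ in range(config.n_vessels):
        area = rng.uniform(2000.0, 6000.0)
        ar = rng.uniform(1.0, 2.0)
        theta = rng.uniform(0.0, math.pi)
        a, b = _axes_from_area_ar(area, ar)
        center = canvas.try_place(a, b, theta, strip_x, (0.0, height_px * mpp), 0.5)
        if center is not None:
            rr, cc = _ellipse_pixels(center[0], center[1], a, b, theta, mpp, shape)
            labels[rr, cc] = EXCLUDED

    records: list[dict] = []
    n_failed = 0
    cell_id = 0
    for spec, (r0, r1) in zip(specs, bands):
        band_mm2 = (config.strip_width / 1000.0) * (spec.thickness / 1000.0)
        n_cells = int(rng.poisson(spec.cell_count_per_mm2 * band_mm2))
        areas = _sample_areas(rng, n_cells, spec.area_mean, spec.area_cv)
        ars = _sample_ars(rng, n_cells, spec.ar_mean)
        thetas = rng.uniform(0.0, math.pi, size=n_cells)
        y_range = (r0 * mpp, r1 * mpp)
        for area, ar, theta in zip(areas, ars, thetas):
            a, b = _axes_from_area_ar(area, ar)
            center = canvas.try_place(a, b, theta, strip_x, y_range, spec.intensity_mean)
            if center is None:
                n_failed += 1
                continue
            records.append({
                "cell_id": cell_id,
                "side": side,
                "layer_id": spec.layer_id,
                "centroid_x_um": center[0],
                "centroid_y_um": center[1],
                "true_area_um2": area,
                "true_major_axis_um": 2.0 * a,
                "true_minor_axis_um": 2.0 * b,
                "true_orientation_rad": theta,
            })
            cell_id += 1
    if records and n_failed > 0.05 * (len(records) + n_failed):
        warnings.warn(
            f"{n_failed} of {len(records) + n_failed} somata could not be "
            "placed without overlap; realized density is below the configured one",
            stacklevel=2,
        )

    # Glial specks (< 25 μm²) and large artifacts (> 400 μm²), dark like
    # somata so that only the particle gate removes them.
    for _ in range(config.n_glial_specks):
        area = rng.uniform(6.0, 20.0)
        theta = rng.uniform(0.0, math.pi)
        a, b = _axes_from_area_ar(area, rng.uniform(1.0, 1.5))
        canvas.try_place(a, b, theta, strip_x, (0.0, height_px * mpp), 0.45)
    for _ in range(config.n_large_artifacts):
        area = rng.uniform(500.0, 1500.0)
        theta = rng.uniform(0.0, math.pi)
        a, b = _axes_from_area_ar(area, rng.uniform(1.0, 2.5))
        canvas.try_place(a, b, theta, strip_x, (0.0, height_px * mpp), 0.5)

    # Compose intensities: background + diagonal illumination gradient,
    # minus the stain darkness of painted objects, plus clipped noise.
    cols = np.arange(width_px, dtype=np.float64)
    rows = np.arange(height_px, dtype=np.float64)
    u = (cols[None, :] / max(width_px - 1, 1) + rows[:, None] / max(height_px - 1, 1)) / 2.0
    background = config.background_level - config.gradient_amplitude * (u - 0.5)
    pixels = background - canvas.darkness
    if config.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sd, size=shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    truth = pd.DataFrame.from_records(
        records,
        columns=[
            "cell_id", "side", "layer_id", "centroid_x_um", "centroid_y_um",
            "true_area_um2", "true_major_axis_um", "true_minor_axis_um",
            "true_orientation_rad",
        ],
    )
    section_id = f"synthetic-{config.seed}-{side}"
    truth.attrs["section_id"] = section_id
    image = CalibratedImage(
        pixels=pixels,
        microns_per_pixel=mpp,
        specimen_id="synthetic",
        side=side,
        section_id=section_id,
    )
    return image, LayerMap(labels=labels), truth


def derive_section_seed(master_seed: int, specimen_index: int, replicate: int) -> int:
    """Deterministic per-section seed from the cohort master seed."""
    ss = np.random.SeedSequence([int(master_seed), specimen_index, replicate])
    return int(ss.generate_state(1)[0])


@dataclasses.dataclass
class SectionTriple:
    specimen_id: str
    side: str
    image: CalibratedImage
    layer_map: LayerMap
    truth: pd.DataFrame


def generate_cohort(
    config: SynthConfig, n_specimens: int, sections_per_side: int = 1
) -> list[SectionTriple]:
    """Generate paired left/right sections for ``n_specimens`` animals.

    Each section gets a specimen- and replicate-specific seed derived
    deterministically from the master seed, so a cohort is reproducible
    piecewise.  Replication per hemisphere is configurable.
    """
    if n_specimens < 1:
        raise ConfigError("n_specimens must be >= 1")
    if sections_per_side < 1:
        raise ConfigError("sections_per_side must be >= 1")
    out: list[SectionTriple] = []
    for i in range(n_specimens):
        specimen_id = f"specimen-{i + 1:02d}"
        for rep in range(sections_per_side):
            sec_cfg = dataclasses.replace(
                config, seed=derive_section_seed(config.seed, i, rep)
            )
            for side in SIDES:
                image, layer_map, truth = generate_section(sec_cfg, side)
                section_id = f"{specimen_id}-{side}-s{rep + 1}"
                image.specimen_id = specimen_id
                image.section_id = section_id
                truth = truth.copy()
                truth.attrs["section_id"] = section_id
                truth["specimen_id"] = specimen_id
                out.append(SectionTriple(specimen_id, side, image, layer_map, truth))
    return out


# ---------------------------------------------------------------------------
# descriptor-level simulation (no rendering)

def simulate_table(
    config: SynthConfig,
    n_cells_per_side: int,
    rng: np.random.Generator | int | None = None,
    specimen_id: str = "sim",
    family: str = "lognormal",
) -> pd.DataFrame:
    """Sample a morphometry table directly from the generative laws.

    Bypasses rendering and segmentation: draws per-cell area, aspect ratio,
    perimeter (Ramanujan perimeter of the sampled ellipse with 2%
    multiplicative jitter) and neighbour count (Poisson at the configured
    density) for each layer x side cell of the design.  Cells are allocated
    to layers in proportion to expected abundance (thickness x density).
    Used for statistical calibration and power studies where the imaging
    stage is not under test.

    ``family`` selects the area law: ``"lognormal"`` (default) emulates the
    right-skewed soma-area distributions of real sections; ``"normal"``
    draws Gaussian areas with the same mean and SD, matching the normal
    error assumption of the downstream linear model exactly — use it for
    type-I-error calibration of the ANOVA, where skew would confound the
    check (values are not forced positive and are not physical areas).
    """
    if n_cells_per_side < 12:
        raise ConfigError("n_cells_per_side must be >= 12 (2 per design cell)")
    if family not in ("lognormal", "normal"):
        raise ConfigError("family must be 'lognormal' or 'normal'")
    rng = np.random.default_rng(rng)
    frames = []
    for side in SIDES:
        specs = config.layers(side)
        weights = np.array([s.thickness * s.cell_count_per_mm2 for s in specs])
        if weights.sum() <= 0:
            raise ConfigError("at least one layer must have positive density")
        n_by_layer = np.maximum(
            2, np.round(n_cells_per_side * weights / weights.sum()).astype(int)
        )
        for spec, n in zip(specs, n_by_layer):
            if family == "normal":
                areas = rng.normal(
                    spec.area_mean, spec.area_mean * spec.area_cv, size=n
                )
            else:
                areas = _sample_areas(rng, n, spec.area_mean, spec.area_cv)
            ars = _sample_ars(rng, n, spec.ar_mean)
            semi_b = np.sqrt(np.abs(areas) / (np.pi * ars))
            semi_a = semi_b * ars
            perims = np.array([ellipse_perimeter(a, b) for a, b in zip(semi_a, semi_b)])
            perims = perims * (1.0 + rng.normal(0.0, 0.02, size=n))
            dens = rng.poisson(max(spec.neighbor_mean, 0.0), size=n)
            frames.append(pd.DataFrame({
                "specimen_id": specimen_id,
                "side": side,
                "layer_id": spec.layer_id,
                "area_um2": areas,
                "perimeter_um": perims,
                "aspect_ratio": ars,
                "density": dens,
            }))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", np.arange(len(table)))
    return table


# ---------------------------------------------------------------------------
# detection matching

@dataclasses.dataclass
class MatchReport:
    """Outcome of matching detections to ground truth for one section."""

    n_truth: int
    n_detected: int
    n_matched: int
    precision: float  # NaN when there are no detections
    precision_defined: bool
    recall: float
    matches: pd.DataFrame
    unmatched_truth: list
    unmatched_detected: list

    @property
    def median_abs_area_error(self) -> float:
        """Median |detected - true| / true area over matched pairs."""
        if len(self.matches) == 0:
            return float("nan")
        return float(self.matches["area_rel_error"].abs().median())


def match_detections(
    truth: pd.DataFrame, detected: pd.DataFrame, tol: float = 5.0
) -> MatchReport:
    """Greedy nearest-centroid one-to-one matching within ``tol`` μm.

    Candidate truth-detection pairs closer than ``tol`` are ranked by
    distance and matched greedily, each row used at most once.  Precision is
    matched/detected (undefined when nothing was detected), recall is
    matched/truth.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    t_sec = truth.attrs.get("section_id")
    d_sec = detected.attrs.get("section_id")
    if t_sec and d_sec and t_sec != d_sec:
        raise ValueError(f"section id mismatch: truth={t_sec!r} detected={d_sec!r}")

    n_truth, n_det = len(truth), len(detected)
    empty = pd.DataFrame(
        columns=["truth_id", "detected_id", "distance_um",
                 "true_area_um2", "area_um2", "area_rel_error"]
    )
    if n_truth == 0 or n_det == 0:
        return MatchReport(
            n_truth=n_truth, n_detected=n_det, n_matched=0,
            precision=float("nan") if n_det == 0 else 0.0,
            precision_defined=n_det > 0,
            recall=float("nan") if n_truth == 0 else 0.0,
            matches=empty,
            unmatched_truth=list(truth["cell_id"]) if n_truth else [],
            unmatched_detected=list(detected["cell_id"]) if n_det else [],
        )

    t_xy = truth[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    d_xy = detected[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    pairs = cKDTree(t_xy).query_ball_tree(cKDTree(d_xy), r=tol)
    candidates = []
    for ti, js in enumerate(pairs):
        for di in js:
            dist = float(np.hypot(*(t_xy[ti] - d_xy[di])))
            candidates.append((dist, ti, di))
    candidates.sort()
    t_used = np.zeros(n_truth, dtype=bool)
    d_used = np.zeros(n_det, dtype=bool)
    rows = []
    for dist, ti, di in candidates:
        if t_used[ti] or d_used[di]:
            continue
        t_used[ti] = d_used[di] = True
        t_area = float(truth["true_area_um2"].iloc[ti])
        d_area = float(detected["area_um2"].iloc[di]) if "area_um2" in detected else np.nan
        rows.append({
            "truth_id": truth["cell_id"].iloc[ti],
            "detected_id": detected["cell_id"].iloc[di],
            "distance_um": dist,
            "true_area_um2": t_area,
            "area_um2": d_area,
            "area_rel_error": (d_area - t_area) / t_area if t_area else np.nan,
        })
    matches = pd.DataFrame(rows) if rows else empty
    n_matched = len(matches)
    return MatchReport(
        n_truth=n_truth, n_detected=n_det, n_matched=n_matched,
        precision=n_matched / n_det,
        precision_defined=True,
        recall=n_matched / n_truth,
        matches=matches,
        unmatched_truth=list(truth.loc[~t_used, "cell_id"]),
        unmatched_detected=list(detected.loc[~d_used, "cell_id"]),
    )


# ---------------------------------------------------------------------------
# config serialization

def config_to_yaml(config: SynthConfig, path: str | Path) -> None:
    doc = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> SynthConfig:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("layers_left", "layers_right"):
        doc[key] = [LayerSpec(**spec) for spec in doc[key]]
    return SynthConfig(**doc)
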