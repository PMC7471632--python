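"""Soma segmentation by local space-varying thresholding.

The stain renders somata dark on a light background, but uneven illumination
and regional stain density defeat any single global threshold.  The
segmenter therefore estimates a smooth local background by Gaussian
smoothing at a scale well above the soma size, marks as foreground every
pixel that is darker than its local background by at least a fixed offset,
extracts connected components, and gates them by physical area to the
25-400 μm² soma range, removing glial specks below and staining artifacts
above.  The identical procedure runs independently within each cortical
layer's pixel region, so every layer gets its own locally adapted
background; excluded (vessel) pixels are never foreground.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .image import EXCLUDED, LAYER_IDS, CalibratedImage, LayerMap

#: Default particle gate in μm²: somata lie between glial specks and artifacts.
MIN_AREA_UM2 = 25.0
MAX_AREA_UM2 = 400.0


@dataclasses.dataclass
class SegmentationParams:
    """Tunable parameters of the soma segmenter.

    background_scale : Gaussian smoothing scale in μm for the local
        background estimate; must be large relative to soma diameter
        (~10 μm) and small relative to illumination variation.
    threshold_offset : intensity units in [0, 1]; a pixel is foreground when
        strictly darker than ``background - threshold_offset``.
    connectivity : 4 or 8 (pixel adjacency for component extraction).
    min_area, max_area : inclusive physical area gate in μm².
    background_estimator : ``"gaussian"`` (default) or ``"median"``.
    """

    background_scale: float = 25.0
    threshold_offset: float = 0.2
    connectivity: int = 8
    min_area: float = MIN_AREA_UM2
    max_area: float = MAX_AREA_UM2
    background_estimator: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.background_scale > 0:
            raise ValueError("background_scale must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if self.background_estimator not in ("gaussian", "median"):
            raise ValueError("background_estimator must be 'gaussian' or 'median'")


@dataclasses.dataclass
class Component:
    """One connected foreground region."""

    label: int
    rows: np.ndarray
    cols: np.ndarray
    layer_id: int
    on_border: bool

    @property
    def pixel_count(self) -> int:
        return self.rows.size

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1), half-open."""
        return (
            int(self.rows.min()), int(self.cols.min()),
            int(self.rows.max()) + 1, int(self.cols.max()) + 1,
        )

    def area_um2(self, microns_per_pixel: float) -> float:
        return self.pixel_count * microns_per_pixel ** 2


@dataclasses.dataclass
class ComponentSet:
    """All retained components of one section, with provenance."""

    components: list[Component]
    shape: tuple[int, int]
    microns_per_pixel: float
    params: SegmentationParams
    specimen_id: str = ""
    side: str = ""
    section_id: str = ""

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)


def estimate_local_background(
    image: CalibratedImage | np.ndarray,
    background_scale: float,
    microns_per_pixel: float | None = None,
    estimator: str = "gaussian",
) -> np.ndarray:
    """Smooth background intensity field at a physical scale.

    ``background_scale`` is converted to pixels through the calibration and
    used as the Gaussian sigma (or half-width of the median window), with
    reflective boundary handling.  Scales below one pixel are clamped with a
    warning.
    """
    if isinstance(image, CalibratedImage):
        pixels, mpp = image.pixels, image.microns_per_pixel
    else:
        if microns_per_pixel is None:
            raise ValueError("microns_per_pixel required for a bare array")
        pixels, mpp = np.asarray(image, dtype=np.float64), microns_per_pixel
    if not background_scale > 0:
        raise ValueError("background_scale must be > 0")
    sigma_px = background_scale / mpp
    if sigma_px < 1.0:
        warnings.warn(
            f"background_scale {background_scale} μm is below one pixel "
            f"({mpp} μm); clamping to 1 px", stacklevel=2,
        )
        sigma_px = 1.0
    if estimator == "gaussian":
        # truncate=3: affine intensity fields are preserved exactly at >= 3
        # sigma from the borders (symmetric normalized kernel)
        return ndimage.gaussian_filter(pixels, sigma=sigma_px, mode="reflect", truncate=3.0)
    if estimator == "median":
        size = 2 * int(round(sigma_px)) + 1
        return ndimage.median_filter(pixels, size=size, mode="reflect")
    raise ValueError(f"unknown estimator {estimator!r}")


def _masked_background(
    pixels: np.ndarray, mask: np.ndarray, sigma_px: float, estimator: str
) -> np.ndarray:
    """Background restricted to ``mask`` via normalized convolution.

    Pixels outside the mask contribute nothing, so a layer's background is
    estimated from that layer's own pixels only.
    """
    if estimator == "median":
        size = 2 * int(round(sigma_px)) + 1
        filled = np.where(mask, pixels, np.median(pixels[mask]))
        return ndimage.median_filter(filled, size=size, mode="reflect")
    num = ndimage.gaussian_filter(np.where(mask, pixels, 0.0), sigma_px, mode="reflect")
    den = ndimage.gaussian_filter(mask.astype(np.float64), sigma_px, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~np.isfinite(out)] = 0.0
    return out


def apply_local_threshold(
    image: CalibratedImage | np.ndarray,
    background: np.ndarray,
    threshold_offset: float,
) -> np.ndarray:
    """Foreground mask: strictly darker than local background minus offset."""
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    if pixels.shape != background.shape:
        raise ValueError("image and background shapes differ")
    return pixels < background - threshold_offset


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def extract_components(mask: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Maximal connected foreground regions, labeled in row-major order.

    Labels are assigned by the row-major position of each component's first
    pixel, so the labeling is deterministic and independent of the
    underlying labeling library's internals.
    """
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_structure(connectivity))
    if n == 0:
        return []
    objects = ndimage.find_objects(labeled)
    h, w = mask.shape
    comps = []
    for idx, sl in enumerate(objects, start=1):
        rr, cc = np.nonzero(labeled[sl] == idx)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        on_border = (
            rows[0] == 0 or cols.min() == 0 or rows[-1] == h - 1 or cols.max() == w - 1
        )
        comps.append(Component(0, rows, cols, layer_id=0, on_border=bool(on_border)))
    comps.sort(key=lambda c: (int(c.rows[0]), int(c.cols[0])))
    for i, comp in enumerate(comps, start=1):
        comp.label = i
    return comps


def filter_by_size(
    components: list[Component],
    min_area: float,
    max_area: float,
    microns_per_pixel: float,
) -> list[Component]:
    """Retain components with physical area in [min_area, max_area] (inclusive)."""
    if not (0 < min_area < max_area):
        raise ValueError("need 0 < min_area < max_area")
    return [
        c for c in components
        if min_area <= c.area_um2(microns_per_pixel) <= max_area
    ]


def segment_cells(
    image: CalibratedImage, layers: LayerMap, params: SegmentationParams | None = None
) -> ComponentSet:
    """Segment somata per layer: threshold, extract, size-gate.

    The identical procedure (background estimate → local threshold →
    component extraction → particle gate) runs independently within each
    layer's pixel region with the same parameters; each retained component
    is tagged with its layer.  Excluded pixels (vessels) are never
    foreground, and component labels are globally unique, ordered by layer
    then row-major first pixel.
    """
    params = params or SegmentationParams()
    if image.shape != layers.shape:
        raise ValueError(
            f"image {image.shape} and layer map {layers.shape} are not aligned"
        )
    mpp = image.microns_per_pixel
    sigma_px = max(params.background_scale / mpp, 1.0)

    present = [lid for lid in LAYER_IDS if (layers.labels == lid).any()]
    if not present:
        warnings.warn("layer map contains no layer pixels; empty result", stacklevel=2)

    retained: list[Component] = []
    for lid in present:
        region = layers.labels == lid
        background = _masked_background(
            image.pixels, region, sigma_px, params.background_estimator
        )
        mask = apply_local_threshold(image.pixels, background, params.threshold_offset)
        mask &= region  # restricts to the layer; excludes vessels/background
        comps = extract_components(mask, params.connectivity)
        comps = filter_by_size(comps, params.min_area, params.max_area, mpp)
        for comp in comps:
            comp.layer_id = lid
        retained.extend(comps)
    for i, comp in enumerate(retained, start=1):
        comp.label = i
    return ComponentSet(
        components=retained,
        shape=image.shape,
        microns_per_pixel=mpp,
        params=params,
        specimen_id=image.specimen_id,
        side=image.side,
        section_id=image.section_id,
    )
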