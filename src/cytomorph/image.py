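"""Calibrated section images and layer label maps.

A section is represented by two aligned rasters: a grayscale intensity image
in [0, 1] with a physical calibration (microns per pixel), and an integer
label map assigning every pixel to a cortical layer (1-6), background (0) or
an excluded region such as a blood vessel (255).

Physical coordinates follow the raster convention: origin at the top-left
pixel center, x increasing rightward (columns), y increasing downward (rows),
``physical = pixel_index * microns_per_pixel``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image as PILImage

#: LayerMap code for pixels excluded from analysis (vessels, artifacts).
EXCLUDED = 255
#: Valid layer codes L1..L6.
LAYER_IDS = (1, 2, 3, 4, 5, 6)


@dataclasses.dataclass
class CalibratedImage:
    """Grayscale section image with physical calibration and provenance.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities in [0, 1]; Nissl polarity is dark somata on a light
        background.
    microns_per_pixel : float
        Physical size of one pixel side, in micrometres.
    specimen_id : str
        Animal / case identifier.
    side : str
        Hemisphere side, ``"left"`` or ``"right"``.
    section_id : str
        Unique section identifier within the study.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    specimen_id: str = ""
    side: str = ""
    section_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2-D grid")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.side and self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass
class LayerMap:
    """Per-pixel layer labels aligned to a :class:`CalibratedImage`.

    ``labels`` holds 0 for background, 1-6 for cortical layers L1-L6 and
    :data:`EXCLUDED` (255) for pixels removed from analysis.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        allowed = {0, *LAYER_IDS, EXCLUDED}
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise ValueError(f"invalid layer codes: {sorted(present - allowed)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def layer_mask(self, layer_id: int) -> np.ndarray:
        return self.labels == layer_id


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_image(image: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image as 8-bit grayscale TIFF or PNG.

    Calibration and section metadata go to a ``<name>.meta.yaml`` sidecar so
    the round trip is lossless apart from 8-bit intensity quantisation.
    """
    path = Path(path)
    data = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(data, mode="L").save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    meta = {
        "microns_per_pixel": float(image.microns_per_pixel),
        "specimen_id": image.specimen_id,
        "side": image.side,
        "section_id": image.section_id,
    }
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_image(path: str | Path) -> CalibratedImage:
    """Read a calibrated image written by :func:`write_image`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        data = np.asarray(PILImage.open(path).convert("L"))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"missing calibration sidecar for {path}: {meta_file}")
    meta = yaml.safe_load(meta_file.read_text())
    return CalibratedImage(
        pixels=data.astype(np.float64) / 255.0,
        microns_per_pixel=float(meta["microns_per_pixel"]),
        specimen_id=str(meta.get("specimen_id", "")),
        side=str(meta.get("side", "")),
        section_id=str(meta.get("section_id", "")),
    )


def write_layer_map(layers: LayerMap, path: str | Path) -> None:
    """Write a layer map as an integer-label TIFF (uint8)."""
    tifffile.imwrite(Path(path), layers.labels.astype(np.uint8))


def read_layer_map(path: str | Path) -> LayerMap:
    return LayerMap(labels=tifffile.imread(Path(path)))
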