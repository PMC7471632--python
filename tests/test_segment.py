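"""Segmenter: background estimation, thresholding, components, size gate."""

import dataclasses
import warnings
from collections import deque

import numpy as np
import pytest

from cytomorph.image import CalibratedImage, LayerMap
from cytomorph.segment import (
    Component,
    SegmentationParams,
    apply_local_threshold,
    estimate_local_background,
    extract_components,
    filter_by_size,
    segment_cells,
)
from cytomorph.synth import generate_section

from conftest import small_config


def _img(pixels, mpp=1.0):
    return CalibratedImage(pixels=np.asarray(pixels, float), microns_per_pixel=mpp)


def test_background_preserves_constant_image():
    image = _img(np.full((64, 64), 0.8))
    bg = estimate_local_background(image, background_scale=5.0)
    assert np.allclose(bg, 0.8, atol=1e-12)


def test_background_preserves_ramp_in_interior():
    h, w = 120, 160
    ramp = np.linspace(0, 1, w)[None, :] * np.ones((h, 1))
    image = _img(ramp, mpp=1.0)
    scale = 6.0
    bg = estimate_local_background(image, background_scale=scale)
    margin = int(3 * scale) + 1
    interior = (slice(margin, h - margin), slice(margin, w - margin))
    assert np.allclose(bg[interior], ramp[interior], atol=1e-6)


def test_background_scale_below_pixel_warns_and_clamps():
    image = _img(np.random.default_rng(0).uniform(size=(32, 32)), mpp=2.0)
    with pytest.warns(UserWarning, match="clamping"):
        bg = estimate_local_background(image, background_scale=0.5)
    assert bg.shape == image.shape


def test_background_flattens_illumination_gradient():
    cfg = small_config(seed=9, gradient_amplitude=0.2)
    image, layer_map, _ = generate_section(cfg, "left")
    bg = estimate_local_background(image, background_scale=25.0)
    resid = image.pixels - bg
    interior = np.zeros(image.shape, bool)
    m = 60
    interior[m:-m, m:-m] = True
    bg_px = interior & (layer_map.labels > 0) & (layer_map.labels != 255)
    # residual must vary less than the raw image over background-dominated tissue
    assert resid[bg_px].std() < image.pixels[bg_px].std()


def test_threshold_trivial_cases():
    pixels = np.random.default_rng(1).uniform(0.2, 0.8, size=(40, 40))
    bg = np.full((40, 40), 0.9)
    assert not apply_local_threshold(pixels, bg, threshold_offset=1.5).any()
    assert not apply_local_threshold(bg.copy(), bg, threshold_offset=0.0).any()


def test_threshold_monotone_in_offset():
    rng = np.random.default_rng(2)
    pixels = rng.uniform(size=(80, 80))
    bg = estimate_local_background(pixels, 4.0, microns_per_pixel=1.0)
    counts = [
        apply_local_threshold(pixels, bg, off).sum()
        for off in np.linspace(0.0, 0.5, 11)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_threshold_recovers_known_ellipse_interiors():
    cfg = small_config(seed=13, noise_sd=0.02)
    image, layer_map, truth = generate_section(cfg, "left")
    bg = estimate_local_background(image, background_scale=25.0)
    mask = apply_local_threshold(image, bg, threshold_offset=0.15)
    mpp = image.microns_per_pixel
    covered = 0
    total = 0
    from cytomorph.synth import _ellipse_pixels
    for _, cell in truth.iterrows():
        rr, cc = _ellipse_pixels(
            cell.centroid_x_um, cell.centroid_y_um,
            cell.true_major_axis_um / 2, cell.true_minor_axis_um / 2,
            cell.true_orientation_rad, mpp, image.shape,
        )
        covered += mask[rr, cc].sum()
        total += rr.size
    assert covered / total >= 0.95


def _flood_fill_count(mask, connectivity):
    """Independent BFS component counter."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
    return count


def test_connectivity_conventions_on_diagonal_pair():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    assert len(extract_components(mask, connectivity=8)) == 1
    assert len(extract_components(mask, connectivity=4)) == 2


def test_empty_mask_has_no_components():
    assert extract_components(np.zeros((10, 10), bool)) == []


@pytest.mark.parametrize("connectivity", [4, 8])
def test_components_agree_with_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(17)
    for _ in range(20):
        mask = rng.uniform(size=(60, 60)) < 0.35
        comps = extract_components(mask, connectivity)
        assert len(comps) == _flood_fill_count(mask, connectivity)
        # partition: disjoint and complete
        total = sum(c.pixel_count for c in comps)
        assert total == int(mask.sum())


def test_component_labels_are_row_major_deterministic():
    mask = np.zeros((10, 10), bool)
    mask[8, 1] = True
    mask[0, 5] = True
    mask[4, 2:4] = True
    comps = extract_components(mask, 8)
    firsts = [(int(c.rows[0]), int(c.cols[0])) for c in comps]
    assert firsts == sorted(firsts)
    assert [c.label for c in comps] == [1, 2, 3]


def _component_of(n_pixels):
    cols = np.arange(n_pixels) % 50
    rows = np.arange(n_pixels) // 50
    return Component(0, rows, cols, layer_id=1, on_border=False)


def test_size_gate_inclusive_bounds():
    # pixel counts at mpp 0.5 -> areas 24.5, 25.0, 100, 400.0, 400.5 μm²
    comps = [_component_of(n) for n in (98, 100, 400, 1600, 1602)]
    kept = filter_by_size(comps, 25.0, 400.0, microns_per_pixel=0.5)
    assert [c.pixel_count for c in kept] == [100, 400, 1600]
    assert filter_by_size([], 25.0, 400.0, 0.5) == []
    with pytest.raises(ValueError):
        filter_by_size(comps, 400.0, 25.0, 0.5)


def test_segment_blank_image_is_empty():
    image = _img(np.full((100, 100), 0.85), mpp=1.0)
    layers = LayerMap(labels=np.full((100, 100), 1, dtype=np.uint8))
    assert len(segment_cells(image, layers)) == 0


def test_segment_all_background_map_warns():
    image = _img(np.full((50, 50), 0.85), mpp=1.0)
    layers = LayerMap(labels=np.zeros((50, 50), dtype=np.uint8))
    with pytest.warns(UserWarning, match="no layer pixels"):
        result = segment_cells(image, layers)
    assert len(result) == 0


def test_segment_is_deterministic(small_segmentation):
    image, layer_map, _, comps = small_segmentation
    again = segment_cells(image, layer_map, SegmentationParams())
    assert len(again) == len(comps)
    for a, b in zip(comps, again):
        assert a.label == b.label and a.layer_id == b.layer_id
        assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)


def test_retained_components_respect_gate_and_layers(small_segmentation):
    image, layer_map, _, comps = small_segmentation
    mpp = image.microns_per_pixel
    seen = np.zeros(image.shape, bool)
    for comp in comps:
        area = comp.area_um2(mpp)
        assert 25.0 <= area <= 400.0
        labels_under = layer_map.labels[comp.rows, comp.cols]
        assert (labels_under == comp.layer_id).all()  # one layer, never excluded/bg
        assert not seen[comp.rows, comp.cols].any()  # disjoint
        seen[comp.rows, comp.cols] = True


def test_segment_rejects_misaligned_inputs():
    image = _img(np.full((20, 20), 0.8))
    layers = LayerMap(labels=np.ones((10, 10), dtype=np.uint8))
    with pytest.raises(ValueError, match="aligned"):
        segment_cells(image, layers)


def test_invalid_params_raise():
    with pytest.raises(ValueError):
        SegmentationParams(background_scale=0)
    with pytest.raises(ValueError):
        SegmentationParams(connectivity=6)
    with pytest.raises(ValueError):
        SegmentationParams(min_area=500, max_area=400)
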