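"""Background modeling, dynamic thresholding, and colony measurement."""

import numpy as np
import pandas as pd
import pytest

from platescreen.colony_quant import (
    SizeTable,
    bound_colony,
    dynamic_threshold,
    fit_background,
    measure_colony,
    quantify_plate,
)
from platescreen.colony_quant import BackgroundModel
from platescreen.grid import GridSpec
from platescreen.image_ingest import CropBox
from platescreen.synthetic_plate import (
    GrowthParams,
    SceneParams,
    generate_plate,
)


# ---------------------------------------------------------------- background

def test_constant_window_fits_exactly():
    bg = fit_background(np.full((20, 20), 80, dtype=np.uint8))
    assert bg.mu_bg == 80.0
    assert bg.sigma_bg == 0.0
    assert bg.fit_quality == 1.0


def test_background_window_needs_100_pixels():
    with pytest.raises(ValueError):
        fit_background(np.full((9, 9), 80, dtype=np.uint8))


def test_leftmost_peak_ignores_bright_colony_pixels():
    """80% N(60, 5) background + 20% saturated colony at 200: the fit
    must recover the background mode, not the mixture mean."""
    rng = np.random.default_rng(17)
    n = 10_000
    vals = np.concatenate(
        [rng.normal(60, 5, int(0.8 * n)), np.full(int(0.2 * n), 200.0)]
    )
    window = np.clip(np.rint(vals), 0, 255).astype(np.uint8).reshape(100, 100)
    bg = fit_background(window)
    assert 59.0 <= bg.mu_bg <= 61.0
    assert 4.0 <= bg.sigma_bg <= 6.0


def test_background_map_reveals_reflection_blob():
    """The per-position background-mean map over a 0-h plate reproduces
    the injected camera-reflection artifact's location."""
    from platescreen.colony_quant import _background_window
    from platescreen.image_ingest import PlateImage, crop_to_plate
    from platescreen.grid_align import fit_grid
    from platescreen.synthetic_plate import growth_at_time

    spec = GridSpec.from_density(1536)
    scene = SceneParams(
        rotation_deg=0.0, reflection_amplitude=0.15, seed=19,
        reflection_center=(0.3 * spec.plate_width_px, 0.6 * spec.plate_height_px),
    )
    img, truth = generate_plate(spec, scene, growth_at_time(1536, 0))
    crop, box = crop_to_plate(PlateImage(img))
    grid = fit_grid(crop, spec)
    mu_map = np.zeros((spec.rows, spec.cols))
    for r in range(spec.rows):
        for c in range(spec.cols):
            cx, cy = grid.positions[r, c]
            win, _ = _background_window(crop.pixels, cx, cy, 2 * spec.spacing_px)
            mu_map[r, c] = fit_background(win).mu_bg
    peak_r, peak_c = np.unravel_index(np.argmax(mu_map), mu_map.shape)
    peak_xy = grid.positions[peak_r, peak_c] + [box.x0, box.y0]
    true_center = np.array(scene.reflection_center) + [
        scene.surround_margin_px, scene.surround_margin_px,
    ]
    assert np.linalg.norm(peak_xy - true_center) < 2 * scene.reflection_sigma_px


# ---------------------------------------------------------------- threshold

def test_threshold_is_mu_plus_k_sigma():
    assert dynamic_threshold(BackgroundModel(60.0, 5.0), k=4.0) == 80.0


def test_flat_background_threshold_steps_one_unit():
    assert dynamic_threshold(BackgroundModel(80.0, 0.0), k=4.0) == 81.0


def test_threshold_clamps_to_bit_depth():
    assert dynamic_threshold(BackgroundModel(250.0, 5.0), k=4.0) == 255.0
    with pytest.raises(ValueError):
        dynamic_threshold(BackgroundModel(80.0, 1.0), k=0.0)


def test_background_only_window_passes_almost_no_pixels():
    """At k = 4 the false-positive rate on pure background is far below
    the 0.1% spec bound (normal tail ~3e-5)."""
    rng = np.random.default_rng(23)
    window = np.clip(
        np.rint(rng.normal(80, 3, (200, 200))), 0, 255
    ).astype(np.uint8)
    bg = fit_background(window)
    thr = dynamic_threshold(bg, k=4.0)
    assert (window > thr).mean() <= 0.001


# ---------------------------------------------------------------- bounding

def _two_colony_scene(effect_b: float, mean_radius: float = 8.0):
    """Two adjacent colonies at 6144 spacing; areas scaled by effect_b."""
    spec = GridSpec.from_density(6144)
    layout = pd.DataFrame(
        {"row": [10, 10], "col": [10, 11], "strain": ["a", "b"]}
    )
    growth = GrowthParams(
        mean_radius_px=mean_radius, radius_cv=0.0,
        strain_effects={"b": effect_b},
    )
    scene = SceneParams(
        noise_sd=0.0, gradient_amplitude=0.0, reflection_amplitude=0.0,
        rotation_deg=0.0, jitter_sd_px=0.0, seed=0,
    )
    img, truth = generate_plate(
        spec, scene, growth, layout=layout, allow_overgrowth=True
    )
    return spec, img, truth


def test_isolated_colony_bounds_at_half_spacing_midpoints(truth_grid):
    spec, img, truth = _two_colony_scene(effect_b=1.0, mean_radius=5.0)
    grid = truth_grid(truth)
    box, flags = bound_colony(img, grid, 10, 10, threshold=151.0)
    cx, cy = grid.positions[10, 10]
    half = spec.spacing_px / 2
    # left/top/bottom neighbors are empty -> midpoint edges
    assert box.x0 == pytest.approx(cx - half, abs=1.5)
    assert box.y0 == pytest.approx(cy - half, abs=1.5)
    assert box.y1 == pytest.approx(cy + half, abs=1.5)
    assert "edge" not in flags


def test_merged_equal_pair_splits_at_midpoint_saddle(truth_grid):
    # r = 7.3 on 14-px spacing: merged toward the neighbor (2r > 14) but
    # barely overflowing the half-spacing cell on the other sides, so the
    # per-side area remains comparable to the full disk
    spec, img, truth = _two_colony_scene(effect_b=1.0, mean_radius=7.3)
    grid = truth_grid(truth)
    (ax, ay), (bx, by) = grid.positions[10, 10], grid.positions[10, 11]
    box_a, _ = bound_colony(img, grid, 10, 10, threshold=151.0)
    box_b, _ = bound_colony(img, grid, 10, 11, threshold=151.0)
    midpoint = (ax + bx) / 2
    assert box_a.x1 == pytest.approx(midpoint, abs=1.5)
    assert box_b.x0 == pytest.approx(midpoint, abs=1.5)
    # each side recovers its truth area within 10%
    m_a = measure_colony(img, box_a, 151.0)
    m_b = measure_colony(img, box_b, 151.0)
    true_area = truth.per_position.query("row == 10 and col == 10").iloc[0][
        "area_px2"
    ]
    assert m_a.area_px == pytest.approx(true_area, rel=0.10)
    assert m_b.area_px == pytest.approx(true_area, rel=0.10)


def test_merged_sum_conserves_isolated_areas(truth_grid):
    """Merged pair total within 10% of the sum of isolated renders."""
    spec, img, truth = _two_colony_scene(effect_b=1.0)
    grid = truth_grid(truth)
    total_merged = sum(
        measure_colony(
            img, bound_colony(img, grid, 10, c, threshold=151.0)[0], 151.0
        ).area_px
        for c in (10, 11)
    )
    # isolated render: same colony alone
    spec_i, img_i, truth_i = _two_colony_scene(effect_b=1e-9)
    grid_i = truth_grid(truth_i)
    box_i, _ = bound_colony(img_i, grid_i, 10, 10, threshold=151.0)
    isolated = measure_colony(img_i, box_i, 151.0).area_px
    assert total_merged == pytest.approx(2 * isolated, rel=0.10)


def test_unequal_merged_pair_saddle_sits_nearer_small_colony(truth_grid):
    spec, img, truth = _two_colony_scene(effect_b=0.5625)  # r_b = 6, r_a = 8
    grid = truth_grid(truth)
    (ax, _), (bx, _) = grid.positions[10, 10], grid.positions[10, 11]
    box_a, _ = bound_colony(img, grid, 10, 10, threshold=151.0)
    saddle = box_a.x1
    assert abs(saddle - bx) < abs(saddle - ax)


def test_border_positions_are_flagged_edge(plate12h):
    box, flags = bound_colony(
        plate12h.crop, plate12h.grid, 0, 0, threshold=160.0
    )
    assert "edge" in flags


# --------------------------------------------------------------- measuring

def test_no_foreground_measures_empty():
    img = np.full((30, 30), 100, dtype=np.uint8)
    m = measure_colony(img, CropBox(5, 5, 25, 25), threshold=150.0)
    assert m.area_px == 0
    assert "empty" in m.flags


def test_synthetic_disk_area_within_five_percent(radius_ladder):
    """Noise-free disks: measured areas track pi*r^2 across the ladder."""
    for strain, sub in radius_ladder.groupby("strain"):
        r = sub["radius_px"].iloc[0]
        expected = np.pi * r**2
        assert np.median(sub["area_px"]) == pytest.approx(expected, rel=0.05)


def test_measured_area_strictly_increases_with_radius(radius_ladder):
    medians = (
        radius_ladder.groupby("radius_px")["area_px"].median().sort_index()
    )
    assert (np.diff(medians.to_numpy()) > 0).all()


def test_overgrowth_flag_rate_rises_with_time(quant12h, quant48h):
    f12 = quant12h[1]["flags"].str.contains("overgrown").mean()
    f48 = quant48h[1]["flags"].str.contains("overgrown").mean()
    assert f48 > f12


def test_quantify_correlates_with_truth_at_analysis_point(plate12h, quant12h):
    table, _ = quant12h
    true_areas = plate12h.truth.area_matrix()
    r = np.corrcoef(true_areas.ravel(), table.values.ravel())[0, 1]
    assert r >= 0.98


def test_quantification_is_deterministic(plate12h, quant12h):
    table2, meas2 = quantify_plate(plate12h.crop, plate12h.grid)
    assert np.array_equal(table2.values, quant12h[0].values)
    pd.testing.assert_frame_equal(meas2, quant12h[1])


def test_gradient_does_not_shift_measured_areas():
    """The same plate rendered with and without an illumination gradient
    yields per-position areas within 5% (dynamic thresholding adapts)."""
    from platescreen.image_ingest import PlateImage, crop_to_plate
    from platescreen.grid_align import fit_grid
    from platescreen.synthetic_plate import growth_at_time

    spec = GridSpec.from_density(1536)
    g = growth_at_time(1536, 24)
    areas = {}
    for amp in (0.0, 0.15):
        scene = SceneParams(
            gradient_amplitude=amp, reflection_amplitude=0.0,
            rotation_deg=0.0, seed=37, noise_sd=1.0,
        )
        img, _ = generate_plate(spec, scene, g)
        crop, _ = crop_to_plate(PlateImage(img))
        grid = fit_grid(crop, spec)
        areas[amp] = quantify_plate(crop, grid)[0].values
    flat, graded = areas[0.0], areas[0.15]
    ok = flat > 0
    rel = np.abs(graded[ok] - flat[ok]) / flat[ok]
    assert np.median(rel) < 0.05
    assert np.mean(rel < 0.05) > 0.9


# -------------------------------------------------------------- size table

def test_sizetable_shape_and_stage_validation(spec6144):
    with pytest.raises(ValueError):
        SizeTable(spec=spec6144, values=np.zeros((3, 3)))
    with pytest.raises(ValueError):
        SizeTable(spec=spec6144, values=np.zeros((64, 96)), stage="bogus")
    with pytest.raises(ValueError):
        SizeTable(spec=spec6144, values=np.full((64, 96), -1.0))


def test_sizetable_round_trips_through_frame():
    spec = GridSpec.from_density(1536)
    rng = np.random.default_rng(3)
    values = rng.uniform(10, 100, (spec.rows, spec.cols))
    t = SizeTable(spec=spec, values=values)
    back = SizeTable.from_frame(t.to_frame(), spec)
    assert np.allclose(back.values, values)
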