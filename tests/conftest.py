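"""Shared fixtures: synthetic plates rendered once per session.

Rendering a full ultra-high-density plate takes a couple of seconds, so
the canonical scenes (12-h analysis point, 0-h and 48-h extremes, the
hyper-density format) are session-scoped and reused by unit and
acceptance tests alike.
"""

from __future__ import annotations

import numpy as np
import pytest

from platescreen.grid import GridSpec
from platescreen.grid_align import estimate_rotation, fit_grid
from platescreen.image_ingest import PlateImage, crop_to_plate
from platescreen.colony_quant import quantify_plate, quantify_plate_global
from platescreen.synthetic_plate import (
    SceneParams,
    generate_plate,
    growth_at_time,
)


class FittedPlate:
    """A rendered plate with its crop, fitted grid, and truth."""

    def __init__(self, img, truth, crop, box, grid):
        self.img = img
        self.truth = truth
        self.crop = crop
        self.box = box
        self.grid = grid

    def truth_positions(self) -> np.ndarray:
        """True centers in cropped-image coordinates, (rows, cols, 2)."""
        return self.truth.positions_xy() - np.array([self.box.x0, self.box.y0])


def _fitted(density: int, time_h: float, seed: int, rotation_deg: float = 0.5):
    spec = GridSpec.from_density(density)
    scene = SceneParams(rotation_deg=rotation_deg, seed=seed)
    growth = growth_at_time(density, time_h)
    img, truth = generate_plate(spec, scene, growth, allow_overgrowth=True)
    crop, box = crop_to_plate(PlateImage(img))
    grid = fit_grid(crop, spec)
    return FittedPlate(img, truth, crop, box, grid)


@pytest.fixture(scope="session")
def spec6144() -> GridSpec:
    return GridSpec.from_density(6144)


@pytest.fixture(scope="session")
def plate12h() -> FittedPlate:
    """6144 format at its standard 12-h analysis point."""
    return _fitted(6144, 12, seed=42)


@pytest.fixture(scope="session")
def plate0h() -> FittedPlate:
    """6144 format at pinning time: tiny, low-contrast colonies."""
    return _fitted(6144, 0, seed=43)


@pytest.fixture(scope="session")
def plate48h() -> FittedPlate:
    """6144 format at 48 h: heavily overgrown."""
    return _fitted(6144, 48, seed=44)


@pytest.fixture(scope="session")
def plate24576() -> FittedPlate:
    """Hyper-density format at its standard 3-h analysis point."""
    return _fitted(24576, 3, seed=45)


@pytest.fixture(scope="session")
def quant12h(plate12h):
    return quantify_plate(plate12h.crop, plate12h.grid)


@pytest.fixture(scope="session")
def quant0h(plate0h):
    return quantify_plate(plate0h.crop, plate0h.grid)


@pytest.fixture(scope="session")
def quant48h(plate48h):
    return quantify_plate(plate48h.crop, plate48h.grid)


@pytest.fixture(scope="session")
def quant0h_global(plate0h):
    return quantify_plate_global(plate0h.crop, plate0h.grid)


@pytest.fixture(scope="session")
def quant48h_global(plate48h):
    return quantify_plate_global(plate48h.crop, plate48h.grid)


def grid_from_truth(truth, origin=(0.0, 0.0)):
    """Oracle GridModel built from generator truth (bypasses fitting)."""
    from platescreen.grid_align import GridModel

    spec = truth.spec
    pos = truth.positions_xy() - np.asarray(origin, dtype=float)
    r, c = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    design = np.stack(
        [np.ones(r.size), c.ravel(), r.ravel()], axis=1
    ).astype(float)
    coeffs, *_ = np.linalg.lstsq(design, pos.reshape(-1, 2), rcond=None)
    return GridModel(
        spec=spec,
        theta=np.radians(truth.rotation_deg),
        coeffs=coeffs.T,
        positions=pos,
        snapped=np.ones((spec.rows, spec.cols), dtype=bool),
    )


@pytest.fixture(scope="session")
def truth_grid():
    return grid_from_truth


@pytest.fixture(scope="session")
def radius_ladder():
    """Noise-free plate carrying colonies at radii 4, 6, 8, 10, 12 px.

    Returns a frame with per-colony true radius and measured area from
    the full crop→fit→quantify path under a flat (gradient-free) scene.
    """
    import pandas as pd

    spec = GridSpec.from_density(1536)
    radii = (4, 6, 8, 10, 12)
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    strains = np.array([f"r{radii[i % 5]}" for i in range(spec.n_positions)])
    layout = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel(), "strain": strains})
    from platescreen.synthetic_plate import GrowthParams

    growth = GrowthParams(
        mean_radius_px=8.0,
        radius_cv=0.0,
        strain_effects={f"r{d}": (d / 8.0) ** 2 for d in radii},
    )
    scene = SceneParams(
        noise_sd=0.0, gradient_amplitude=0.0, reflection_amplitude=0.0,
        rotation_deg=0.2, jitter_sd_px=0.3, seed=31,
    )
    img, truth = generate_plate(spec, scene, growth, layout=layout)
    crop, box = crop_to_plate(PlateImage(img))
    grid = fit_grid(crop, spec)
    _, meas = quantify_plate(crop, grid)
    merged = meas.merge(
        truth.per_position[["row", "col", "strain", "radius_px"]],
        on=["row", "col"],
    )
    return merged


def render_rect_crop_theta(W: float, H: float, theta_deg: float) -> float:
    """Rendering oracle for the rotation estimator.

    Renders a soft-edged W×H rectangle rotated by ``theta_deg``, takes
    the tight bounding box of its binary mask (the crop contract), and
    runs the closed-form estimator on the box dimensions.  Returns the
    estimate in degrees.
    """
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, s], [-s, c]])
    margin = 60
    bw, bh = W * abs(c) + H * abs(s), W * abs(s) + H * abs(c)
    cw, ch = int(np.ceil(bw + 2 * margin)), int(np.ceil(bh + 2 * margin))
    yy, xx = np.mgrid[0:ch, 0:cw]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    center = np.array([cw / 2, ch / 2])
    back = (pix - center) @ R + np.array([W / 2, H / 2])
    d = np.minimum.reduce([back[:, 0], W - back[:, 0], back[:, 1], H - back[:, 1]])
    mask = (np.clip(d + 0.5, 0, 1) >= 0.5).reshape(ch, cw)
    ys, xs = np.nonzero(mask)
    X = int(xs.max() - xs.min() + 1)
    Y = int(ys.max() - ys.min() + 1)
    return float(np.degrees(estimate_rotation(X, Y, W / H)))


@pytest.fixture(scope="session")
def rect_oracle():
    return render_rect_crop_theta
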