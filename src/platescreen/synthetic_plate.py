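"""Synthetic plate-photograph generator with full ground truth.

Emulates transilluminated white-box imaging of arrayed microbial
colonies: a bright agar rectangle on a darker surround, disk-like
colonies brighter than the agar, a smooth multiplicative illumination
gradient, one localized camera-reflection blob, a small global grid
rotation, sub-pixel pin jitter, saturating colony growth over time,
overgrowth (merging neighbors) at late time points, and per-source-plate
batch effects for up-scaled (4-to-1 interleaved) plates.

Every rendered plate comes with a :class:`SyntheticTruth` record so each
downstream stage (cropping, grid fitting, thresholding, normalization,
screen statistics) has an exact oracle.

Colony profile
--------------
Each colony of radius ``R`` is a flat-top disk with a cosine falloff
shoulder: intensity is at its peak for radial distance ``rho <= 0.75 R``,
falls as ``0.5 * (1 + cos(pi * (rho - 0.75 R) / (0.25 R)))`` on the
shoulder, and reaches the agar level exactly at ``rho = R``.  A faint
2-intensity-unit pedestal covers the whole disk interior — a thin
translucent colony rim — so the above-agar optical footprint of a
noise-free render is exactly the pixel disk of radius ``R`` (area
``pi * R**2`` up to lattice quantization) while the smooth shoulder
keeps thresholding behavior nontrivial.

Overlapping colonies compose by maximum, which produces the saddle-shaped
intensity profile between merged neighbors that the local-minima bounding
step relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .grid import GridSpec

__all__ = [
    "GridSpec",
    "SceneParams",
    "GrowthParams",
    "TimecourseParams",
    "SyntheticTruth",
    "STANDARD_CURVES",
    "ANALYSIS_TIME_H",
    "growth_at_time",
    "generate_plate",
    "generate_timecourse",
    "generate_upscaled_plate",
    "make_screen_layout",
    "radius_at_time",
    "save_plate",
]

#: supported imaging time points after pinning, hours
TIME_POINTS_H = (0, 3, 6, 9, 12, 24, 48)

#: fraction of the colony radius occupied by the cosine shoulder
SHOULDER_FRACTION = 0.25

#: faint translucent-rim intensity (units above agar) covering the whole
#: disk interior, so the noise-free optical footprint is exactly rho < R
RIM_PEDESTAL = 2.0

#: up-scaling interleave: position (r, c) came from source plate
#: ``2 * (r % 2) + (c % 2)`` (quadrant pattern, indices 0..3)
N_SOURCE_PLATES = 4


@dataclass(frozen=True)
class SceneParams:
    """Imaging-scene parameters for a synthetic plate photograph.

    Intensities are on the 8-bit [0, 255] scale.  ``rotation_deg`` is the
    grid/plate orientation, positive = counterclockwise in image
    coordinates (x right, y down).  The illumination field is
    ``1 + gradient_amplitude * (planar ramp) + reflection_amplitude *
    (Gaussian blob)`` and multiplies the whole scene, mimicking uneven
    lighting plus the camera's reflection in the diffusor box.
    """

    agar_level: float = 150.0
    background_level: float = 40.0
    colony_peak: float = 230.0
    gradient_amplitude: float = 0.12
    gradient_angle_deg: float = 30.0
    reflection_center: tuple[float, float] | None = None  # plate-frame (x, y)
    reflection_amplitude: float = 0.10
    reflection_sigma_px: float = 120.0
    noise_sd: float = 2.0
    rotation_deg: float = 0.0
    jitter_sd_px: float = 0.3
    surround_margin_px: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.colony_peak > self.agar_level > self.background_level):
            raise ValueError(
                "scene polarity requires colony_peak > agar_level > background_level"
            )
        for name in ("agar_level", "background_level", "colony_peak"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside 8-bit range")
        if self.jitter_sd_px < 0 or self.noise_sd < 0:
            raise ValueError("noise_sd and jitter_sd_px must be non-negative")


@dataclass(frozen=True)
class GrowthParams:
    """Colony-size parameters at a single imaging time point.

    ``mean_radius_px`` is the population mean colony radius; individual
    colonies scatter around it with coefficient of variation
    ``radius_cv`` (lognormal multiplicative factors, drawn once per
    plate).  ``strain_effects`` maps strain id -> multiplicative *area*
    factor (a fitness of 0.8 shrinks area by 0.8, radius by sqrt(0.8)).
    ``source_batch_factors`` are 4 multiplicative area factors for
    up-scaled plates, one per interleaved source plate.
    """

    time_h: float = 12.0
    mean_radius_px: float = 5.0
    radius_cv: float = 0.05
    strain_effects: dict[str, float] | None = None
    source_batch_factors: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mean_radius_px <= 0:
            raise ValueError("mean_radius_px must be positive")
        if self.radius_cv < 0:
            raise ValueError("radius_cv must be non-negative")
        if (
            self.source_batch_factors is not None
            and len(self.source_batch_factors) != N_SOURCE_PLATES
        ):
            raise ValueError("source_batch_factors must have exactly 4 entries")


@dataclass(frozen=True)
class TimecourseParams:
    """Saturating growth curve for :func:`generate_timecourse`.

    Mean radius over time follows
    ``r(t) = r0 * sqrt(1 + (fold_area - 1) * g(t))`` with the saturating
    ramp ``g(t) = (1 - exp(-t/tau)) / (1 - exp(-t_final/tau))``, so the
    median colony *area* grows exactly ``fold_area``-fold between t = 0
    and ``t_final`` — mirroring the ~7–8-fold area increases seen between
    pinning and the analysis time point on real plates.
    """

    radius_t0_px: float = 2.0
    fold_area: float = 7.0
    t_final_h: float = 48.0
    tau_h: float = 12.0

    def __post_init__(self) -> None:
        if self.radius_t0_px <= 0 or self.fold_area < 1 or self.tau_h <= 0:
            raise ValueError("invalid growth-curve parameters")


#: canonical growth curves per density, emulating the study conditions:
#: the ultra-high-density format grows ~7-fold in area by its 12-h
#: analysis point and begins to overgrow just after it; the 1536 format
#: is analyzed at 48 h with ~8-fold growth and no overgrowth; the
#: hyper-density format overgrows within 3–6 h.  Radii are in pixels at
#: each density's default spacing.
STANDARD_CURVES: dict[int, TimecourseParams] = {
    96: TimecourseParams(radius_t0_px=8.0, fold_area=8.0, tau_h=24.0),
    384: TimecourseParams(radius_t0_px=6.0, fold_area=8.0, tau_h=20.0),
    1536: TimecourseParams(radius_t0_px=4.0, fold_area=8.0, tau_h=16.0),
    6144: TimecourseParams(radius_t0_px=2.45, fold_area=10.0, tau_h=12.0),
    24576: TimecourseParams(radius_t0_px=1.2, fold_area=10.0, tau_h=6.0),
}

#: standard analysis time point per density, hours
ANALYSIS_TIME_H: dict[int, int] = {96: 48, 384: 48, 1536: 48, 6144: 12, 24576: 3}


def growth_at_time(
    density: int,
    time_h: float | None = None,
    radius_cv: float = 0.05,
    strain_effects: dict[str, float] | None = None,
) -> GrowthParams:
    """Canonical :class:`GrowthParams` for a density at a time point.

    ``time_h`` defaults to the density's standard analysis point (48 h
    for 96–1536, 12 h for 6144, 3 h for 24576).
    """
    curve = STANDARD_CURVES[density]
    if time_h is None:
        time_h = ANALYSIS_TIME_H[density]
    return GrowthParams(
        time_h=time_h,
        mean_radius_px=radius_at_time(time_h, curve),
        radius_cv=radius_cv,
        strain_effects=strain_effects,
    )


def radius_at_time(t_h: float, curve: TimecourseParams) -> float:
    """Mean colony radius (px) at time ``t_h`` on a saturating curve."""
    ramp = (1.0 - np.exp(-t_h / curve.tau_h)) / (
        1.0 - np.exp(-curve.t_final_h / curve.tau_h)
    )
    return float(curve.radius_t0_px * np.sqrt(1.0 + (curve.fold_area - 1.0) * ramp))


@dataclass
class SyntheticTruth:
    """Ground truth for one rendered plate.

    ``per_position`` has one row per grid position with columns
    ``row, col, x, y, radius_px, area_px2, strain, source_index,
    overgrown`` — (x, y) are canvas-frame pixel coordinates of the true
    colony center, ``area_px2 = pi * radius**2``, ``source_index`` is the
    1-based source-plate index for up-scaled layouts (0 otherwise) and
    ``overgrown`` flags colonies whose gap to a grid neighbor is < 0.
    Plate-level fields record the applied rotation, the true tight
    bounding box of the agar region on the canvas (half-open pixel
    coordinates), and the four true plate-corner coordinates.
    """

    spec: GridSpec
    per_position: pd.DataFrame
    rotation_deg: float
    plate_box: tuple[int, int, int, int]  # x0, y0, x1, y1 half-open
    plate_corners: np.ndarray  # (4, 2) canvas-frame (x, y)
    params: dict = field(default_factory=dict)

    def positions_xy(self) -> np.ndarray:
        """(rows, cols, 2) array of true centers in canvas coordinates."""
        arr = np.full((self.spec.rows, self.spec.cols, 2), np.nan)
        r = self.per_position["row"].to_numpy()
        c = self.per_position["col"].to_numpy()
        arr[r, c, 0] = self.per_position["x"].to_numpy()
        arr[r, c, 1] = self.per_position["y"].to_numpy()
        return arr

    def area_matrix(self) -> np.ndarray:
        """(rows, cols) matrix of true colony areas, px^2."""
        arr = np.full((self.spec.rows, self.spec.cols), np.nan)
        r = self.per_position["row"].to_numpy()
        c = self.per_position["col"].to_numpy()
        arr[r, c] = self.per_position["area_px2"].to_numpy()
        return arr


def _rotation_matrix(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    # positive theta = counterclockwise for x-right / y-down image coords
    return np.array([[c, s], [-s, c]])


def _source_index(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """1-based source-plate index under the 2×2 quadrant interleave."""
    return 2 * (rows % 2) + (cols % 2) + 1


def _render_scene(
    scene: SceneParams,
    canvas_w: int,
    canvas_h: int,
    canvas_center: np.ndarray,
    plate_center: np.ndarray,
    R: np.ndarray,
    W: float,
    H: float,
    centers_canvas: np.ndarray,
    radii: np.ndarray,
    rng_noise: np.random.Generator,
) -> np.ndarray:
    """Synthesize the photograph: agar, colonies, illumination, noise."""
    # agar mask with ~1 px soft edge (camera blur), via plate-frame coords
    yy, xx = np.mgrid[0:canvas_h, 0:canvas_w]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    back = (pix - canvas_center) @ R + plate_center  # inverse rotation
    d_inside = np.minimum.reduce(
        [back[:, 0], W - back[:, 0], back[:, 1], H - back[:, 1]]
    )
    alpha = np.clip(d_inside + 0.5, 0.0, 1.0).reshape(canvas_h, canvas_w)
    img = scene.background_level + alpha * (scene.agar_level - scene.background_level)

    # colonies: flat-top disk + cosine shoulder + rim pedestal, composed by max
    bump = np.zeros_like(img)
    peak = scene.colony_peak - scene.agar_level
    for (cx, cy), rad in zip(centers_canvas, radii):
        if rad <= 0:
            continue
        x0 = max(int(np.floor(cx - rad - 1)), 0)
        x1 = min(int(np.ceil(cx + rad + 2)), canvas_w)
        y0 = max(int(np.floor(cy - rad - 1)), 0)
        y1 = min(int(np.ceil(cy + rad + 2)), canvas_h)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        rho = np.hypot(xs - cx, ys - cy)
        flat = (1.0 - SHOULDER_FRACTION) * rad
        prof = np.where(
            rho <= flat,
            1.0,
            0.5 * (1.0 + np.cos(np.pi * (rho - flat) / (SHOULDER_FRACTION * rad))),
        )
        val = np.where(rho < rad, np.maximum(peak * prof, RIM_PEDESTAL), 0.0)
        np.maximum(bump[y0:y1, x0:x1], val, out=bump[y0:y1, x0:x1])
    img = img + bump * alpha  # colonies only exist on agar

    # multiplicative illumination: planar gradient + reflection blob
    phi = np.radians(scene.gradient_angle_deg)
    u = (xx / max(canvas_w - 1, 1)) - 0.5
    v = (yy / max(canvas_h - 1, 1)) - 0.5
    field_mult = 1.0 + scene.gradient_amplitude * (u * np.cos(phi) + v * np.sin(phi)) * 2.0
    if scene.reflection_amplitude > 0:
        rc = scene.reflection_center
        if rc is None:
            rc = (0.65 * W, 0.40 * H)  # off-center, like an overhead camera
        rc_canvas = (np.asarray(rc, dtype=float) - plate_center) @ R.T + canvas_center
        d2 = (xx - rc_canvas[0]) ** 2 + (yy - rc_canvas[1]) ** 2
        field_mult = field_mult + scene.reflection_amplitude * np.exp(
            -d2 / (2.0 * scene.reflection_sigma_px**2)
        )
    img = img * field_mult

    if scene.noise_sd > 0:
        img = img + rng_noise.normal(0.0, scene.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_plate(
    spec: GridSpec,
    scene: SceneParams | None = None,
    growth: GrowthParams | None = None,
    layout: pd.DataFrame | None = None,
    allow_overgrowth: bool = False,
    render: bool = True,
) -> tuple[np.ndarray | None, SyntheticTruth]:
    """Render one synthetic plate photograph plus its ground truth.

    Parameters
    ----------
    spec
        Grid geometry.
    scene
        Imaging-scene parameters (illumination, rotation, jitter, noise,
        seed).  Defaults emulate a clean 8-bit white-box photograph.
    growth
        Colony-size parameters at the imaged time point.
    layout
        Optional table with columns ``row, col, strain`` assigning a
        strain id to each position; positions absent from the layout are
        left empty (no colony).  Default: every position carries ``"WT"``.
    allow_overgrowth
        Permit colony radii that exceed half the grid spacing (merging
        neighbors).  Without it, a spacing too small for the requested
        radii raises ``ValueError``.
    render
        When False, skip image synthesis and return ``(None, truth)`` —
        the truth (centers, radii, areas, strains, merges) is identical
        to a rendered run and is enough for table-level simulations.

    Returns
    -------
    (image, truth)
        ``image`` is a ``uint8`` 2-D array (the plate photograph);
        ``truth`` records per-position centers, radii, areas, strains,
        source indices and the plate-level geometry.
    """
    scene = scene or SceneParams()
    growth = growth or GrowthParams()

    rng_jitter, rng_radius, rng_noise = [
        np.random.default_rng(s) for s in np.random.SeedSequence(scene.seed).spawn(3)
    ]

    rows, cols = spec.rows, spec.cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()

    # strain assignment
    if layout is None:
        strains = np.array(["WT"] * rr.size, dtype=object)
        present = np.ones(rr.size, dtype=bool)
    else:
        lut = {
            (int(r), int(c)): str(s)
            for r, c, s in zip(layout["row"], layout["col"], layout["strain"])
        }
        strains = np.array(
            [lut.get((r, c), "") for r, c in zip(rr, cc)], dtype=object
        )
        present = strains != ""

    # per-colony radii: mean radius × lognormal replicate scatter × strain
    # and source-batch area factors (area factors enter as sqrt on radius)
    radii = np.full(rr.size, float(growth.mean_radius_px))
    if growth.radius_cv > 0:
        sigma = np.sqrt(np.log1p(growth.radius_cv**2))
        radii *= rng_radius.lognormal(-0.5 * sigma**2, sigma, size=rr.size)
    else:
        rng_radius.lognormal(0, 1, size=rr.size)  # keep substream alignment
    if growth.strain_effects:
        eff = np.array(
            [growth.strain_effects.get(s, 1.0) for s in strains], dtype=float
        )
        radii *= np.sqrt(eff)
    src = _source_index(rr, cc)
    if growth.source_batch_factors is not None:
        factors = np.asarray(growth.source_batch_factors, dtype=float)
        radii *= np.sqrt(factors[src - 1])
    else:
        src = np.zeros_like(src)
    radii[~present] = 0.0

    max_r = radii.max() if radii.size else 0.0
    if 2 * max_r > spec.spacing_px and not allow_overgrowth:
        raise ValueError(
            f"colony diameter {2 * max_r:.1f} px exceeds spacing "
            f"{spec.spacing_px:.1f} px; pass allow_overgrowth=True to render "
            "merging colonies"
        )

    # plate-frame centers with sub-pixel pin jitter
    x_p, y_p = spec.position_xy(rr, cc)
    jitter = rng_jitter.normal(0.0, 1.0, size=(rr.size, 2)) * scene.jitter_sd_px
    x_p = x_p + jitter[:, 0]
    y_p = y_p + jitter[:, 1]

    # canvas geometry: plate rectangle rotated about its center, dark surround
    W, H = spec.plate_width_px, spec.plate_height_px
    theta = np.radians(scene.rotation_deg)
    R = _rotation_matrix(theta)
    plate_center = np.array([W / 2.0, H / 2.0])
    corners_p = np.array([[0, 0], [W, 0], [W, H], [0, H]], dtype=float)
    corners_rot = (corners_p - plate_center) @ R.T
    bbox_w = corners_rot[:, 0].max() - corners_rot[:, 0].min()
    bbox_h = corners_rot[:, 1].max() - corners_rot[:, 1].min()
    m = scene.surround_margin_px
    canvas_w = int(np.ceil(bbox_w + 2 * m))
    canvas_h = int(np.ceil(bbox_h + 2 * m))
    canvas_center = np.array([canvas_w / 2.0, canvas_h / 2.0])
    corners_canvas = corners_rot + canvas_center

    # colony centers in canvas frame
    centers_canvas = (np.stack([x_p, y_p], axis=1) - plate_center) @ R.T + canvas_center

    img = None
    if render:
        img = _render_scene(
            scene, canvas_w, canvas_h, canvas_center, plate_center, R, W, H,
            centers_canvas, radii, rng_noise,
        )
    # overgrowth: gap to any grid neighbor < 0
    rad_mat = np.zeros((rows, cols))
    rad_mat[rr, cc] = radii
    overgrown = np.zeros((rows, cols), dtype=bool)
    gap_h = spec.spacing_px - (rad_mat[:, :-1] + rad_mat[:, 1:])
    merged_h = (gap_h < 0) & (rad_mat[:, :-1] > 0) & (rad_mat[:, 1:] > 0)
    overgrown[:, :-1] |= merged_h
    overgrown[:, 1:] |= merged_h
    gap_v = spec.spacing_px - (rad_mat[:-1, :] + rad_mat[1:, :])
    merged_v = (gap_v < 0) & (rad_mat[:-1, :] > 0) & (rad_mat[1:, :] > 0)
    overgrown[:-1, :] |= merged_v
    overgrown[1:, :] |= merged_v

    x0b = int(np.floor(corners_canvas[:, 0].min()))
    y0b = int(np.floor(corners_canvas[:, 1].min()))
    x1b = int(np.ceil(corners_canvas[:, 0].max()))
    y1b = int(np.ceil(corners_canvas[:, 1].max()))

    truth = SyntheticTruth(
        spec=spec,
        per_position=pd.DataFrame(
            {
                "row": rr,
                "col": cc,
                "x": centers_canvas[:, 0],
                "y": centers_canvas[:, 1],
                "radius_px": radii,
                "area_px2": np.pi * radii**2,
                "strain": strains,
                "source_index": src,
                "overgrown": overgrown[rr, cc],
            }
        ),
        rotation_deg=scene.rotation_deg,
        plate_box=(x0b, y0b, x1b, y1b),
        plate_corners=corners_canvas,
        params={
            "scene": dataclasses.asdict(scene),
            "growth": {
                **dataclasses.asdict(growth),
                "strain_effects": dict(growth.strain_effects or {}),
            },
            "spec": dataclasses.asdict(spec),
        },
    )
    return img, truth


def generate_timecourse(
    spec: GridSpec,
    scene: SceneParams,
    curve: TimecourseParams,
    times: list[float],
    radius_cv: float = 0.05,
    layout: pd.DataFrame | None = None,
    strain_effects: dict[str, float] | None = None,
) -> list[tuple[np.ndarray, SyntheticTruth]]:
    """Render the same plate imaged at several time points.

    Per-colony relative size factors are drawn once and reused at every
    time point (the same physical colonies growing), so the fold increase
    of the median true area between t=0 and ``t_final`` reproduces
    ``curve.fold_area`` exactly.  Late time points may merge neighbors;
    overgrowth is permitted and flagged in the truth.
    """
    unsupported = [t for t in times if t not in TIME_POINTS_H]
    if unsupported:
        raise ValueError(
            f"unsupported time points {unsupported}; supported: {TIME_POINTS_H}"
        )
    out = []
    for t in times:
        growth = GrowthParams(
            time_h=t,
            mean_radius_px=radius_at_time(t, curve),
            radius_cv=radius_cv,
            strain_effects=strain_effects,
        )
        # same seed at every time point -> identical jitter and per-colony
        # size factors; only the deterministic mean radius changes
        img, truth = generate_plate(
            spec, scene, growth, layout=layout, allow_overgrowth=True
        )
        truth.params["time_h"] = t
        out.append((img, truth))
    return out


def generate_upscaled_plate(
    spec: GridSpec,
    batch_factors: tuple[float, float, float, float],
    scene: SceneParams | None = None,
    growth: GrowthParams | None = None,
    layout: pd.DataFrame | None = None,
    allow_overgrowth: bool = False,
    render: bool = True,
) -> tuple[np.ndarray | None, SyntheticTruth]:
    """Render an up-scaled plate: 4 interleaved source plates, one target.

    Position (r, c) belongs to source plate ``2*(r%2) + (c%2) + 1``; all
    colony *areas* from one source are multiplied by its batch factor,
    emulating per-source pinning/growth batch effects.  Requires a target
    density of at least 4 × 1536.
    """
    if len(batch_factors) != N_SOURCE_PLATES:
        raise ValueError("exactly 4 batch factors required")
    if spec.density < 4 * 1536:
        raise ValueError("up-scaling requires target density >= 6144")
    growth = growth or GrowthParams()
    growth = dataclasses.replace(
        growth, source_batch_factors=tuple(float(f) for f in batch_factors)
    )
    return generate_plate(
        spec, scene, growth, layout=layout,
        allow_overgrowth=allow_overgrowth, render=render,
    )


def make_screen_layout(
    spec: GridSpec,
    n_strains: int,
    control_strain: str = "control",
    control_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Random strain layout for a synthetic screen.

    A ``control_fraction`` of positions carries the control strain; the
    remaining positions are split evenly (round-robin after shuffling)
    among ``n_strains`` mutant strains named ``strain_0001`` ...  Returns
    a table with columns ``row, col, strain``.
    """
    rng = np.random.default_rng(seed)
    n_pos = spec.n_positions
    n_ctrl = int(round(control_fraction * n_pos))
    if n_strains > n_pos - n_ctrl:
        raise ValueError("more strains than available non-control positions")
    names = [f"strain_{i + 1:04d}" for i in range(n_strains)]
    assignment = np.array(
        [control_strain] * n_ctrl
        + [names[i % n_strains] for i in range(n_pos - n_ctrl)],
        dtype=object,
    )
    rng.shuffle(assignment)
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    return pd.DataFrame(
        {"row": rr.ravel(), "col": cc.ravel(), "strain": assignment}
    )


def save_plate(
    path,
    image: np.ndarray,
    truth: SyntheticTruth | None = None,
    jpeg_quality: int | None = None,
) -> None:
    """Write the rendered image (PNG by default, JPEG via ``jpeg_quality``)
    plus optional truth CSV and a YAML parameter sidecar."""
    path = str(path)
    if jpeg_quality is not None:
        iio.imwrite(path, image, quality=jpeg_quality)
    else:
        iio.imwrite(path, image)
    if truth is not None:
        stem = path.rsplit(".", 1)[0]
        truth.per_position.to_csv(stem + ".truth.csv", index=False)
        with open(stem + ".params.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    **truth.params,
                    "rotation_deg": truth.rotation_deg,
                    "plate_box": list(truth.plate_box),
                },
                fh,
            )
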