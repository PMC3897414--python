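"""Grid alignment: closed-form rotation, corner estimation, affine fitting.

At ultra-high density a fraction of a degree of plate rotation is enough
to push grid predictions at the row/column ends onto the wrong colony,
so the grid must be located precisely.  The approach:

1. **Rotation.**  When a rotated rectangular plate is cropped tightly,
   its corners touch the crop edges, and the crop width ``X`` and height
   ``Y`` decompose as ``X = W·cosθ + H·sinθ`` and ``Y = W·sinθ + H·cosθ``
   where ``W × H`` is the plate and ``W = r·H`` with known aspect ratio
   ``r``.  Eliminating ``W`` and ``H`` gives the closed form
   ``θ = atan((r·Y − X) / (r·X − Y))``.  The crop box is symmetric under
   ``θ → −θ``, so the closed form recovers the magnitude of the angle;
   the sign is resolved against the image content during fitting.
2. **Corners.**  Plate extent, grid spacing and margin predict the pixel
   coordinates of the four extreme grid positions.
3. **Iterative fit.**  Every grid position is a linear (affine) function
   of its row and column index.  Starting from the corner-anchored
   affine model, positions with detectable signal are snapped to their
   local intensity-weighted foreground centroid and the affine model is
   refit by least squares, until convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec
from .image_ingest import PlateImage

__all__ = [
    "RotationGeometry",
    "GridModel",
    "GeometryError",
    "GridFitError",
    "estimate_rotation",
    "rotation_geometry",
    "estimate_corners",
    "fit_grid",
]

#: grid-index order of the four corners returned by estimate_corners
CORNER_INDEX = ((0, 0), (0, -1), (-1, 0), (-1, -1))


class GeometryError(ValueError):
    """Degenerate crop geometry: the closed form has no valid solution."""


class GridFitError(RuntimeError):
    """Grid fitting failed (too few positions with signal)."""


@dataclass(frozen=True)
class RotationGeometry:
    """Decomposition of a tight crop around a rotated plate.

    ``X = X1 + X2`` and ``Y = Y1 + Y2`` with ``X1 = W·cosθ``,
    ``X2 = H·sinθ``, ``Y1 = W·sinθ``, ``Y2 = H·cosθ``.
    """

    X: float
    Y: float
    W: float
    H: float
    r: float
    theta: float  # radians, magnitude (crop box is sign-symmetric)

    @property
    def X1(self) -> float:
        return self.W * np.cos(self.theta)

    @property
    def X2(self) -> float:
        return self.H * np.sin(self.theta)

    @property
    def Y1(self) -> float:
        return self.W * np.sin(self.theta)

    @property
    def Y2(self) -> float:
        return self.H * np.cos(self.theta)


def estimate_rotation(X: float, Y: float, r: float) -> float:
    """Closed-form grid-rotation magnitude from tight-crop dimensions.

    Parameters
    ----------
    X, Y
        Width and height of the tight crop, pixels.
    r
        Plate aspect ratio W/H (> 1, landscape).

    Returns
    -------
    theta : float
        Rotation angle in radians, ``theta >= 0`` (the tight crop of a
        rotated rectangle is identical for ``±theta``).

    Raises
    ------
    GeometryError
        If ``r·X − Y <= 0`` (not a landscape plate crop) or inputs are
        non-positive.
    """
    if X <= 0 or Y <= 0:
        raise GeometryError("crop dimensions must be positive")
    if r <= 1:
        raise GeometryError("aspect ratio must exceed 1 (landscape)")
    denom = r * X - Y
    if denom <= 0:
        raise GeometryError(
            f"degenerate geometry: r*X - Y = {denom:.3g} <= 0 "
            "(crop is not consistent with a landscape plate)"
        )
    # numerator can dip just below 0 from pixel quantization at theta ~ 0
    return float(np.arctan(max(r * Y - X, 0.0) / denom))


def rotation_geometry(X: float, Y: float, r: float) -> RotationGeometry:
    """Full crop decomposition (plate extent W, H and the four lengths)."""
    theta = estimate_rotation(X, Y, r)
    c, s = np.cos(theta), np.sin(theta)
    cos2 = c * c - s * s
    W = (X * c - Y * s) / cos2
    H = (Y * c - X * s) / cos2
    return RotationGeometry(X=X, Y=Y, W=W, H=H, r=r, theta=theta)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def estimate_corners(
    img: PlateImage, spec: GridSpec, theta: float
) -> np.ndarray:
    """Predict pixel coordinates of the four extreme grid positions.

    Uses the crop extent, the rotation angle, and the grid's spacing and
    margin (margin defaults to 3.5 spacings via :class:`GridSpec`) to
    place grid corners (0,0), (0,cols−1), (rows−1,0), (rows−1,cols−1).

    Returns a ``(4, 2)`` array of (x, y), in :data:`CORNER_INDEX` order.

    Raises
    ------
    GridFitError
        If the implied spacing differs from the spec's by more than 30%.
    """
    X, Y = float(img.width), float(img.height)
    c, s = np.cos(theta), np.sin(theta)
    cos2 = c * c - s * s
    W = (X * c - Y * abs(s)) / cos2
    H = (Y * c - X * abs(s)) / cos2
    margin_sp = spec.margin_px / spec.spacing_px
    sp_x = W / (spec.cols - 1 + 2 * margin_sp)
    sp_y = H / (spec.rows - 1 + 2 * margin_sp)
    for sp in (sp_x, sp_y):
        if abs(sp / spec.spacing_px - 1.0) > 0.30:
            raise GridFitError(
                f"estimated spacing {sp:.2f} px differs from spec "
                f"{spec.spacing_px:.2f} px by more than 30%"
            )
    corners_plate = np.array(
        [
            [
                margin_sp * sp_x + (spec.cols - 1) * sp_x * (ci % 2),
                margin_sp * sp_y + (spec.rows - 1) * sp_y * (ci // 2),
            ]
            for ci in range(4)
        ]
    )
    plate_center = np.array([W / 2.0, H / 2.0])
    crop_center = np.array([X / 2.0, Y / 2.0])
    return (corners_plate - plate_center) @ _rot(theta).T + crop_center


@dataclass
class GridModel:
    """Fitted affine grid: position (row r, col c) maps to pixel
    ``x = ax0 + ax_c·c + ax_r·r``, ``y = ay0 + ay_c·c + ay_r·r``, plus
    per-position refined coordinates (snapped where signal existed)."""

    spec: GridSpec
    theta: float
    coeffs: np.ndarray  # (2, 3): [[ax0, ax_c, ax_r], [ay0, ay_c, ay_r]]
    positions: np.ndarray = field(default=None)  # (rows, cols, 2)
    snapped: np.ndarray = field(default=None)  # (rows, cols) bool
    n_iter: int = 0

    def affine_positions(self) -> np.ndarray:
        """(rows, cols, 2) pixel coordinates from the affine model alone."""
        r, c = np.meshgrid(
            np.arange(self.spec.rows), np.arange(self.spec.cols), indexing="ij"
        )
        design = np.stack([np.ones_like(c), c, r], axis=-1).astype(float)
        return design @ self.coeffs.T

    @property
    def spacing_xy(self) -> tuple[float, float]:
        """Fitted center-to-center spacing along columns and rows, px."""
        return (
            float(np.hypot(self.coeffs[0, 1], self.coeffs[1, 1])),
            float(np.hypot(self.coeffs[0, 2], self.coeffs[1, 2])),
        )

    def to_frame(self):
        import pandas as pd

        r, c = np.meshgrid(
            np.arange(self.spec.rows), np.arange(self.spec.cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "row": r.ravel(),
                "col": c.ravel(),
                "x": self.positions[..., 0].ravel(),
                "y": self.positions[..., 1].ravel(),
            }
        )


def _affine_from_corners(spec: GridSpec, corners: np.ndarray) -> np.ndarray:
    design = np.array(
        [[1.0, (spec.cols - 1) * (ci % 2), (spec.rows - 1) * (ci // 2)] for ci in range(4)]
    )
    coeffs, *_ = np.linalg.lstsq(design, np.asarray(corners, dtype=float), rcond=None)
    return coeffs.T  # (2, 3)


def _foreground_threshold(pixels: np.ndarray) -> float:
    """Plate-level foreground cutoff for grid snapping.

    Colonies are the brightest structures; the cutoff sits between the
    plate's typical (agar-dominated) level and the upper colony tail, far
    enough above the illumination-gradient spread of the agar.
    """
    med = float(np.median(pixels))
    hi = float(np.percentile(pixels, 99.8))
    return med + 0.4 * (hi - med)


def _snap_positions(
    pixels: np.ndarray,
    coeffs: np.ndarray,
    spec: GridSpec,
    fg_thr: float,
):
    """Vectorized snap: assign each foreground pixel to its nearest grid
    position under the current affine model and compute intensity-weighted
    centroids per position."""
    rows, cols = spec.rows, spec.cols
    ys, xs = np.nonzero(pixels > fg_thr)
    w = pixels[ys, xs].astype(float) - fg_thr
    A = coeffs[:, 1:]  # (2, 2)
    b = coeffs[:, 0]
    inv = np.linalg.inv(A)
    rc = (np.stack([xs, ys], axis=1) - b) @ inv.T  # columns: (c, r)
    cf, rf = rc[:, 0], rc[:, 1]
    ci = np.rint(cf).astype(int)
    ri = np.rint(rf).astype(int)
    ok = (
        (ri >= 0)
        & (ri < rows)
        & (ci >= 0)
        & (ci < cols)
        & (np.abs(cf - ci) <= 0.5)
        & (np.abs(rf - ri) <= 0.5)
    )
    ri, ci, w = ri[ok], ci[ok], w[ok]
    xs, ys = xs[ok], ys[ok]
    label = ri * cols + ci
    n = rows * cols
    counts = np.bincount(label, minlength=n)
    wsum = np.bincount(label, weights=w, minlength=n)
    cx = np.bincount(label, weights=w * xs, minlength=n)
    cy = np.bincount(label, weights=w * ys, minlength=n)
    min_pixels = max(int(0.01 * spec.spacing_px**2), 3)
    snapped = (counts >= min_pixels) & (wsum > 0)
    centroids = np.full((n, 2), np.nan)
    centroids[snapped, 0] = cx[snapped] / wsum[snapped]
    centroids[snapped, 1] = cy[snapped] / wsum[snapped]
    return snapped.reshape(rows, cols), centroids.reshape(rows, cols, 2)


def _grid_score(pixels: np.ndarray, positions: np.ndarray, fg_thr: float) -> float:
    """Total foreground intensity captured in 3×3 windows at predicted
    positions — used to pick the rotation-sign candidate."""
    h, w = pixels.shape
    pts = np.rint(positions.reshape(-1, 2)).astype(int)
    score = 0.0
    excess = np.clip(pixels.astype(float) - fg_thr, 0, None)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            x = np.clip(pts[:, 0] + dx, 0, w - 1)
            y = np.clip(pts[:, 1] + dy, 0, h - 1)
            score += float(excess[y, x].sum())
    return score


def fit_grid(
    img: PlateImage,
    spec: GridSpec,
    corners: np.ndarray | None = None,
    theta: float | None = None,
    max_iter: int = 10,
    tol_px: float = 0.1,
) -> GridModel:
    """Fit the affine colony grid to a cropped plate image.

    When ``corners`` is omitted they are estimated from the crop
    geometry: the rotation magnitude comes from the closed-form
    aspect-ratio estimator (or ``theta`` when given), and both sign
    candidates are scored against the image foreground, keeping the
    better one.

    Iteration: predict all positions from the affine model, snap every
    position with detectable signal (foreground fraction > 1% of a
    spacing-sized window) to its local intensity-weighted centroid, refit
    the affine model by least squares; stop when the mean position change
    drops below ``tol_px`` or after ``max_iter`` rounds.

    Raises
    ------
    GridFitError
        If fewer than 3 non-collinear positions carry signal.
    """
    pixels = img.pixels
    fg_thr = _foreground_threshold(pixels)

    if corners is None:
        if theta is None:
            theta = estimate_rotation(
                img.width, img.height, spec.aspect_ratio
            )
        theta = abs(theta)
        candidates = [theta] if theta < np.radians(0.02) else [theta, -theta]
        best, best_score = None, -np.inf
        for th in candidates:
            cand_corners = estimate_corners(img, spec, th)
            cand_coeffs = _affine_from_corners(spec, cand_corners)
            model = GridModel(spec=spec, theta=th, coeffs=cand_coeffs)
            score = _grid_score(pixels, model.affine_positions(), fg_thr)
            if score > best_score:
                best, best_score = th, score
        theta = best
        corners = estimate_corners(img, spec, theta)
    elif theta is None:
        theta = 0.0

    coeffs = _affine_from_corners(spec, np.asarray(corners, dtype=float))
    positions = GridModel(spec=spec, theta=theta, coeffs=coeffs).affine_positions()
    snapped = np.zeros((spec.rows, spec.cols), dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        snapped, centroids = _snap_positions(pixels, coeffs, spec, fg_thr)
        n_anchor = int(snapped.sum())
        if n_anchor < 3:
            raise GridFitError(
                f"only {n_anchor} grid positions carry signal; cannot fit"
            )
        r, c = np.nonzero(snapped)
        design = np.stack([np.ones_like(c), c, r], axis=-1).astype(float)
        if np.linalg.matrix_rank(design) < 3:
            raise GridFitError("anchor positions are collinear; cannot fit")
        new_coeffs, *_ = np.linalg.lstsq(
            design, centroids[r, c], rcond=None
        )
        new_coeffs = new_coeffs.T
        new_positions = GridModel(
            spec=spec, theta=theta, coeffs=new_coeffs
        ).affine_positions()
        shift = float(
            np.mean(np.hypot(*(new_positions - positions).transpose(2, 0, 1)))
        )
        coeffs, positions = new_coeffs, new_positions
        if shift < tol_px:
            break

    # final per-position refinement: affine prediction, snapped where signal
    snapped, centroids = _snap_positions(pixels, coeffs, spec, fg_thr)
    final = positions.copy()
    final[snapped] = centroids[snapped]
    return GridModel(
        spec=spec,
        theta=theta,
        coeffs=coeffs,
        positions=final,
        snapped=snapped,
        n_iter=n_iter,
    )
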