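"""Colony-size normalization: plate, spatial, and intra-plate source.

Raw pixel areas are not comparable across plates (different incubation,
agar volume, camera distance) or across a plate (nutrient gradients,
edge effects).  The pipeline is fixed:

``raw`` → :func:`plate_normalize` → :func:`spatial_correct`
(→ :func:`source_correct` for up-scaled plates)

*Plate normalization* divides by the plate's center statistic (median of
non-missing, non-edge positions), so a typical colony has size 1.
*Spatial correction* divides by a smooth surface estimated as the moving
median over a square grid neighborhood (default 9×9 positions),
removing local nutrient-based growth effects while being robust to
genuine mutant effects.  *Source correction* treats each of the four
interleaved source-plate subgrids of an up-scaled plate as an
independent lower-density plate, removing per-source batch effects.

Medians are used for every center statistic; missing values (NaN)
propagate and are never imputed.
"""

from __future__ import annotations

import numpy as np

from .colony_quant import SizeTable
from .grid import DENSITY_SHAPES, GridSpec

__all__ = [
    "NormalizationError",
    "plate_normalize",
    "spatial_correct",
    "source_correct",
    "DEFAULT_SURFACE_WINDOW",
]

#: side of the square grid-position neighborhood for the spatial surface
DEFAULT_SURFACE_WINDOW = 9


class NormalizationError(RuntimeError):
    pass


def plate_normalize(t: SizeTable) -> SizeTable:
    """Divide by the plate median so the typical colony has size 1.

    The center statistic is the median over non-missing, non-edge
    positions (the outermost ring grows systematically differently).
    Requires a raw table with at least 50% non-missing positions.
    """
    if t.stage != "raw":
        raise NormalizationError(f"plate_normalize expects a raw table, got {t.stage!r}")
    values = t.values
    finite = np.isfinite(values)
    if finite.mean() < 0.5:
        raise NormalizationError(
            f"only {finite.mean():.0%} of positions are non-missing (need >= 50%)"
        )
    interior = values[~t.edge_mask]
    center = np.nanmedian(interior) if np.isfinite(interior).any() else np.nanmedian(values)
    if not np.isfinite(center) or center <= 0:
        raise NormalizationError("plate center statistic is undefined or non-positive")
    return t.with_values(
        values / center, "plate_normalized", f"plate_normalize(median={center:.4g})"
    )


def _moving_nanmedian(values: np.ndarray, window: int) -> np.ndarray:
    """Moving median over a window×window grid neighborhood, NaN-aware,
    truncated (not padded) at the plate borders."""
    half = window // 2
    rows, cols = values.shape
    padded = np.full((rows + 2 * half, cols + 2 * half), np.nan)
    padded[half:half + rows, half:half + cols] = values
    stack = np.empty((window * window, rows, cols))
    idx = 0
    for dr in range(window):
        for dc in range(window):
            stack[idx] = padded[dr:dr + rows, dc:dc + cols]
            idx += 1
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(stack, axis=0)


def spatial_correct(t: SizeTable, window: int = DEFAULT_SURFACE_WINDOW) -> SizeTable:
    """Remove smooth position-dependent growth effects.

    Estimates the spatial surface as the moving median over a
    ``window × window`` neighborhood of grid positions (missing values
    ignored; neighborhoods truncated at plate borders) and divides each
    value by its surface value.  Neighborhoods with no finite values
    fall back to the plate median.
    """
    if t.stage != "plate_normalized":
        raise NormalizationError(
            f"spatial_correct expects a plate_normalized table, got {t.stage!r}"
        )
    surface = _moving_nanmedian(t.values, window)
    fallback = np.nanmedian(t.values)
    surface = np.where(np.isfinite(surface) & (surface > 0), surface, fallback)
    return t.with_values(
        t.values / surface, "spatially_corrected", f"spatial_correct(window={window})"
    )


def source_correct(
    t: SizeTable, interleave: tuple[int, int] = (2, 2), window: int = DEFAULT_SURFACE_WINDOW
) -> SizeTable:
    """Intra-plate source correction for up-scaled plates.

    An up-scaled plate interleaves 4 lower-density source plates in a
    2×2 quadrant pattern: position (r, c) came from source
    ``2*(r%2) + (c%2)``.  Each subgrid is deinterleaved, plate-normalized
    and spatially corrected as an independent lower-density plate, then
    re-interleaved — removing per-source batch effects that plate-level
    normalization cannot see.
    """
    if interleave != (2, 2):
        raise NormalizationError("only the 2×2 quadrant interleave is supported")
    spec = t.spec
    sub_density = spec.density // 4
    if (
        spec.density < 4 * 1536
        or spec.rows % 2
        or spec.cols % 2
        or sub_density not in DENSITY_SHAPES
    ):
        raise NormalizationError(
            f"density {spec.density} is not an up-scaled format "
            "(4 interleaved source plates of >= 1536)"
        )
    if t.stage not in ("raw", "plate_normalized"):
        raise NormalizationError(
            f"source_correct expects a raw or plate_normalized table, got {t.stage!r}"
        )
    sub_spec = GridSpec(
        rows=spec.rows // 2, cols=spec.cols // 2, spacing_px=2 * spec.spacing_px
    )
    out = np.full_like(t.values, np.nan)
    for dr in (0, 1):
        for dc in (0, 1):
            sub = SizeTable(
                spec=sub_spec, values=t.values[dr::2, dc::2], stage="raw"
            )
            corrected = spatial_correct(plate_normalize(sub), window=window)
            out[dr::2, dc::2] = corrected.values
    return t.with_values(
        out, "source_corrected", f"source_correct(interleave=2x2, window={window})"
    )
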