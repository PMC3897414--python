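"""Colony-grid geometry shared across the toolkit.

A plate carries ``rows × cols`` colonies at a fixed center-to-center
``spacing_px``, inset from the agar edge by ``margin_px``.  Supported
densities follow the standard pinning-pad series, each format doubling
rows and columns of the previous one (96 = 8×12 up to 24576 = 128×192).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: density label -> (rows, cols) for the standard pad series
DENSITY_SHAPES: dict[int, tuple[int, int]] = {
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
    6144: (64, 96),
    24576: (128, 192),
}

#: default grid-edge-to-plate-edge margin, in units of spacing
DEFAULT_MARGIN_SPACINGS = 3.5

#: default center-to-center spacing for the 6144 format, pixels.
#: A full plate then renders at roughly 1430×980 px — large enough for
#: sub-pixel position tests while staying desk-scale.
DEFAULT_SPACING_6144 = 14.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a colony grid on a plate.

    Parameters
    ----------
    rows, cols
        Grid dimensions; ``rows * cols`` must be one of the supported
        density labels.
    spacing_px
        Center-to-center distance between neighboring colonies, pixels.
    margin_px
        Distance from the outermost colony centers to the plate (agar)
        edge, pixels.  Defaults to 3.5 spacings.
    """

    rows: int
    cols: int
    spacing_px: float = DEFAULT_SPACING_6144
    margin_px: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be positive")
        if self.density not in DENSITY_SHAPES:
            raise ValueError(
                f"unsupported density {self.density}; "
                f"supported: {sorted(DENSITY_SHAPES)}"
            )
        if DENSITY_SHAPES[self.density] != (self.rows, self.cols):
            raise ValueError(
                f"{self.density} colonies must be arrayed "
                f"{DENSITY_SHAPES[self.density][0]}×{DENSITY_SHAPES[self.density][1]}, "
                f"got {self.rows}×{self.cols}"
            )
        if self.spacing_px <= 0:
            raise ValueError("spacing_px must be positive")
        if self.margin_px < 0:
            # frozen dataclass: bypass immutability for the default fill-in
            object.__setattr__(
                self, "margin_px", DEFAULT_MARGIN_SPACINGS * self.spacing_px
            )

    @property
    def density(self) -> int:
        """Total number of grid positions (the density label)."""
        return self.rows * self.cols

    @property
    def n_positions(self) -> int:
        return self.rows * self.cols

    @property
    def plate_width_px(self) -> float:
        """Agar width implied by the grid: span plus both margins."""
        return (self.cols - 1) * self.spacing_px + 2 * self.margin_px

    @property
    def plate_height_px(self) -> float:
        return (self.rows - 1) * self.spacing_px + 2 * self.margin_px

    @property
    def aspect_ratio(self) -> float:
        """Plate width / height (landscape > 1 for all standard formats)."""
        return self.plate_width_px / self.plate_height_px

    @classmethod
    def from_density(
        cls, density: int, spacing_px: float | None = None, margin_px: float = -1.0
    ) -> "GridSpec":
        """Build a spec from a density label (96/384/1536/6144/24576).

        When ``spacing_px`` is omitted it is scaled from the 6144-format
        default so every density renders a plate of roughly the same
        pixel extent (e.g. 1536 at 28 px, 24576 at 7 px).
        """
        if density not in DENSITY_SHAPES:
            raise ValueError(f"unsupported density {density}")
        rows, cols = DENSITY_SHAPES[density]
        if spacing_px is None:
            cols_6144 = DENSITY_SHAPES[6144][1]
            spacing_px = DEFAULT_SPACING_6144 * cols_6144 / cols
        return cls(rows=rows, cols=cols, spacing_px=spacing_px, margin_px=margin_px)

    def position_xy(self, row, col):
        """Unrotated plate-frame (x, y) of grid position(s) (row, col)."""
        x = self.margin_px + _asarray(col) * self.spacing_px
        y = self.margin_px + _asarray(row) * self.spacing_px
        return x, y


def _asarray(v):
    import numpy as np

    return np.asarray(v, dtype=float)


def parse_grid(text: str) -> GridSpec:
    """Parse a CLI grid argument: a density (``6144``) or ``ROWSxCOLS``."""
    text = text.strip().lower()
    if "x" in text:
        r, c = text.split("x", 1)
        return GridSpec(rows=int(r), cols=int(c))
    return GridSpec.from_density(int(text))
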