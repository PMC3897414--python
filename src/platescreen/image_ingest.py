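"""Load plate photographs and crop them tightly to the plate.

The downstream rotation geometry assumes the cropped image is the tight
axis-aligned bounding box of the (possibly slightly rotated) plate, so
that all four plate corners touch the crop edges.  Cropping therefore
separates the bright agar region from the darker surround, keeps the
largest connected bright component, and returns its bounding box.

Coordinate convention (used everywhere in this package): x = column
index, y = row index, origin at the top-left pixel, 0-based, boxes
half-open ``[x0, x1) × [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import measure

__all__ = ["PlateImage", "CropBox", "load_image", "crop_to_plate"]

#: ITU-R BT.601 luminance weights for RGB → grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PlateImage:
    """8-bit grayscale plate photograph.

    ``pixels`` is a row-major 2-D ``uint8`` array; pixel centers sit at
    integer coordinates.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("PlateImage requires a 2-D raster of at least 2×2")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel box ``[x0, x1) × [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("CropBox must have positive extent")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height


class CropError(RuntimeError):
    """Plate region could not be distinguished from the background."""


def load_image(path) -> PlateImage:
    """Load a PNG/JPEG/TIFF plate photograph as 8-bit grayscale.

    RGB(A) inputs are converted by BT.601 luminance; an alpha channel is
    ignored.
    """
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
        arr = np.clip(np.rint(arr), 0, 255)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}: {path}")
    return PlateImage(pixels=arr.astype(np.uint8), source_path=str(path))


def _intensity_modes(pixels: np.ndarray) -> list[int]:
    """Prominent modes of the intensity histogram, darkest first.

    The histogram is smoothed with a 9-bin triangular kernel; local
    maxima below 1% of the tallest peak are ignored (they are noise or
    minor structures, never the surround or the agar)."""
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    kernel = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1], dtype=float)
    smooth = np.convolve(hist, kernel / kernel.sum(), mode="same")
    floor = 0.01 * smooth.max()
    modes = [
        i
        for i in range(1, 255)
        if smooth[i] >= smooth[i - 1]
        and smooth[i] >= smooth[i + 1]
        and smooth[i] >= floor
    ]
    # collapse plateaus/near-duplicates closer than 10 units
    collapsed: list[int] = []
    for m in modes:
        if collapsed and m - collapsed[-1] < 10:
            continue
        collapsed.append(m)
    return collapsed


def crop_to_plate(
    img: PlateImage, pad: int = 0
) -> tuple[PlateImage, CropBox]:
    """Crop to the tight bounding box of the bright plate region.

    Candidate thresholds are midpoints between adjacent prominent
    intensity modes (dark surround, bright agar, brighter colonies),
    tried darkest first; a threshold is accepted when its largest
    connected bright component covers at least half the image — that
    component is the plate, and its tight bounding box is returned (so
    for a slightly rotated plate every corner lies on a box edge).
    When modes exist but no threshold isolates a plate-sized region, the
    image is taken to be already cropped and returned unchanged.

    Parameters
    ----------
    pad
        Extra pixels retained per side (clipped at the image border).

    Raises
    ------
    CropError
        If no plate/background separation exists at all (near-constant
        image, or the bright region covers < 5% or > 95% of the frame
        for every candidate threshold).
    """
    pixels = img.pixels
    modes = _intensity_modes(pixels)
    if len(modes) < 2:
        raise CropError(
            "intensity histogram is unimodal; cannot distinguish plate "
            "from background"
        )
    for lo, hi in zip(modes, modes[1:]):
        if hi - lo < 20:
            continue
        thr = (lo + hi) / 2.0
        mask = pixels > thr
        frac = mask.mean()
        if frac < 0.05 or frac > 0.95:
            continue
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        biggest = int(np.argmax(counts))
        if counts[biggest] < 0.5 * pixels.size:
            continue
        ys, xs = np.nonzero(labels == biggest)
        x0 = max(int(xs.min()) - pad, 0)
        x1 = min(int(xs.max()) + 1 + pad, img.width)
        y0 = max(int(ys.min()) - pad, 0)
        y1 = min(int(ys.max()) + 1 + pad, img.height)
        box = CropBox(x0, y0, x1, y1)
        cropped = PlateImage(
            pixels=pixels[y0:y1, x0:x1],
            bit_depth=img.bit_depth,
            source_path=img.source_path,
        )
        return cropped, box
    # multimodal but nothing plate-sized above any threshold: the frame
    # is already tight around the plate (agar + colonies only)
    return img, CropBox(0, 0, img.width, img.height)
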