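"""Background estimation, speckle filtering, and single-cell segmentation.

The camera offset plus stray light is estimated from the four image corners
(the cell is guaranteed to sit away from them), subtracted with clamping at
zero, impulse noise is removed with a small median filter, and the cell is
segmented by Otsu thresholding followed by largest-component selection and
hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .exceptions import NoCellFoundError, ValidationError

__all__ = [
    "BackgroundEstimate",
    "CellMask",
    "estimate_background",
    "subtract_background",
    "despeckle",
    "segment_cell",
]

DEFAULT_CORNER_WINDOW_PX = 8
DEFAULT_DESPECKLE_RADIUS_PX = 1
DEFAULT_MIN_CELL_AREA_PX = 200


@dataclass(frozen=True)
class BackgroundEstimate:
    """Scalar background level of one frame/channel and how it was measured."""

    value: float
    corner_window_px: int
    corner_sd: float = 0.0  # pixel SD within the corner windows (noise scale)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("background value must be >= 0")


@dataclass
class CellMask:
    """Binary mask of the segmented single cell in one frame."""

    mask: np.ndarray  # (H, W) bool
    frame_index: int = 0
    area_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        self.area_px = int(self.mask.sum())


def _corner_pixels(image: np.ndarray, w: int) -> np.ndarray:
    return np.concatenate(
        [
            image[:w, :w].ravel(),
            image[:w, -w:].ravel(),
            image[-w:, :w].ravel(),
            image[-w:, -w:].ravel(),
        ]
    )


def estimate_background(
    image: np.ndarray, corner_window_px: int = DEFAULT_CORNER_WINDOW_PX
) -> BackgroundEstimate:
    """Average the four ``w x w`` corner windows of a frame.

    Every corner pixel enters with equal weight, so the estimate equals the
    mean over the union of the four windows.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("background estimation expects a single 2-D frame")
    h, wid = image.shape
    w = int(corner_window_px)
    if w < 1:
        raise ValidationError("corner_window_px must be >= 1")
    if 2 * w > h or 2 * w > wid or 4 * w * w >= h * wid:
        raise ValidationError(
            f"corner windows of {w} px do not fit a {h}x{wid} image"
        )
    px = _corner_pixels(image, w)
    return BackgroundEstimate(
        value=float(px.mean()), corner_window_px=w, corner_sd=float(px.std())
    )


def subtract_background(image: np.ndarray, background: BackgroundEstimate | float) -> np.ndarray:
    """Subtract the scalar background, clamping negative results at zero."""
    value = background.value if isinstance(background, BackgroundEstimate) else float(background)
    return np.maximum(np.asarray(image, dtype=float) - value, 0.0)


def despeckle(image: np.ndarray, radius_px: int = DEFAULT_DESPECKLE_RADIUS_PX) -> np.ndarray:
    """Median filter over a ``(2r+1) x (2r+1)`` window with replicated borders."""
    r = int(radius_px)
    if r < 1:
        raise ValidationError("radius_px must be >= 1")
    return ndimage.median_filter(
        np.asarray(image, dtype=float), size=2 * r + 1, mode="nearest"
    )


def segment_cell(
    image: np.ndarray,
    min_cell_area_px: int = DEFAULT_MIN_CELL_AREA_PX,
    frame_index: int = 0,
) -> CellMask:
    """Segment the single adherent cell in a background-subtracted frame.

    Pipeline: global Otsu threshold over the nonzero intensities, keep the
    largest 4-connected foreground component, fill its holes.  If every
    nonzero pixel shares one value (a clean two-level image) the threshold is
    placed halfway between zero and that value.

    Raises
    ------
    NoCellFoundError
        If there is no foreground or the largest component is smaller than
        ``min_cell_area_px``.
    """
    image = np.asarray(image, dtype=float)
    nonzero = image[image > 0]
    if nonzero.size == 0:
        raise NoCellFoundError(f"frame {frame_index}: image has no positive pixels")
    if np.ptp(nonzero) == 0:
        thr = float(nonzero[0]) / 2.0
    else:
        thr = float(threshold_otsu(nonzero))
    binary = image > thr
    labels = label(binary, connectivity=1)  # 4-connectivity
    if labels.max() == 0:
        raise NoCellFoundError(f"frame {frame_index}: nothing above threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(counts.argmax())
    mask = ndimage.binary_fill_holes(labels == biggest)
    area = int(mask.sum())
    if area < int(min_cell_area_px):
        raise NoCellFoundError(
            f"frame {frame_index}: largest component has {area} px "
            f"< min_cell_area_px={min_cell_area_px}"
        )
    return CellMask(mask=mask, frame_index=frame_index, area_px=area)
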