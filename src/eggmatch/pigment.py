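"""Percent-pigmentation index: Bernsen local thresholding over a standard ROI.

The pigment score of an egg is the percentage of black pixels after local
binarisation, measured inside a standardised oval at the large pole - the
region where maculation is typically densest.  The oval is inscribed in a
3.4 cm x 2.4 cm block converted to pixels at each image's physical scale, so
the same physical (and, at a common scale, pixel) area is measured on every
egg and scores are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageprep import EggMask

__all__ = [
    "PigmentParams",
    "PigmentResult",
    "RoiError",
    "bernsen_threshold",
    "large_pole_roi",
    "percent_black",
    "pigment_score",
]

#: standard measurement block, physical units (height along long axis, width)
STANDARD_BLOCK_CM = (3.4, 2.4)


class RoiError(ValueError):
    """The standard oval cannot be placed inside the egg."""


@dataclass(frozen=True)
class PigmentParams:
    """Bernsen threshold and ROI settings.

    The original protocol names Bernsen thresholding but not its parameters;
    the defaults here (15 px window radius, contrast limit 15, low-contrast
    pixels treated as unpigmented background) are package choices and every
    reported percentage is conditional on them.
    """

    window_radius_px: int = 15
    contrast_limit: int = 15
    block_cm: tuple[float, float] = STANDARD_BLOCK_CM
    inset_px: int = 1


@dataclass(frozen=True)
class PigmentResult:
    egg_id: str
    percent_black: float
    roi_area_px: int
    window_radius_px: int
    contrast_limit: int


def bernsen_threshold(gray: np.ndarray, window_radius_px: int = 15,
                      contrast_limit: int = 15) -> np.ndarray:
    """Local midrange binarisation (Bernsen).

    For each pixel the threshold is ``(local max + local min) / 2`` over a
    square window of side ``2 r + 1`` (edges replicate).  Pixels darker than
    their local threshold are marked black (True).  Where the local contrast
    ``max - min`` falls below ``contrast_limit`` the neighbourhood is deemed
    unpatterned and the pixel is assigned to the background (white).
    """
    if gray.ndim != 2:
        raise ValueError("bernsen_threshold expects a 2-D grayscale image")
    if gray.dtype != np.uint8:
        raise ValueError("bernsen_threshold expects 8-bit input")
    size = 2 * window_radius_px + 1
    if size > min(gray.shape):
        raise ValueError(
            f"window ({size} px) larger than image {gray.shape}")
    g = gray.astype(np.int16)
    local_max = ndimage.maximum_filter(g, size=size, mode="nearest")
    local_min = ndimage.minimum_filter(g, size=size, mode="nearest")
    midrange = (local_max + local_min) / 2.0
    low_contrast = (local_max - local_min) < contrast_limit
    black = g < midrange
    black[low_contrast] = False
    return black


def large_pole_roi(mask: EggMask, mm_per_px: float,
                   block_cm: tuple[float, float] = STANDARD_BLOCK_CM,
                   inset_px: int = 1) -> np.ndarray:
    """Place the standard oval tangent to the egg outline at the large pole.

    The oval is inscribed in the physical block converted to pixels, centred
    on the egg's column centroid, and slid down from the pole (starting
    ``inset_px`` inside the outline, which keeps the binarisation's dark rim
    artefact out of the count) until it lies entirely inside the mask.  The
    rasterised oval uses an integer centre, so its pixel area is identical
    for every egg analysed at the same scale.  Raises :class:`RoiError` when
    the egg is too small for the standard block.
    """
    m = mask.mask
    if mask.large_pole_end == "bottom":
        m = np.flipud(m)
    h_px = block_cm[0] * 10.0 / mm_per_px
    w_px = block_cm[1] * 10.0 / mm_per_px
    a = h_px / 2.0
    b = w_px / 2.0
    rows = np.where(m.any(axis=1))[0]
    cols_idx = np.where(m.any(axis=0))[0]
    if (rows[-1] - rows[0] + 1) < h_px or (cols_idx[-1] - cols_idx[0] + 1) < w_px:
        raise RoiError(
            f"egg extent smaller than the standard {block_cm[0]} x {block_cm[1]} cm block")
    cx = int(round(cols_idx.mean()))
    yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
    offset = inset_px
    while True:
        cy = int(round(rows[0] + offset + a))
        if cy + a > rows[-1]:  # slid past the small pole: cannot fit
            raise RoiError("standard oval does not fit inside the egg mask")
        oval = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        if not np.any(oval & ~m):
            if mask.large_pole_end == "bottom":
                oval = np.flipud(oval)
            return oval
        offset += 1


def percent_black(binary: np.ndarray, roi: np.ndarray) -> float:
    """Percentage of ROI pixels marked black; black + white is exactly 100."""
    if binary.shape != roi.shape:
        raise ValueError("binary image and ROI must have the same shape")
    total = int(roi.sum())
    if total == 0:
        raise ValueError("empty ROI")
    return 100.0 * float(binary[roi].sum()) / total


def pigment_score(gray: np.ndarray, mask: EggMask, mm_per_px: float,
                  egg_id: str = "egg",
                  params: PigmentParams | None = None) -> PigmentResult:
    """Full pigment index for one egg: Bernsen + standard oval + percentage."""
    params = params or PigmentParams()
    binary = bernsen_threshold(gray, params.window_radius_px, params.contrast_limit)
    roi = large_pole_roi(mask, mm_per_px, params.block_cm, params.inset_px)
    pct = percent_black(binary, roi)
    return PigmentResult(egg_id=egg_id, percent_black=pct,
                         roi_area_px=int(roi.sum()),
                         window_radius_px=params.window_radius_px,
                         contrast_limit=params.contrast_limit)
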