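"""Image standardisation: grayscale conversion, egg segmentation, quality gates.

Field photographs arrive as colour images of single eggs on a contrasting
board.  Before pattern features or pigment fractions can be measured, each
image is converted to 8-bit grayscale, the egg is segmented from the
background, and obviously unusable shots (out of focus, overexposed) are
excluded while staying in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure, transform
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

__all__ = [
    "EggImage",
    "EggMask",
    "QualityThresholds",
    "QualityDecision",
    "SegmentationError",
    "to_grayscale",
    "segment_egg",
    "quality_filter",
    "orient_canonical",
    "load_egg_image",
]

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])  # standard luminance


class SegmentationError(RuntimeError):
    """No plausible egg region found in the image."""


@dataclass
class EggImage:
    """A single egg photograph with its physical scale and identity."""

    pixels: np.ndarray  # (H, W) gray or (H, W, 3) colour
    mm_per_px: float
    egg_id: str | None = None
    clutch_id: str | None = None
    quality_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass
class EggMask:
    """Binary egg-versus-background mask plus the large-pole convention."""

    mask: np.ndarray  # bool, same shape as the gray image
    large_pole_end: str  # "top" or "bottom"

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            raise ValueError("mask area must be > 0")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def load_egg_image(path: str | Path, mm_per_px: float,
                   egg_id: str | None = None,
                   clutch_id: str | None = None) -> EggImage:
    """Read a PNG/TIFF/JPEG egg photo from disk."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return EggImage(pixels=arr, mm_per_px=mm_per_px,
                    egg_id=egg_id or Path(path).stem, clutch_id=clutch_id)


def to_grayscale(img: EggImage) -> EggImage:
    """8-bit luminance conversion; a no-op on images that are already gray."""
    if img.pixels.size == 0:
        raise ValueError("empty image")
    if img.is_gray:
        pixels = img.pixels
        if pixels.dtype != np.uint8:
            pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
        return EggImage(pixels=pixels, mm_per_px=img.mm_per_px,
                        egg_id=img.egg_id, clutch_id=img.clutch_id,
                        quality_flags=set(img.quality_flags))
    gray = img.pixels[..., :3].astype(float) @ GRAY_WEIGHTS
    gray = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    return EggImage(pixels=gray, mm_per_px=img.mm_per_px,
                    egg_id=img.egg_id, clutch_id=img.clutch_id,
                    quality_flags=set(img.quality_flags))


def segment_egg(img: EggImage, min_area_px: int = 100) -> EggMask:
    """Separate the egg from the background and locate the large pole.

    Otsu's threshold splits the bright shell from the dark board; interior
    holes left by dark maculation are filled and the largest connected
    component is kept.  The large pole is the mask half (split at the middle
    of the vertical extent) with the greater area; exact ties resolve to the
    image top, which is also the rendering convention of the synthetic data.
    """
    gray = to_grayscale(img).pixels
    if gray.max() == gray.min():
        raise SegmentationError("uniform image: no egg/background contrast")
    thresh = threshold_otsu(gray)
    fg = gray > thresh
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no foreground region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = labels == biggest
    # dark maculation touching the outline leaves notches that hole-filling
    # cannot close; the shell itself is convex, so take the convex hull
    mask = convex_hull_image(mask)
    if mask.sum() < min_area_px:
        raise SegmentationError(
            f"largest region ({int(mask.sum())} px) below minimum {min_area_px} px")
    top_area, bottom_area = _half_areas(mask)
    large_pole = "top" if top_area >= bottom_area else "bottom"
    return EggMask(mask=mask, large_pole_end=large_pole)


def _half_areas(mask: np.ndarray) -> tuple[int, int]:
    """Mask area above/below the exact centre of its vertical extent.

    An exact middle row (odd extent) belongs to neither half, so a
    vertically symmetric shape ties exactly.
    """
    rows = np.where(mask.any(axis=1))[0]
    centre = (rows[0] + rows[-1]) / 2.0
    row_idx = np.arange(mask.shape[0])
    row_sums = mask.sum(axis=1)
    return (int(row_sums[row_idx < centre].sum()),
            int(row_sums[row_idx > centre].sum()))


@dataclass(frozen=True)
class QualityThresholds:
    """Numeric stand-ins for the field protocol's visual exclusion judgments.

    ``blur_floor`` is a floor on the variance of the Laplacian inside the egg
    (a standard focus measure); ``clip_ceiling`` caps the fraction of
    saturated pixels.
    """

    blur_floor: float = 15.0
    clip_ceiling: float = 0.10
    saturation_level: int = 254


@dataclass(frozen=True)
class QualityDecision:
    keep: bool
    reason: str | None = None


def quality_filter(img: EggImage, thresholds: QualityThresholds | None = None,
                   mask: EggMask | None = None) -> QualityDecision:
    """Keep or exclude an egg image, recording the reason.

    Excluded eggs are dropped from downstream analyses but never from the
    manifest, so retained + excluded always equals the input count.
    """
    thresholds = thresholds or QualityThresholds()
    gray = to_grayscale(img).pixels.astype(float)
    region = mask.mask if mask is not None else np.ones_like(gray, dtype=bool)
    clip_frac = float((gray[region] >= thresholds.saturation_level).mean())
    if clip_frac > thresholds.clip_ceiling:
        return QualityDecision(keep=False, reason="overexposed")
    lap = ndimage.laplace(gray)
    focus = float(lap[region].var())
    if focus < thresholds.blur_floor:
        return QualityDecision(keep=False, reason="blurry")
    return QualityDecision(keep=True)


def orient_canonical(img: EggImage, mask: EggMask) -> tuple[EggImage, EggMask]:
    """Rotate so the egg's long axis is vertical with the large pole on top.

    Rotations that are (within 1 degree) multiples of 90 degrees are applied
    exactly with ``np.rot90``; anything else is interpolated.  Synthetic eggs
    are rendered in canonical pose already, so this is usually the identity.
    """
    gray = to_grayscale(img)
    props = measure.regionprops(mask.mask.astype(np.uint8))[0]
    # regionprops orientation: angle between vertical axis and major axis
    angle_deg = -np.degrees(props.orientation)
    nearest90 = round(angle_deg / 90.0) * 90
    if abs(angle_deg - nearest90) <= 1.0:
        k = (nearest90 // 90) % 4
        pixels = np.rot90(gray.pixels, k=k)
        m = np.rot90(mask.mask, k=k)
    else:
        pixels = transform.rotate(gray.pixels.astype(float), angle_deg,
                                  resize=True, preserve_range=True,
                                  cval=float(gray.pixels.min()))
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
        m = transform.rotate(mask.mask.astype(float), angle_deg,
                             resize=True, preserve_range=True) > 0.5
    top_area, bottom_area = _half_areas(m)
    if top_area < bottom_area:
        pixels = np.flipud(pixels)
        m = np.flipud(m)
    out_img = EggImage(pixels=np.ascontiguousarray(pixels),
                       mm_per_px=img.mm_per_px, egg_id=img.egg_id,
                       clutch_id=img.clutch_id, quality_flags=set(img.quality_flags))
    return out_img, EggMask(mask=np.ascontiguousarray(m), large_pole_end="top")
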