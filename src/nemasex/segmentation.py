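"""Binarization and candidate-worm region extraction from plate images.

Brightfield plate scans show worms as dark elongated objects on a bright
agar background. The pipeline here is: adaptive local-mean thresholding
(robust to the uneven illumination typical of stitched plate scans),
hole filling, 8-connected component labelling, and a physical-unit size
filter that discards debris specks, eggs and truncated border objects
before any shape measurement is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops


class InvalidParameterError(ValueError):
    """A configuration value is outside its documented range."""


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2-D grayscale plate image with its physical calibration.

    Parameters
    ----------
    pixels:
        2-D array of intensities (integer or float).
    um_per_pixel:
        Physical scale in micrometres per pixel. Plate scanners for
        adult *C. elegans* typically run at 6-7 um/px; the default
        calibration is 6.5.
    """

    pixels: np.ndarray
    um_per_pixel: float = 6.5

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidParameterError("image must be a non-empty 2-D array")
        if not self.um_per_pixel > 0:
            raise InvalidParameterError("um_per_pixel must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask aligned with its source image."""

    pixels: np.ndarray
    um_per_pixel: float

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))


@dataclass(frozen=True)
class WormRegion:
    """One connected candidate-worm object.

    ``mask`` is cropped to the bounding box; ``bbox`` is
    (row0, col0, height, width), 0-based, half-open.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area_px: int
    touches_border: bool
    um_per_pixel: float
    region_id: int = 0


@dataclass(frozen=True)
class RegionFilterConfig:
    """Physical-unit bounds for screening out non-worm objects.

    Defaults bracket L4-to-adult *C. elegans* at 6-7 um/px: eggs
    (~1500 um^2) and debris specks fall below ``min_area_um2``, while
    merged clumps much larger than a single adult exceed
    ``max_area_um2``. Border-touching objects are excluded by default
    because their shape parameters would be truncated.
    """

    min_area_um2: float = 3_000.0
    max_area_um2: float = 120_000.0
    min_bbox_diag_um: float = 120.0
    max_bbox_diag_um: float = 2_500.0
    exclude_border: bool = True

    def __post_init__(self):
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise InvalidParameterError("area bounds must satisfy 0 < min < max")
        if not (0 < self.min_bbox_diag_um < self.max_bbox_diag_um):
            raise InvalidParameterError("bbox diagonal bounds must satisfy 0 < min < max")


def binarize(
    image: GrayscaleImage,
    window_um: float = 300.0,
    offset: float = 0.02,
    dark_foreground: bool = True,
) -> BinaryMask:
    """Adaptive local-mean threshold of a plate image.

    A pixel is foreground when it is darker than the mean intensity of
    the square window of physical side ``window_um`` centred on it, by
    more than ``offset`` times the image intensity range. Holes inside
    foreground components are filled so that downstream skeletons are
    not perforated. A constant image yields an empty mask.

    The default 300 um window is roughly one worm-width scale above
    adult body thickness, large enough to average over a worm body and
    small enough to track illumination gradients.

    Set ``dark_foreground=False`` for bright objects on dark background.
    """
    if not np.isfinite(window_um) or window_um <= 0:
        raise InvalidParameterError("window_um must be positive")
    win_px = int(round(window_um / image.um_per_pixel))
    if win_px < 3:
        raise InvalidParameterError(
            f"window of {window_um} um spans only {win_px} px at "
            f"{image.um_per_pixel} um/px; need >= 3 px"
        )
    px = image.pixels.astype(np.float64)
    rng = float(px.max() - px.min())
    if rng == 0.0:
        return BinaryMask(np.zeros(px.shape, dtype=bool), image.um_per_pixel)
    local_mean = ndi.uniform_filter(px, size=win_px, mode="reflect")
    delta = offset * rng
    if dark_foreground:
        fg = px < (local_mean - delta)
    else:
        fg = px > (local_mean + delta)
    fg = ndi.binary_fill_holes(fg)
    return BinaryMask(fg, image.um_per_pixel)


def extract_regions(mask: BinaryMask, cfg: RegionFilterConfig | None = None) -> list[WormRegion]:
    """8-connected components of the mask, size-filtered, sorted by bbox origin.

    Components outside the area or bounding-box-diagonal bounds are
    discarded, as are border-touching components when
    ``cfg.exclude_border`` is set. Returns an empty list for an empty
    mask.
    """
    if cfg is None:
        cfg = RegionFilterConfig()
    upp = mask.um_per_pixel
    lab = label(mask.pixels, connectivity=2)
    nrow, ncol = mask.pixels.shape
    # drop sub-threshold specks before regionprops; noisy plates produce
    # thousands of 1-2 px components that would dominate the runtime
    min_area_px = int(np.floor(cfg.min_area_um2 / (upp * upp)))
    if min_area_px > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = sizes >= min_area_px
        lab = np.where(keep[lab], lab, 0)
    out: list[WormRegion] = []
    for prop in regionprops(lab):
        r0, c0, r1, c1 = prop.bbox
        h, w = r1 - r0, c1 - c0
        touches = r0 == 0 or c0 == 0 or r1 == nrow or c1 == ncol
        area_um2 = prop.area * upp * upp
        diag_um = float(np.hypot(h, w)) * upp
        if not (cfg.min_area_um2 <= area_um2 <= cfg.max_area_um2):
            continue
        if not (cfg.min_bbox_diag_um <= diag_um <= cfg.max_bbox_diag_um):
            continue
        if cfg.exclude_border and touches:
            continue
        out.append(
            WormRegion(
                mask=prop.image.copy(),
                bbox=(r0, c0, h, w),
                area_px=int(prop.area),
                touches_border=touches,
                um_per_pixel=upp,
            )
        )
    out.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    return [
        WormRegion(r.mask, r.bbox, r.area_px, r.touches_border, r.um_per_pixel, region_id=i)
        for i, r in enumerate(out)
    ]
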