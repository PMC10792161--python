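"""Foveal circular ROI construction and slab binarization.

Two binarization routes, matching standard OCTA practice:

* global thresholding (Otsu by default, plain mean as an option) for the
  superficial and deep capillary plexus slabs, with the threshold computed
  from intensities inside the ROI only;
* Phansalkar local adaptive thresholding for the low-contrast
  choriocapillaris slab, with the local threshold

      T = m * (1 + p * exp(-q * m) + k * (s / r - 1))

  where m and s are the mean and (population) standard deviation of the
  intensities in a circular window around each pixel. The window is
  truncated at image borders. Ties are background everywhere: a pixel is
  foreground iff its intensity is strictly above its threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from octaquant.imaging_io import EnFaceSlab, SlabKind

logger = logging.getLogger(__name__)

DEFAULT_ROI_RADIUS_MM = 1.5


@dataclass(frozen=True)
class CircularROI:
    """Foveal disc mask in pixel space.

    ``mask`` is True exactly where the pixel-center Euclidean distance to
    ``center_px`` is <= ``radius_px``. Construction fails if the disc is
    not fully inside the image.
    """

    center_px: tuple[float, float]
    radius_mm: float
    radius_px: float
    mask: np.ndarray = field(repr=False)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def make_roi(slab: EnFaceSlab, radius_mm: float = DEFAULT_ROI_RADIUS_MM) -> CircularROI:
    """Build the circular measurement ROI centered on the fovea.

    The radius in pixels is ``radius_mm / pixel_pitch``; pixel centers at
    integer coordinates, distance compared with <=.

    Raises
    ------
    ValueError
        If the fovea center is unset, the radius is not positive, or the
        disc extends beyond the image bounds (fovea too close to an edge).
    """
    if slab.fovea_center_px is None:
        raise ValueError("slab has no fovea_center_px; the fovea is a required input")
    if not radius_mm > 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    r0, c0 = slab.fovea_center_px
    radius_px = radius_mm / slab.pixel_pitch_mm
    nrows, ncols = slab.shape
    if (r0 - radius_px < -0.5 or r0 + radius_px > nrows - 0.5
            or c0 - radius_px < -0.5 or c0 + radius_px > ncols - 0.5):
        raise ValueError(
            f"ROI of radius {radius_px:.1f} px at ({r0}, {c0}) extends outside "
            f"the {nrows}x{ncols} image"
        )
    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px**2
    roi = CircularROI(center_px=(r0, c0), radius_mm=radius_mm,
                      radius_px=radius_px, mask=mask)
    if roi.pixel_count == 0:
        raise ValueError("ROI mask is empty")
    logger.debug("ROI radius %.2f px, %d pixels", radius_px, roi.pixel_count)
    return roi


def full_frame_roi(shape: tuple[int, int]) -> CircularROI:
    """A whole-frame measurement region (every pixel included).

    Useful when a metric should be taken over the full scan rather than
    the foveal disc, e.g. when validating against a generator whose
    ground-truth fractions are defined over the whole image. Implemented
    as a circular ROI whose radius exceeds the frame diagonal, so the
    distance rule trivially includes every pixel.
    """
    nrows, ncols = shape
    radius_px = float(np.hypot(nrows, ncols)) + 1.0
    return CircularROI(
        center_px=((nrows - 1) / 2, (ncols - 1) / 2),
        radius_mm=float("nan"),
        radius_px=radius_px,
        mask=np.ones(shape, dtype=bool),
    )


@dataclass(frozen=True)
class BinaryMask:
    """Foreground/background mask with full thresholding provenance."""

    mask: np.ndarray = field(repr=False)
    thresholder: str = ""
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class PhansalkarParams:
    """Parameters of the Phansalkar local threshold.

    Defaults follow the de-facto standard implementation: circular window
    of radius 15 px, k = 0.25, r = 0.5, p = 2, q = 10. ``r`` is the
    dynamic-range normalizer of the local standard deviation and assumes
    intensities in [0, 1].
    """

    window_radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.window_radius_px < 1:
            raise ValueError("window_radius_px must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")


def binarize_global(
    slab: EnFaceSlab, roi: CircularROI, method: str = "otsu"
) -> BinaryMask:
    """Binarize an SCP/DCP slab with a single ROI-wide threshold.

    The threshold is computed from intensities inside the ROI only; pixels
    strictly above it are foreground; everything outside the ROI is
    background. A constant ROI yields an all-background mask with a warning
    (the threshold is degenerate).
    """
    if slab.slab_kind not in (SlabKind.SCP, SlabKind.DCP):
        raise ValueError(
            f"global binarization applies to SCP/DCP slabs, got {slab.slab_kind}"
        )
    if slab.shape != roi.mask.shape:
        raise ValueError("slab and ROI shapes differ")
    values = slab.image[roi.mask]
    if np.ptp(values) == 0:
        logger.warning("constant image inside ROI: degenerate threshold, "
                       "returning all-background mask")
        mask = np.zeros(slab.shape, dtype=bool)
        return BinaryMask(mask, thresholder=f"global-{method}",
                          params={"threshold": float(values[0]), "degenerate": True})
    if method == "otsu":
        thr = float(threshold_otsu(values))
    elif method == "mean":
        thr = float(values.mean())
    else:
        raise ValueError(f"unknown global threshold method: {method!r}")
    mask = (slab.image > thr) & roi.mask
    return BinaryMask(mask, thresholder=f"global-{method}",
                      params={"threshold": thr})


def _circular_footprint(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius**2


def local_mean_std(
    image: np.ndarray, window_radius_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and population std over a circular window.

    At image borders the window is truncated to in-bounds pixels, i.e. the
    statistics are always over the pixels actually present.
    """
    footprint = _circular_footprint(window_radius_px).astype(float)
    kwargs = dict(mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(image), footprint, **kwargs)
    sums = ndimage.correlate(image, footprint, **kwargs)
    sumsq = ndimage.correlate(image**2, footprint, **kwargs)
    mean = sums / counts
    var = np.maximum(sumsq / counts - mean**2, 0.0)
    return mean, np.sqrt(var)


def phansalkar_threshold_map(
    image: np.ndarray, params: PhansalkarParams
) -> np.ndarray:
    """Per-pixel Phansalkar threshold T = m(1 + p e^{-qm} + k(s/r - 1))."""
    m, s = local_mean_std(image, params.window_radius_px)
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1.0))


def binarize_phansalkar(
    slab: EnFaceSlab,
    roi: CircularROI,
    params: PhansalkarParams | None = None,
) -> BinaryMask:
    """Binarize a choriocapillaris slab with the Phansalkar local threshold.

    Each ROI pixel is foreground iff its intensity strictly exceeds its
    local threshold; outside-ROI pixels are background.

    Raises
    ------
    ValueError
        If the slab is not a CC slab or the window radius exceeds half the
        smaller image side.
    """
    if params is None:
        params = PhansalkarParams()
    if slab.slab_kind is not SlabKind.CC:
        raise ValueError(
            f"Phansalkar binarization applies to CC slabs, got {slab.slab_kind}"
        )
    if slab.shape != roi.mask.shape:
        raise ValueError("slab and ROI shapes differ")
    if params.window_radius_px > min(slab.shape) // 2:
        raise ValueError(
            f"window_radius_px={params.window_radius_px} exceeds half the "
            f"image size {slab.shape}"
        )
    threshold = phansalkar_threshold_map(slab.image, params)
    mask = (slab.image > threshold) & roi.mask
    return BinaryMask(
        mask,
        thresholder="phansalkar",
        params={
            "window_radius_px": params.window_radius_px,
            "k": params.k,
            "r": params.r,
            "p": params.p,
            "q": params.q,
        },
    )
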