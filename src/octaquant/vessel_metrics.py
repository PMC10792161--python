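"""Skeleton-based vessel metrics inside the foveal ROI.

Definitions (all on pixel counts — every metric is a ratio, so the
physical pixel pitch cancels):

* perfusion density        PD  = 100 * |foreground ∩ ROI| / |ROI|
* vessel length density    VLD = 100 * |skeleton ∩ ROI| / |ROI|
* vessel diameter index    VDI = |foreground ∩ ROI| / |skeleton ∩ ROI|

VLD is a percent of ROI area (skeleton-pixel fraction), the convention in
which typical macular plexus values are a few percent. VDI is the
dimensionless area/length pixel ratio, a surrogate for mean vessel caliber
in pixels; it satisfies PD = VDI * VLD whenever the skeleton is non-empty.
PDCC is the perfusion density of a Phansalkar-binarized choriocapillaris
slab, same formula as PD.

Foreground and skeleton use 8-connectivity throughout; thinning is the
Zhang-Suen 2-D method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from octaquant.imaging_io import SlabKind
from octaquant.roi_threshold import BinaryMask, CircularROI


@dataclass(frozen=True)
class SkeletonMask:
    """1-px-wide centerline mask produced by topology-preserving thinning."""

    mask: np.ndarray = field(repr=False)
    algorithm: str = "zhang-suen"


@dataclass(frozen=True)
class VesselMetrics:
    """PD / VLD / VDI for one slab of one eye.

    ``vdi`` is None (undefined) when the skeleton is empty while the mask
    is also empty or not; callers must check before use.
    """

    pd_percent: float
    vld_percent: float
    vdi: float | None
    slab_kind: SlabKind | None = None
    provenance: dict = field(default_factory=dict)


def skeletonize(mask: BinaryMask, roi: CircularROI) -> SkeletonMask:
    """Thin a binarized plexus mask to 1-px-wide centerlines.

    The skeleton is a subset of the foreground and preserves the
    8-connected component count of the source within the ROI. An empty
    mask yields an empty skeleton.
    """
    if mask.shape != roi.mask.shape:
        raise ValueError("mask and ROI shapes differ")
    fg = mask.mask & roi.mask
    skel = _skimage_skeletonize(fg, method="zhang")
    return SkeletonMask(mask=skel & fg)


def compute_plexus_metrics(
    mask: BinaryMask,
    skeleton: SkeletonMask,
    roi: CircularROI,
    slab_kind: SlabKind | None = None,
) -> VesselMetrics:
    """Compute PD, VLD and VDI from a binarized mask and its skeleton.

    Raises
    ------
    ValueError
        If shapes disagree, the ROI is empty, or the skeleton is not a
        subset of the mask.
    """
    if not (mask.shape == skeleton.mask.shape == roi.mask.shape):
        raise ValueError("mask, skeleton and ROI shapes differ")
    if roi.pixel_count == 0:
        raise ValueError("empty ROI")
    if np.any(skeleton.mask & ~mask.mask):
        raise ValueError("skeleton is not a subset of its source mask")
    n_roi = roi.pixel_count
    n_fg = int((mask.mask & roi.mask).sum())
    n_skel = int((skeleton.mask & roi.mask).sum())
    pd_percent = 100.0 * n_fg / n_roi
    vld_percent = 100.0 * n_skel / n_roi
    vdi = (n_fg / n_skel) if n_skel > 0 else None
    return VesselMetrics(
        pd_percent=pd_percent,
        vld_percent=vld_percent,
        vdi=vdi,
        slab_kind=slab_kind,
        provenance={
            "thresholder": mask.thresholder,
            "threshold_params": dict(mask.params),
            "skeleton_algorithm": skeleton.algorithm,
            "roi_pixels": n_roi,
        },
    )


def compute_pdcc(mask: BinaryMask, roi: CircularROI) -> float:
    """Choriocapillaris perfusion density: percent of ROI that is foreground."""
    if mask.shape != roi.mask.shape:
        raise ValueError("mask and ROI shapes differ")
    if roi.pixel_count == 0:
        raise ValueError("empty ROI")
    return 100.0 * int((mask.mask & roi.mask).sum()) / roi.pixel_count
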