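"""Normalized ellipsoid-zone reflectivity.

Raw en-face brightness is not comparable across subjects: acquisition gain,
media opacity and illumination all rescale the signal. The standard remedy
is a two-point normalization against structures of known relative
brightness within the same eye — the vitreous as the dark reference and the
retinal nerve fiber layer (RNFL) as the bright reference:

    ez_norm = (mean_EZ - mean_dark) / (mean_bright - mean_dark)

Because all three means come from the same acquisition, any global affine
intensity transform a*I + b (a > 0) cancels exactly; ez_norm is the
position of the EZ brightness on the eye's own dark-to-bright scale. It is
typically in [0, 1] but is deliberately not clamped — out-of-range values
are diagnostic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from octaquant.imaging_io import EnFaceSlab
from octaquant.roi_threshold import CircularROI


@dataclass(frozen=True)
class ReflectivityResult:
    mean_ez: float
    mean_dark: float
    mean_bright: float
    ez_norm: float


def _region_mean(slab: EnFaceSlab, roi: CircularROI | None) -> float:
    if roi is None:
        values = slab.image
    else:
        if slab.shape != roi.mask.shape:
            raise ValueError("slab and ROI shapes differ")
        values = slab.image[roi.mask]
    if values.size == 0:
        raise ValueError("reference region is empty")
    return float(np.mean(values))


def normalized_reflectivity(
    ez: EnFaceSlab,
    dark_ref: EnFaceSlab,
    bright_ref: EnFaceSlab,
    roi: CircularROI,
    reference_scope: str = "full",
) -> ReflectivityResult:
    """Compute the two-point normalized EZ reflectivity for one eye.

    Parameters
    ----------
    ez, dark_ref, bright_ref
        Same-shape slabs from the same eye: the ellipsoid-zone en-face
        image and the vitreous (dark) and RNFL (bright) references.
    roi
        Foveal measurement ROI applied to the EZ slab.
    reference_scope
        "full": reference means over the whole reference slabs (default);
        "roi": reference means restricted to the same ROI. Exposed because
        either convention is defensible; the choice is recorded by the
        caller's provenance, not hidden.

    Raises
    ------
    ValueError
        If shapes disagree, a reference region is empty, or the bright
        reference mean does not exceed the dark one (references inverted
        or degenerate).
    """
    if not (ez.shape == dark_ref.shape == bright_ref.shape):
        raise ValueError("EZ and reference slabs must share one shape")
    if reference_scope not in ("full", "roi"):
        raise ValueError(f"reference_scope must be 'full' or 'roi', got {reference_scope!r}")
    ref_roi = roi if reference_scope == "roi" else None
    mean_ez = _region_mean(ez, roi)
    mean_dark = _region_mean(dark_ref, ref_roi)
    mean_bright = _region_mean(bright_ref, ref_roi)
    if not mean_bright > mean_dark:
        raise ValueError(
            f"bright reference mean ({mean_bright:.4g}) must exceed dark "
            f"reference mean ({mean_dark:.4g}); references inverted or degenerate"
        )
    ez_norm = (mean_ez - mean_dark) / (mean_bright - mean_dark)
    return ReflectivityResult(mean_ez, mean_dark, mean_bright, ez_norm)


def affine_invariance_check(
    ez: EnFaceSlab,
    dark_ref: EnFaceSlab,
    bright_ref: EnFaceSlab,
    roi: CircularROI,
    gain: float,
    offset: float,
    tol: float = 1e-10,
    reference_scope: str = "full",
) -> bool:
    """Verify ez_norm is unchanged by a shared affine transform a*I + b.

    The transform is applied jointly to all three slabs with clipping
    disabled (the [0,1] slab invariant is bypassed for the check, since
    a*I + b may leave the unit interval). Returns True iff the two ez_norm
    values agree within ``tol``.
    """
    if not gain > 0:
        raise ValueError(f"gain must be positive, got {gain}")

    original = normalized_reflectivity(ez, dark_ref, bright_ref, roi,
                                       reference_scope=reference_scope)

    def transform(slab: EnFaceSlab) -> EnFaceSlab:
        # shallow copy skips __post_init__, so the [0,1] intensity invariant
        # is deliberately bypassed for the unclipped transform
        out = copy.copy(slab)
        out.image = gain * slab.image + offset
        return out

    transformed = normalized_reflectivity(
        transform(ez), transform(dark_ref), transform(bright_ref), roi,
        reference_scope=reference_scope,
    )
    return abs(transformed.ez_norm - original.ez_norm) <= tol
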