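"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately recompute quantities by direct enumeration
or closed form, independent of the library's vectorized code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from octaquant.imaging_io import EnFaceSlab, SlabKind
from octaquant.roi_threshold import CircularROI, make_roi


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def phansalkar_oracle(
    image: np.ndarray,
    roi_mask: np.ndarray,
    window_radius: int,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Per-pixel brute-force Phansalkar mask.

    For every ROI pixel, gathers the in-bounds pixels of the circular
    window by explicit slicing, computes mean m and population std s
    directly, and applies T = m(1 + p e^{-qm} + k(s/r - 1)) with a strict
    '>' comparison.
    """
    nrows, ncols = image.shape
    w = window_radius
    ax = np.arange(-w, w + 1)
    foot = (ax[:, None] ** 2 + ax[None, :] ** 2) <= w**2
    out = np.zeros_like(roi_mask, dtype=bool)
    for i in range(nrows):
        for j in range(ncols):
            if not roi_mask[i, j]:
                continue
            lo_r, hi_r = max(i - w, 0), min(i + w + 1, nrows)
            lo_c, hi_c = max(j - w, 0), min(j + w + 1, ncols)
            sub = image[lo_r:hi_r, lo_c:hi_c]
            fsub = foot[lo_r - i + w:hi_r - i + w, lo_c - j + w:hi_c - j + w]
            vals = sub[fsub]
            m = vals.mean()
            s = vals.std()
            threshold = m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))
            out[i, j] = image[i, j] > threshold
    return out


def otsu_oracle(values: np.ndarray, n_levels: int = 256) -> float:
    """Exhaustive between-class-variance maximization over candidate levels."""
    lo, hi = values.min(), values.max()
    candidates = np.linspace(lo, hi, n_levels)
    best_t, best_v = lo, -np.inf
    for t in candidates:
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            continue
        w0, w1 = below.size, above.size
        v = w0 * w1 * (below.mean() - above.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)


def two_sided_t_p_quadrature(t_stat: float, df: int) -> float:
    """Two-sided p by numerical integration of the Student-t density."""
    from scipy.integrate import quad
    from scipy.special import gammaln

    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)

    def density(x: float) -> float:
        return np.exp(logc - (df + 1) / 2 * np.log1p(x * x / df))

    tail, _ = quad(density, abs(t_stat), np.inf)
    return 2.0 * tail


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_slab(
    image: np.ndarray,
    kind: SlabKind = SlabKind.SCP,
    scan_width_mm: float = 3.0,
    fovea: tuple[float, float] | None = None,
) -> EnFaceSlab:
    if fovea is None:
        fovea = ((image.shape[0] - 1) / 2, (image.shape[1] - 1) / 2)
    return EnFaceSlab(image=image, slab_kind=kind, scan_width_mm=scan_width_mm,
                      fovea_center_px=fovea)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def centered_roi_304() -> tuple[EnFaceSlab, CircularROI]:
    """A 304x304 slab of a 3 mm scan with the standard 1.5 mm foveal ROI."""
    img = np.full((304, 304), 0.5)
    slab = make_slab(img, fovea=(151.5, 151.5))
    return slab, make_roi(slab, 1.5)
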