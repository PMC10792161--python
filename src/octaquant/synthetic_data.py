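"""Synthetic inputs with known ground truth for the whole pipeline.

Every generator is a pure function of its spec (seed included): the same
spec yields byte-identical output, and ground-truth quantities are emitted
alongside the images rather than re-estimated.

* :func:`generate_vessel_slab` — procedural branching curvilinear strokes
  emulating an SCP/DCP en-face angiogram, with the exact vessel mask and
  summed centerline length as ground truth.
* :func:`generate_cc_texture` — granular smoothed-noise texture emulating
  a choriocapillaris slab, with darker flow-void regions of a known area
  fraction.
* :func:`generate_reflectance_scene` — ellipsoid-zone plus dark/bright
  reference maps sharing one multiplicative illumination gain field (the
  disturbance the two-point normalization is meant to cancel).
* :func:`generate_cohort` — paired study/fellow eye metric draws with the
  mean/SD structure of a macula-on retinal-detachment cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from octaquant.imaging_io import EnFaceSlab, SlabKind
from octaquant.roi_threshold import BinaryMask

# ---------------------------------------------------------------------------
# Vessel networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselNetworkSpec:
    """Procedural vessel-network slab: branching strokes of varying width.

    ``area_fraction`` is the target foreground fraction of the whole image;
    the generator keeps adding strokes until the rendered mask is within
    ±0.02 of it (and stops stamping mid-stroke once reached, so the
    overshoot is at most one stamp).
    """

    side_px: int = 304
    area_fraction: float = 0.20
    branch_count: int = 14
    width_range_px: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_px < 64:
            raise ValueError("side_px must be >= 64")
        if not 0.0 <= self.area_fraction < 0.6:
            raise ValueError("area_fraction must be in [0, 0.6)")
        lo, hi = self.width_range_px
        if not (1 <= lo <= hi):
            raise ValueError("width_range_px must satisfy 1 <= lo <= hi")


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: int) -> None:
    n = mask.shape[0]
    ri, ci = int(round(r)), int(round(c))
    lo_r, hi_r = max(ri - radius, 0), min(ri + radius + 1, n)
    lo_c, hi_c = max(ci - radius, 0), min(ci + radius + 1, n)
    rr = np.arange(lo_r, hi_r)[:, None]
    cc = np.arange(lo_c, hi_c)[None, :]
    mask[lo_r:hi_r, lo_c:hi_c] |= (rr - ri) ** 2 + (cc - ci) ** 2 <= radius**2


def generate_vessel_slab(
    spec: VesselNetworkSpec,
) -> tuple[EnFaceSlab, BinaryMask, float]:
    """Render a vessel-network slab; return (slab, truth mask, centerline length).

    Strokes are momentum-biased random walks; later strokes branch off
    random points of earlier centerlines. Each stroke stamps disks of a
    fixed per-stroke half-width along its path. Intensity rendering is a
    smooth falloff of the mask (Gaussian blur) modulated by multiplicative
    speckle plus a dim background, clipped to [0, 1].

    Raises
    ------
    ValueError
        If the target area fraction is unreachable with the spec's branch
        and width constraints (iteration cap hit).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.side_px
    mask = np.zeros((n, n), dtype=bool)
    total_px = n * n
    target = spec.area_fraction
    centerline_len = 0.0
    centerline_pts: list[tuple[float, float]] = []

    if target == 0.0:
        slab = EnFaceSlab(
            image=np.clip(0.10 + 0.05 * rng.standard_normal((n, n)), 0.0, 1.0),
            slab_kind=SlabKind.SCP, fovea_center_px=((n - 1) / 2, (n - 1) / 2),
        )
        return slab, BinaryMask(mask, thresholder="ground-truth", params={}), 0.0

    def fraction() -> float:
        return mask.sum() / total_px

    max_strokes = 40 * max(spec.branch_count, 1)
    stroke_i = 0
    while fraction() < target and stroke_i < max_strokes:
        stroke_i += 1
        width = int(rng.integers(spec.width_range_px[0], spec.width_range_px[1] + 1))
        half = max(width // 2, 1)
        if centerline_pts and stroke_i > spec.branch_count // 2:
            # branch: start from a random point on an existing centerline
            r, c = centerline_pts[int(rng.integers(len(centerline_pts)))]
        else:
            r, c = rng.uniform(0, n - 1, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        step = 1.5
        length = int(rng.integers(n // 4, n))
        for _ in range(length):
            theta += rng.normal(0.0, 0.18)  # momentum walk: gentle curvature
            r += step * np.sin(theta)
            c += step * np.cos(theta)
            if not (0 <= r < n and 0 <= c < n):
                break
            _stamp_disk(mask, r, c, half)
            centerline_len += step
            centerline_pts.append((r, c))
            if fraction() >= target:
                break

    if abs(fraction() - target) > 0.02:
        raise ValueError(
            f"target area fraction {target} unreachable: reached "
            f"{fraction():.3f} after {stroke_i} strokes"
        )

    # narrow falloff keeps the rendered boundary close to the true mask;
    # textured background keeps a global threshold from biting into the halo
    body = ndimage.gaussian_filter(mask.astype(float), sigma=0.6)
    speckle = 1.0 + 0.20 * rng.standard_normal((n, n))
    image = np.clip(
        0.10 + 0.05 * rng.standard_normal((n, n)) + 0.80 * body * speckle, 0.0, 1.0
    )
    slab = EnFaceSlab(
        image=image, slab_kind=SlabKind.SCP,
        fovea_center_px=((n - 1) / 2, (n - 1) / 2),
    )
    truth = BinaryMask(mask, thresholder="ground-truth",
                       params={"area_fraction": float(fraction())})
    return slab, truth, centerline_len


# ---------------------------------------------------------------------------
# Choriocapillaris texture
# ---------------------------------------------------------------------------


def generate_cc_texture(
    side_px: int = 304,
    void_fraction: float = 0.3,
    granule_scale_px: float = 2.0,
    seed: int = 0,
    void_contrast: float = 0.9,
    void_scale_px: float = 8.0,
) -> tuple[EnFaceSlab, np.ndarray]:
    """Granular CC-like texture with darker flow voids of known fraction.

    The granular background is Gaussian noise smoothed at
    ``granule_scale_px`` and rescaled to a bright band; flow voids are the
    sub-``void_fraction`` quantile of a second, larger-scale smooth field,
    so the returned boolean void mask covers exactly that fraction of
    pixels (up to quantile ties). ``void_contrast`` in [0, 1] is the
    fractional darkening inside voids; 0 makes voids invisible.

    Returns the slab and the ground-truth void mask.
    """
    if not 0.0 < void_fraction < 0.9:
        raise ValueError("void_fraction must be in (0, 0.9)")
    if granule_scale_px <= 0 or void_scale_px <= 0:
        raise ValueError("granule and void scales must be positive")
    if not 0.0 <= void_contrast <= 1.0:
        raise ValueError("void_contrast must be in [0, 1]")
    rng = np.random.default_rng(seed)
    granules = ndimage.gaussian_filter(
        rng.standard_normal((side_px, side_px)), sigma=granule_scale_px
    )
    g = (granules - granules.mean()) / granules.std()
    texture = np.clip(0.60 + 0.12 * g, 0.0, 1.0)

    void_field = ndimage.gaussian_filter(
        rng.standard_normal((side_px, side_px)), sigma=void_scale_px
    )
    cut = np.quantile(void_field, void_fraction)
    void_mask = void_field < cut

    image = np.clip(texture * (1.0 - void_contrast * void_mask), 0.0, 1.0)
    slab = EnFaceSlab(
        image=image, slab_kind=SlabKind.CC,
        fovea_center_px=((side_px - 1) / 2, (side_px - 1) / 2),
    )
    return slab, void_mask


# ---------------------------------------------------------------------------
# Reflectance scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReflectanceSceneSpec:
    """EZ + dark/bright reference maps sharing one illumination gain field.

    Levels are true (pre-disturbance) reflectances in [0, 1]; the gain
    field is ``1 + amplitude * F`` with F a smooth zero-mean field scaled
    to [-1, 1], applied multiplicatively to all three maps; i.i.d. Gaussian
    noise of ``noise_sd`` is added per map afterwards.
    """

    side_px: int = 256
    ez_level: float = 0.45
    dark_level: float = 0.15
    bright_level: float = 0.75
    gain_amplitude: float = 0.0
    noise_sd: float = 0.0
    # patchy sub-mm disturbance (shadowing/opacities) rather than
    # frame-scale vignetting: its ROI average then tracks the frame
    # average, which is what lets whole-slab reference means cancel it
    gain_scale_px: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bright_level > self.dark_level:
            raise ValueError("bright_level must exceed dark_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.gain_amplitude < 1.0:
            raise ValueError("gain_amplitude must be in [0, 1)")

    @property
    def true_normalized_reflectivity(self) -> float:
        return (self.ez_level - self.dark_level) / (self.bright_level - self.dark_level)


def generate_reflectance_scene(
    spec: ReflectanceSceneSpec,
) -> tuple[EnFaceSlab, EnFaceSlab, EnFaceSlab, float]:
    """Generate (ez, dark_ref, bright_ref, true normalized reflectivity)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.side_px
    if spec.gain_amplitude > 0:
        f = ndimage.gaussian_filter(rng.standard_normal((n, n)),
                                    sigma=spec.gain_scale_px)
        f = f - f.mean()
        f = f / max(np.abs(f).max(), 1e-12)
        gain = 1.0 + spec.gain_amplitude * f
    else:
        gain = np.ones((n, n))

    def render(level: float, kind: SlabKind) -> EnFaceSlab:
        img = level * gain
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal((n, n))
        return EnFaceSlab(
            image=np.clip(img, 0.0, 1.0), slab_kind=kind,
            fovea_center_px=((n - 1) / 2, (n - 1) / 2),
        )

    ez = render(spec.ez_level, SlabKind.EZ)
    dark = render(spec.dark_level, SlabKind.VITREOUS_REF)
    bright = render(spec.bright_level, SlabKind.RNFL_REF)
    return ez, dark, bright, spec.true_normalized_reflectivity


# ---------------------------------------------------------------------------
# Paired-eye cohorts
# ---------------------------------------------------------------------------

#: Default per-metric (study mean, study SD, fellow mean, fellow SD):
#: the published descriptives of a 21-subject macula-on retinal-detachment
#: cohort with the unaffected fellow eye as paired control.
DEFAULT_METRIC_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "scp_pd": (17.26, 3.34, 20.56, 3.62),
    "scp_vld": (2.69, 0.59, 3.36, 0.70),
    "scp_vdi": (6.45, 0.36, 6.16, 0.32),
    "dcp_pd": (15.69, 3.34, 17.12, 3.97),
    "dcp_vld": (2.82, 0.80, 2.93, 0.75),
    "dcp_vdi": (5.67, 0.62, 5.88, 0.33),
    "cc_pd": (50.21, 6.20, 57.43, 6.20),
    "ez_reflectivity": (0.31, 0.09, 0.42, 0.15),
}


@dataclass(frozen=True)
class CohortSpec:
    """Paired-cohort generator spec.

    Per metric, each subject's (study, fellow) pair is one bivariate
    normal draw with the given means/SDs and within-pair correlation
    ``rho`` (default 0.5 — inter-eye correlation is rarely reported, so
    this is a free parameter of the emulation, not an estimate).
    """

    n_subjects: int = 21
    metric_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_PARAMS)
    )
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(
                f"within-pair correlation must be in (-1, 1), got {self.rho} "
                "(implied covariance not positive definite)"
            )
        for name, (_, sd_s, _, sd_f) in self.metric_params.items():
            if sd_s <= 0 or sd_f <= 0:
                raise ValueError(f"metric {name!r}: SDs must be positive")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a paired cohort; one row per eye, metrics as columns."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subjects = [f"S{i:03d}" for i in range(1, n + 1)]
    data: dict[str, np.ndarray] = {}
    for name, (mu_s, sd_s, mu_f, sd_f) in spec.metric_params.items():
        cov = np.array(
            [
                [sd_s**2, spec.rho * sd_s * sd_f],
                [spec.rho * sd_s * sd_f, sd_f**2],
            ]
        )
        draws = rng.multivariate_normal([mu_s, mu_f], cov, size=n,
                                        method="cholesky")
        data[name] = draws
    rows = []
    for i, sid in enumerate(subjects):
        for j, eye in enumerate(("study", "fellow")):
            row: dict[str, object] = {"subject_id": sid, "eye_label": eye}
            for name in spec.metric_params:
                row[name] = float(data[name][i, j])
            rows.append(row)
    return pd.DataFrame(rows)
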