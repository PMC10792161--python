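# Methods

This note records the measurement conventions, the statistical model, the
design of the synthetic-data generators, and the numerical choices that
were genuinely open — in enough detail that every number the package
produces can be traced to a definition.

## Region of interest

All vascular and reflectivity measurements are taken inside a circular
ROI centered on the fovea, default radius 1.5 mm. The fovea center is
always supplied as metadata (in practice it is localized by a human from
infrared or B-scan images; automating that step is out of scope). Pixel
coordinates are 0-based `(row, col)` with pixel-center geometry: a pixel
belongs to the ROI iff the Euclidean distance from its center to the
fovea center is `<= radius_mm / pixel_pitch`, where
`pixel_pitch = scan_width_mm / columns`. Construction fails if the disc
is not fully inside the frame — a partially clipped ROI would silently
bias every density downstream. ROI pixel count is monotone in the radius
by construction.

A `full_frame_roi` helper measures over the whole frame instead; it is
used when validating against generators whose ground-truth fractions are
defined over the entire image.

## Binarization

Intensities are normalized to `[0, 1]` at read time (division by the
bit-depth maximum), so thresholds are device- and bit-depth-independent.

**Global (SCP/DCP).** The threshold is computed from ROI pixels only,
with Otsu's method by default and the plain ROI mean as an alternative;
the choice and the resulting threshold are stored in the mask's
provenance. A constant ROI yields an all-background mask plus a warning
rather than an arbitrary split. The exact thresholding used by the
original ImageJ-based workflows is typically unstated in publications;
Otsu is the de-facto OCTA default and the option is swappable precisely
because it is a convention, not a derivation.

**Local (choriocapillaris).** The CC slab is low-contrast and granular,
so a local threshold is used:

    T = m · (1 + p·exp(−q·m) + k·(s/r − 1))

with `m`, `s` the mean and population (ddof 0) standard deviation over a
*circular* window of radius 15 px (defaults `k = 0.25`, `r = 0.5`,
`p = 2`, `q = 10`, the de-facto standard parameterization; all
overridable). At image borders the window is truncated to in-bounds
pixels, i.e. the statistics are always over the pixels actually present.
The vectorized implementation (three box correlations) is required to
match a per-pixel brute-force reimplementation *bit for bit*, with no
tolerance — that equivalence is asserted in the test suite and re-measured
by the acceptance script.

**Tie rule.** Everywhere, a pixel is foreground iff its intensity is
*strictly* above the threshold; ties are background. One consistent rule
avoids method-dependent edge cases. Outside-ROI pixels are never
foreground.

## Vessel metrics

Masks are thinned with Zhang–Suen 2-D thinning (8-connectivity
throughout). On pixel counts inside the ROI:

    PD  = 100 · |vessel| / |ROI|        (percent)
    VLD = 100 · |skeleton| / |ROI|      (percent)
    VDI = |vessel| / |skeleton|         (dimensionless)

so `PD = VDI · VLD` exactly whenever the skeleton is non-empty; the
implementation asserts this identity to 1e−6. VLD is reported as a
percent of ROI area (the convention in which macular plexus values are a
few percent), not mm/mm². VDI is a pixel-count ratio even though cohort
reports sometimes print a "%" on it; values around 3–7 are only coherent
as a ratio, and the report's "(%)" on VDI rows is retained purely as a
display convention. All metrics are ratios, so the physical pixel pitch
cancels and no mm conversion is performed.

An empty skeleton leaves VDI undefined (`None`), never infinite.
Endpoint erosion is a property of thinning: a filled bar of width `w`
loses up to about `w/2` skeleton pixels at each end, so skeleton length
approximates centerline length only up to that bias (tests bound it
explicitly rather than pretending it is absent).

## Normalized EZ reflectivity

Raw en-face brightness mixes the biology of interest with acquisition
gain, media opacity and illumination. Within one eye, the vitreous is
reliably the darkest structure and the retinal nerve fiber layer among
the brightest, which motivates the two-point normalization

    EZ_norm = (μ_EZ − μ_dark) / (μ_bright − μ_dark).

A shared affine transform `a·I + b` (a > 0) of all three images cancels
algebraically; the implementation verifies invariance to 1e−10 under
random transforms. `EZ_norm` is not clamped to `[0, 1]`: values outside
the unit interval indicate inverted or degenerate references and are
diagnostic. Construction fails outright if `μ_bright ≤ μ_dark`.

Whether the reference means are taken over the whole reference slabs or
restricted to the same foveal ROI differs between published workflows;
both are exposed (`reference_scope="full"` (default) or `"roi"`). With
`"roi"`, a shared multiplicative gain field cancels exactly (all three
means see the same field over the same region); with `"full"`, the
cancellation is approximate and its accuracy depends on how much the
field's ROI average deviates from its frame average.

## Paired statistics

Both eyes of each subject are used, so the data are nested pairs and
each metric is tested with a two-tailed paired Student's t-test on the
within-subject differences `d = study − fellow`:

    t = mean(d) / (sd(d)/√n),   df = n − 1.

Shapiro–Wilk normality of the differences is attached to every
comparison but never gates the t-test — it is advisory, matching common
clinical-reporting practice. Pairs with a missing side are dropped and
counted. Exactly constant differences make `t` undefined: the low-level
test rejects them, while the cohort report falls back to descriptives
with NaN for `t` and `p` plus a warning. No multiple-testing correction
is applied by default (each metric is reported with its raw p, the usual
convention for descriptive paired-eye tables); Holm adjustment is
available behind a flag.

**Power / sample size.** The a-priori calculation uses the exact
noncentral-t formulation: at sample size `n` the two-sided power is
`P(|T′| > t_{1−α/2, n−1})` with `T′` noncentral t, `df = n − 1`,
noncentrality `d·√n`, and `n_required` is the smallest `n ≥ 2` reaching
the target (found by exponential bracketing plus bisection — power is
monotone in `n`). For `d = 0.7`, `α = 0.05`, power 0.80 the exact
minimum is **19**; planning figures in the literature are commonly
rounded up (to 20 for this configuration), so published requirements are
treated as upper bounds on the computed minimum rather than values to
reproduce digit-for-digit. At extreme noncentrality scipy's `nct`
distribution loses accuracy (returns NaN); the implementation then falls
back to direct quadrature of the defining representation
`T′ = (Z + nc)/√(V/df)`. A caution from that exact computation: with
`df = 1` the t distribution's tails are so heavy that even `d = 10`
still needs `n = 3`; the `n = 2` floor is only reached near `d ≈ 15`.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their spec (seed included) —
identical spec, identical bytes — and emit their ground truth alongside
the images rather than re-estimating it.

**Vessel networks.** Momentum-biased random-walk strokes of varying
width, with later strokes branching off earlier centerlines, stamped as
disks into a boolean mask; the generator stops (mid-stroke if necessary)
once the mask's area fraction is within ±0.02 of the target, and rejects
unreachable targets. Rendering is a narrow Gaussian falloff (σ = 0.6 px)
of the mask, multiplicative speckle (SD 0.20), and a textured background
(0.10 ± 0.05): the narrow falloff keeps the rendered boundary close to
the true mask and the background texture keeps a global threshold from
biting into the blur halo, which together let Otsu recover the target
area fraction to well under 1 percentage point. This emulates the
area/length/width geometry a quantification pipeline must recover — not
retinal hemodynamics, projection artifacts, or physiologic branching
statistics.

**Choriocapillaris texture.** Gaussian noise smoothed at a 2 px granule
scale, rescaled to a bright band (0.60 ± 0.12), with flow voids defined
as the lower quantile of a second, larger-scale (8 px) smooth field —
so the void mask covers exactly the requested fraction — darkened by a
contrast factor. It reproduces the granular statistics Phansalkar
thresholding was designed for, not real choriocapillaris flow-void
morphometry.

**Reflectance scenes.** Three constant true reflectance maps (EZ between
a dark and a bright reference) share one multiplicative gain field
`1 + amplitude·F`, `F` smooth, zero-mean, scaled to `[−1, 1]`, plus
optional i.i.d. Gaussian noise per map. The field's default correlation
scale is 8 px (~0.1 mm at 256 px / 3 mm): patchy shadowing/opacity-like
disturbance whose ROI average tracks its frame average, which is the
regime in which whole-slab reference means cancel it to within ~0.02.
Frame-scale vignetting is deliberately *not* the default — under it,
whole-slab references cancel only approximately and the ROI-scope option
should be used instead.

**Cohorts.** Per metric, each subject's (study, fellow) pair is one
bivariate-normal draw with specified means/SDs and within-pair
correlation ρ (default 0.5; inter-eye correlations are rarely published,
so this is a free emulation parameter). The default means/SDs are the
published descriptives of a 21-subject macula-on retinal-detachment
cohort, giving the generator realistic effect sizes: large for SCP, CC
and EZ reflectivity, small for DCP. The generator draws metrics
independently of one another, which real cohorts do not; it supports
calibration checks (type-I error, power), not multivariate structure.

Passing tests on these generators therefore demonstrate that the
*measurement chain* is correct and the *statistics* calibrated — they do
not validate segmentation quality, artifact handling, or device
comparability on real scans.

## Problem sizes

Defaults throughout are chosen to mirror a typical macular protocol:
3 × 3 mm scans at 304 × 304 px, 1.5 mm ROI, 21-subject cohorts. The
calibration simulations use 1,000 replicate cohorts for the type-I-error
check and 100,000 draws for the Monte-Carlo/analytic power comparison;
vessel-recovery checks use 20 generator seeds. These sizes give binomial
or Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

* No retinal layer segmentation, projection-artifact removal, or device
  raw-format support; inputs are exported en-face images plus metadata.
* The global SCP/DCP thresholder is a declared convention (Otsu within
  ROI), not an inference about any particular vendor pipeline.
* VLD in percent of ROI area is one of two conventions in use (the other
  is mm/mm²); values are not convertible without the pixel pitch.
* The vitreous dark reference can be unreliable in post-vitrectomy eyes;
  no special handling is provided.
* Skeleton-based VLD inherits thinning's endpoint and junction biases;
  they are bounded in tests, not removed.
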