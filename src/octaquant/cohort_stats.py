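"""Paired study-eye versus fellow-eye statistics.

Each subject contributes both eyes, so the eyes are nested paired data and
every metric is compared with a paired two-tailed Student's t-test on the
within-subject differences d = study - fellow:

    t = mean(d) / (sd(d) / sqrt(n)),    df = n - 1

Shapiro-Wilk normality of the differences is reported alongside every test
but never gates it (it is advisory). The a-priori sample-size calculation
uses the exact noncentral-t power of the paired test: at sample size n the
power is P(|T'| > t_{1-alpha/2, n-1}) with T' noncentral t, df = n - 1 and
noncentrality d * sqrt(n), where d is Cohen's d on the paired differences.

No multiple-testing correction is applied by default (each metric is
reported with its raw p); Holm adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Metric columns summarized in the report, with display labels.
#: VDI is a dimensionless area/length ratio; the "(%)" on the VDI rows is
#: retained only as a display convention of the report layout.
TABLE_METRICS: list[tuple[str, str]] = [
    ("scp_pd", "SCP perfusion density (%)"),
    ("scp_vld", "SCP vessel length density (%)"),
    ("scp_vdi", "SCP vessel diameter index (%)"),
    ("dcp_pd", "DCP perfusion density (%)"),
    ("dcp_vld", "DCP vessel length density (%)"),
    ("dcp_vdi", "DCP vessel diameter index (%)"),
    ("cc_pd", "CC perfusion density (%)"),
    ("ez_reflectivity", "EZ normalized reflectivity"),
]


@dataclass(frozen=True)
class PairedComparison:
    """One metric's paired comparison: descriptives, normality, t-test."""

    metric: str
    n_pairs: int
    study_mean: float
    study_sd: float
    fellow_mean: float
    fellow_sd: float
    t_statistic: float
    df: int
    p_value: float
    shapiro_p: float
    n_dropped: int = 0


@dataclass(frozen=True)
class PowerSpec:
    """Inputs (and result) of the paired-t sample-size calculation."""

    effect_size: float
    alpha: float = 0.05
    target_power: float = 0.80
    n_required: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.effect_size == 0:
            raise ValueError("effect_size must be non-zero")


def paired_t_test(
    study_values: np.ndarray, fellow_values: np.ndarray, metric: str = ""
) -> PairedComparison:
    """Two-tailed paired Student's t-test of study vs fellow eyes.

    Pairs with a missing value on either side are dropped and counted in
    ``n_dropped``. Differences with zero variance are rejected (the t
    statistic is undefined), as are fewer than 2 complete pairs.
    """
    study = np.asarray(study_values, dtype=float)
    fellow = np.asarray(fellow_values, dtype=float)
    if study.shape != fellow.shape or study.ndim != 1:
        raise ValueError("study and fellow must be equal-length 1-D vectors")
    complete = ~(np.isnan(study) | np.isnan(fellow))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("metric %s: dropped %d incomplete pair(s)", metric or "?", n_dropped)
    study, fellow = study[complete], fellow[complete]
    n = study.size
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    diff = study - fellow
    if np.ptp(diff) == 0 and diff.std(ddof=1) == 0:
        raise ValueError(
            "paired differences have zero variance; the t statistic is "
            f"undefined (all differences equal {diff[0]:g})"
        )
    t_stat, p_value = stats.ttest_rel(study, fellow)
    shapiro_p = float(stats.shapiro(diff).pvalue)
    return PairedComparison(
        metric=metric,
        n_pairs=n,
        study_mean=float(study.mean()),
        study_sd=float(study.std(ddof=1)),
        fellow_mean=float(fellow.mean()),
        fellow_sd=float(fellow.std(ddof=1)),
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p_value),
        shapiro_p=shapiro_p,
        n_dropped=n_dropped,
    )


def analytic_paired_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Exact two-sided power of the paired t-test at sample size n.

    Noncentral-t formulation: reject when |T| exceeds the central-t
    critical value; under the alternative T is noncentral t with
    noncentrality ``effect_size * sqrt(n)``.
    """
    if n < 2:
        return 0.0
    df = n - 1
    nc = abs(effect_size) * np.sqrt(n)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    value = float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
    if not np.isfinite(value):
        # extreme noncentrality overwhelms scipy's nct; integrate the
        # defining representation T' = (Z + nc) / sqrt(V/df), V ~ chi2(df)
        from scipy.integrate import quad

        def integrand(v: float) -> float:
            scaled = crit * np.sqrt(v / df)
            return stats.chi2.pdf(v, df) * (
                stats.norm.sf(scaled - nc) + stats.norm.cdf(-scaled - nc)
            )

        value, _ = quad(integrand, 0.0, np.inf)
    return float(value)


def required_sample_size(spec: PowerSpec, n_max: int = 10**6) -> PowerSpec:
    """Smallest n >= 2 whose exact paired-t power reaches the target.

    Raises
    ------
    ValueError
        If the target power is unreachable with n <= ``n_max``.
    """
    lo, hi = 2, 2
    while analytic_paired_power(hi, spec.effect_size, spec.alpha) < spec.target_power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(
                f"target power {spec.target_power} unreachable with n <= {n_max}"
            )
    # power is monotone non-decreasing in n, so bisect on (lo, hi]
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if analytic_paired_power(mid, spec.effect_size, spec.alpha) >= spec.target_power:
            hi = mid
        else:
            lo = mid
    n_req = hi if analytic_paired_power(hi, spec.effect_size, spec.alpha) >= spec.target_power else None
    if n_req is None:
        raise ValueError("power target unreachable")
    return replace(spec, n_required=max(n_req, 2))


def _holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    order = np.argsort(pvalues)
    m = len(pvalues)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * pvalues[idx])
        adjusted[idx] = min(running_max, 1.0)
    return adjusted


def summarize_cohort(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
    metrics: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-metric paired report over a cohort table of per-eye rows.

    ``cohort`` has one row per eye with ``subject_id``, ``eye_label``
    ("study"/"fellow") and one column per metric. For each metric with at
    least 2 complete pairs the report gives mean ± SD per eye group (2
    decimals), the paired-t p-value (3 decimals), and the raw numbers.
    Metrics absent for all subjects are omitted with a warning.
    """
    if metrics is None:
        metrics = TABLE_METRICS
    for col in ("subject_id", "eye_label"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    wide = cohort.pivot(index="subject_id", columns="eye_label")
    if len(wide) < 2:
        raise ValueError("cohort must contain at least 2 subjects")
    rows = []
    for column, label in metrics:
        if column not in cohort.columns or cohort[column].isna().all():
            logger.warning("metric %s absent for all subjects; omitted", column)
            continue
        study_vals = wide[(column, "study")].to_numpy()
        fellow_vals = wide[(column, "fellow")].to_numpy()
        try:
            cmp_ = paired_t_test(study_vals, fellow_vals, metric=column)
        except ValueError as exc:
            if "zero variance" not in str(exc):
                raise
            # exactly constant differences: descriptives are still well
            # defined, the t statistic is not
            logger.warning("metric %s: %s; reporting descriptives only", column, exc)
            cmp_ = PairedComparison(
                metric=column, n_pairs=len(study_vals),
                study_mean=float(np.mean(study_vals)),
                study_sd=float(np.std(study_vals, ddof=1)),
                fellow_mean=float(np.mean(fellow_vals)),
                fellow_sd=float(np.std(fellow_vals, ddof=1)),
                t_statistic=float("nan"), df=len(study_vals) - 1,
                p_value=float("nan"), shapiro_p=float("nan"),
            )
        rows.append(
            {
                "metric": column,
                "label": label,
                "n_pairs": cmp_.n_pairs,
                "study_mean_sd": f"{cmp_.study_mean:.2f} ± {cmp_.study_sd:.2f}",
                "fellow_mean_sd": f"{cmp_.fellow_mean:.2f} ± {cmp_.fellow_sd:.2f}",
                "p_value": f"{cmp_.p_value:.3f}",
                "study_mean": cmp_.study_mean,
                "study_sd": cmp_.study_sd,
                "fellow_mean": cmp_.fellow_mean,
                "fellow_sd": cmp_.fellow_sd,
                "t_statistic": cmp_.t_statistic,
                "df": cmp_.df,
                "p_raw": cmp_.p_value,
                "shapiro_p": cmp_.shapiro_p,
                "significant": cmp_.p_value <= alpha,
            }
        )
    report = pd.DataFrame(rows)
    if holm and not report.empty:
        adj = _holm_adjust(report["p_raw"].to_numpy())
        report["p_holm"] = adj
        report["significant"] = adj <= alpha
    return report
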