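"""Paired-eye statistics: t-test, power/sample size, cohort report."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octaquant.cohort_stats import (
    PowerSpec,
    analytic_paired_power,
    paired_t_test,
    required_sample_size,
    summarize_cohort,
    TABLE_METRICS,
)
from octaquant.synthetic_data import CohortSpec, generate_cohort

from conftest import two_sided_t_p_quadrature


class TestPairedTTest:
    def test_identical_pairs_rejected_as_zero_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(x, x)

    def test_one_perturbed_pair_is_computable(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x.copy()
        y[0] += 0.5
        cmp_ = paired_t_test(x, y)
        assert np.isfinite(cmp_.t_statistic)
        assert cmp_.df == 3

    def test_symmetric_differences_give_t0_p1(self):
        study = np.array([1.0, 0.0, 1.0, 0.0])
        fellow = np.array([0.0, 1.0, 0.0, 1.0])  # differences 1,-1,1,-1
        cmp_ = paired_t_test(study, fellow)
        assert cmp_.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_hand_computed_t_and_quadrature_p(self):
        fellow = np.zeros(5)
        study = np.array([2.0, 3.0, 1.0, 4.0, 2.0])
        cmp_ = paired_t_test(study, fellow)
        d = study
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert cmp_.t_statistic == pytest.approx(expected_t, rel=1e-12)
        assert cmp_.p_value == pytest.approx(
            two_sided_t_p_quadrature(expected_t, 4), abs=1e-10
        )
        assert cmp_.df == 4
        assert np.sign(cmp_.t_statistic) == np.sign(cmp_.study_mean - cmp_.fellow_mean)

    def test_incomplete_pairs_dropped_and_counted(self):
        study = np.array([1.0, np.nan, 3.0, 4.0, 2.5])
        fellow = np.array([0.5, 2.0, np.nan, 3.0, 2.0])
        cmp_ = paired_t_test(study, fellow)
        assert cmp_.n_pairs == 3
        assert cmp_.n_dropped == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test(np.array([1.0]), np.array([0.0]))

    def test_agrees_with_quadrature_oracle_on_random_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            study = rng.normal(0, 1, n)
            fellow = rng.normal(0, 1, n)
            if np.ptp(study - fellow) == 0:
                continue
            cmp_ = paired_t_test(study, fellow)
            assert cmp_.p_value == pytest.approx(
                two_sided_t_p_quadrature(cmp_.t_statistic, n - 1), abs=1e-8
            )


class TestRequiredSampleSize:
    def test_study_planning_figure_is_an_upper_bound(self):
        spec = required_sample_size(PowerSpec(effect_size=0.7, alpha=0.05,
                                              target_power=0.80))
        assert spec.n_required <= 20
        assert spec.n_required == 19  # exact noncentral-t minimum
        assert analytic_paired_power(spec.n_required, 0.7) >= 0.80
        assert analytic_paired_power(spec.n_required - 1, 0.7) < 0.80

    def test_enormous_effect_floor(self):
        # at df = 1 the t tail is so heavy that d = 10 still needs n = 3
        # (power at n = 2 is ~0.733); d = 15 reaches the n = 2 floor
        assert required_sample_size(PowerSpec(effect_size=10.0)).n_required == 3
        assert required_sample_size(PowerSpec(effect_size=15.0)).n_required == 2

    def test_monte_carlo_power_matches_analytic(self, rng):
        spec = required_sample_size(PowerSpec(effect_size=0.7))
        n = spec.n_required
        n_sim = 100_000
        draws = rng.normal(0.7, 1.0, size=(n_sim, n))
        t = draws.mean(axis=1) / (draws.std(axis=1, ddof=1) / np.sqrt(n))
        from scipy import stats

        crit = stats.t.ppf(0.975, n - 1)
        mc_power = np.mean(np.abs(t) > crit)
        assert abs(mc_power - analytic_paired_power(n, 0.7)) < 0.015

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.power import TTestPower

        for d in (0.3, 0.5, 0.7, 1.2):
            ours = required_sample_size(PowerSpec(effect_size=d)).n_required
            sm_n = TTestPower().solve_power(effect_size=d, alpha=0.05,
                                            power=0.80, alternative="two-sided")
            assert ours == int(np.ceil(sm_n))

    @given(st.floats(min_value=0.2, max_value=2.0),
           st.floats(min_value=0.2, max_value=2.0))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_effect_size(self, d1, d2):
        lo, hi = sorted([d1, d2])
        n_lo = required_sample_size(PowerSpec(effect_size=lo)).n_required
        n_hi = required_sample_size(PowerSpec(effect_size=hi)).n_required
        assert n_hi <= n_lo

    def test_monotone_in_alpha_and_power(self):
        base = required_sample_size(PowerSpec(effect_size=0.5)).n_required
        stricter_alpha = required_sample_size(
            PowerSpec(effect_size=0.5, alpha=0.01)).n_required
        higher_power = required_sample_size(
            PowerSpec(effect_size=0.5, target_power=0.95)).n_required
        assert stricter_alpha >= base
        assert higher_power >= base

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_size=0.0)
        with pytest.raises(ValueError):
            PowerSpec(effect_size=0.5, alpha=1.5)
        with pytest.raises(ValueError):
            required_sample_size(PowerSpec(effect_size=1e-5), n_max=1000)


class TestSummarizeCohort:
    def test_report_schema_matches_published_layout(self):
        table = generate_cohort(CohortSpec(n_subjects=21, seed=11))
        report = summarize_cohort(table)
        assert list(report["metric"]) == [m for m, _ in TABLE_METRICS]
        assert len(report) == 8
        row = report.iloc[0]
        assert "±" in row["study_mean_sd"] and "±" in row["fellow_mean_sd"]
        assert len(row["p_value"].split(".")[-1]) == 3
        assert (report["n_pairs"] == 21).all()

    def test_constant_shift_pairs(self):
        import pandas as pd

        rows = []
        for i, base in enumerate([10.0, 12.0, 11.0]):
            rows.append({"subject_id": f"S{i}", "eye_label": "study",
                         "scp_pd": base})
            rows.append({"subject_id": f"S{i}", "eye_label": "fellow",
                         "scp_pd": base + 2.0})
        report = summarize_cohort(pd.DataFrame(rows),
                                  metrics=[("scp_pd", "SCP PD")])
        row = report.iloc[0]
        assert row["fellow_mean"] - row["study_mean"] == pytest.approx(2.0)

    def test_absent_metric_omitted_with_warning(self, caplog):
        table = generate_cohort(CohortSpec(n_subjects=5, seed=3))
        table = table.drop(columns=["dcp_vdi"])
        import logging

        with caplog.at_level(logging.WARNING):
            report = summarize_cohort(table)
        assert "dcp_vdi" not in list(report["metric"])
        assert len(report) == 7

    def test_type_one_error_near_nominal_under_null(self):
        # null generator: fellow parameters equal study parameters
        null_params = {"scp_pd": (17.26, 3.34, 17.26, 3.34)}
        n_rep = 400
        rejections = 0
        for i in range(n_rep):
            spec = CohortSpec(n_subjects=21, metric_params=null_params,
                              rho=0.5, seed=50_000 + i)
            report = summarize_cohort(generate_cohort(spec))
            rejections += int(report.iloc[0]["p_raw"] <= 0.05)
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08

    def test_holm_adjustment_flag(self):
        table = generate_cohort(CohortSpec(n_subjects=21, seed=7))
        report = summarize_cohort(table, holm=True)
        assert "p_holm" in report.columns
        assert (report["p_holm"] >= report["p_raw"] - 1e-15).all()
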