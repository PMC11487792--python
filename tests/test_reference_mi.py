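"""Unit and property tests for reference-based multiple imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import chisquare

from ccwmi import (
    CAR,
    J2OP_BOTH,
    J2OP_REGIME2,
    CohortConfig,
    draw_parameters,
    fit_imputation_model,
    generate_cohort,
    impute_event_times,
    rubin_pool,
    run_mi,
    run_primary_analysis,
    summarise_hr,
)
from ccwmi.discrete_time_outcome import HazardFit
from ccwmi.reference_mi import J2OP_TERMS, ReferenceGroupError


def manual_fit(params: dict, cov=None, terms=None, n=1000) -> HazardFit:
    s = pd.Series(params, dtype=float)
    terms = terms if terms is not None else tuple(k for k in params if k != "const")
    if cov is None:
        cov = np.zeros((len(s), len(s)))
    return HazardFit(
        params=s,
        cov=pd.DataFrame(np.asarray(cov, dtype=float), index=s.index, columns=s.index),
        n_clone_months=n,
        converged=True,
        terms=terms,
    )


class TestRubinPool:
    def test_worked_example(self):
        # Qbar = 0.20, Wbar = 0.04, B = 0.01, T = 0.04 + (4/3)(0.01)
        pooled = rubin_pool([0.10, 0.20, 0.30], [0.04, 0.04, 0.04])
        assert pooled.pooled_estimate == pytest.approx(0.20)
        assert pooled.within_variance == pytest.approx(0.04)
        assert pooled.between_variance == pytest.approx(0.01)
        assert pooled.total_variance == pytest.approx(0.0533333333, abs=1e-9)

    def test_identical_estimates_zero_between(self):
        pooled = rubin_pool([0.2, 0.2, 0.2, 0.2], [0.05, 0.05, 0.05, 0.05])
        assert pooled.between_variance == 0.0
        assert pooled.total_variance == pooled.within_variance

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            rubin_pool([0.1], [0.01])

    def test_ci_widens_with_between_variance(self):
        widths = []
        for spread in (0.0, 0.05, 0.1, 0.2, 0.4):
            pooled = rubin_pool(
                [0.2 - spread, 0.2, 0.2 + spread], [0.04, 0.04, 0.04], df_complete=500
            )
            widths.append(pooled.ci_high - pooled.ci_low)
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_barnard_rubin_df_bounded_by_complete_data_df(self):
        pooled = rubin_pool([0.1, 0.3], [0.04, 0.04], df_complete=50)
        assert 0 < pooled.df < 50


class TestDrawParameters:
    def test_zero_covariance_returns_point_estimate(self):
        fit = manual_fit({"const": -3.0, "t": 0.01})
        rng = np.random.default_rng(0)
        draw = draw_parameters(fit, rng)
        assert draw.equals(fit.params)

    def test_deterministic_under_fixed_state(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.02]])
        fit = manual_fit({"const": -3.0, "t": 0.01}, cov=cov)
        d1 = draw_parameters(fit, np.random.default_rng(7))
        d2 = draw_parameters(fit, np.random.default_rng(7))
        assert np.array_equal(d1.to_numpy(), d2.to_numpy())

    def test_law_of_large_numbers(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.02]])
        fit = manual_fit({"const": -3.0, "t": 0.01}, cov=cov)
        rng = np.random.default_rng(3)
        draws = np.array([draw_parameters(fit, rng).to_numpy() for _ in range(10_000)])
        se = np.sqrt(np.diag(cov) / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - fit.params.to_numpy()) < 3 * se)

    def test_non_psd_covariance_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        fit = manual_fit({"const": -3.0, "t": 0.01}, cov=cov)
        with pytest.raises(ValueError, match="positive semi-definite"):
            draw_parameters(fit, np.random.default_rng(0))


def ltfu_rows(n, censor_month, arm=2):
    return pd.DataFrame(
        {
            "patient_id": [f"c{i}" for i in range(n)],
            "clone_arm": arm,
            "month": censor_month,
            "cd4": 150.0,
            "rna": 10000.0,
            "on_prophylaxis": True,
            "censored_ltfu": True,
        }
    )


class TestImputeEventTimes:
    def test_zero_reference_hazard_reaches_horizon(self):
        beta = pd.Series({"const": -1e9, "t": 0.0, "t2": 0.0, "t3": 0.0})
        out = impute_event_times(
            ltfu_rows(5, 10), beta, np.random.default_rng(0), terms=J2OP_TERMS
        )
        last = out.groupby("patient_id").tail(1)
        assert (last["month"] == 59).all()
        assert last["admin_end"].all()
        assert not out["event"].any()
        assert out["imputed"].all()

    def test_unit_reference_hazard_event_immediately(self):
        beta = pd.Series({"const": 1e9, "t": 0.0, "t2": 0.0, "t3": 0.0})
        out = impute_event_times(
            ltfu_rows(5, 10), beta, np.random.default_rng(0), terms=J2OP_TERMS
        )
        assert (out.groupby("patient_id").size() == 1).all()
        assert (out["month"] == 11).all()
        assert out["event"].all()

    def test_horizon_boundary_clone_untouched(self):
        beta = pd.Series({"const": 1e9, "t": 0.0, "t2": 0.0, "t3": 0.0})
        out = impute_event_times(
            ltfu_rows(2, 59), beta, np.random.default_rng(0), terms=J2OP_TERMS
        )
        assert len(out) == 0

    def test_geometric_distribution_of_imputed_event_month(self):
        # constant reference hazard p: event month - (c+1) follows the
        # geometric law truncated at the horizon (chi-square GOF oracle)
        p, c, n = 0.05, 9, 10_000
        beta = pd.Series({"const": float(logit(p)), "t": 0.0, "t2": 0.0, "t3": 0.0})
        out = impute_event_times(
            ltfu_rows(n, c), beta, np.random.default_rng(11), terms=J2OP_TERMS
        )
        last = out.groupby("patient_id").tail(1)
        k = (last.loc[last["event"], "month"] - (c + 1)).to_numpy()  # 0-based waiting time
        n_slots = 59 - c  # months c+1 .. 59
        observed, expected = [], []
        for j in range(n_slots):
            observed.append(int((k == j).sum()))
            expected.append(n * (1 - p) ** j * p)
        observed.append(int(last["admin_end"].sum()))  # survived to horizon
        expected.append(n * (1 - p) ** n_slots)
        stat, pval = chisquare(observed, expected)
        assert pval > 0.001


class TestFitImputationModel:
    def test_empty_reference_group_rejected(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        always_on = res.weighted.assign(on_prophylaxis=True)
        with pytest.raises(ReferenceGroupError, match="empty reference"):
            fit_imputation_model(always_on, J2OP_BOTH)

    def test_zero_event_reference_rejected(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        no_events = res.weighted.assign(event=False)
        with pytest.raises(ReferenceGroupError, match="no events"):
            fit_imputation_model(no_events, J2OP_BOTH)

    def test_constant_hazard_intercept_recovery(self, mixed_cohort):
        # intercept-only reference model is the Bernoulli MLE of the
        # off-prophylaxis event rate
        res = run_primary_analysis(mixed_cohort)
        fit = fit_imputation_model(res.weighted, J2OP_BOTH, terms=())
        off = res.weighted[~res.weighted["on_prophylaxis"].astype(bool)]
        off = off.drop_duplicates(subset=["patient_id", "month"])
        rate = off["event"].mean()
        assert fit.params["const"] == pytest.approx(float(logit(rate)), abs=1e-6)

    def test_j2op_drops_arm_terms(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        fit = fit_imputation_model(res.weighted, J2OP_BOTH)
        assert "arm" not in fit.params.index

    def test_car_keeps_arm_terms(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        fit = fit_imputation_model(res.weighted, CAR)
        assert "arm" in fit.params.index


class TestRunMI:
    def test_no_ltfu_identity(self, no_ltfu_cohort):
        # zero LTFU clones: every scenario's MIResult equals the primary
        # analysis exactly
        res = run_primary_analysis(no_ltfu_cohort)
        primary = summarise_hr(res.fit)
        for scenario in (CAR, J2OP_BOTH, J2OP_REGIME2):
            mi = run_mi(res, scenario, m=5, seed=1)
            assert mi.hr == pytest.approx(primary.hr, abs=1e-12)
            assert mi.ci_low == pytest.approx(primary.ci_low, abs=1e-12)
            assert mi.ci_high == pytest.approx(primary.ci_high, abs=1e-12)
            assert mi.p_value == pytest.approx(primary.p_value, abs=1e-12)
            assert mi.between_variance == 0.0
            assert mi.n_imputed_clones == 0

    def test_deterministic_for_fixed_seed(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        a = run_mi(res, J2OP_BOTH, m=3, seed=9)
        b = run_mi(res, J2OP_BOTH, m=3, seed=9)
        assert a.per_imputation == b.per_imputation
        assert a.hr == b.hr

    def test_asymmetric_scenario_imputes_arm2_only(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        clones = res.clone_months
        ltfu2 = int(
            (clones["censored_ltfu"] & (clones["clone_arm"] == 2) & (clones["month"] < 59)).sum()
        )
        mi = run_mi(res, J2OP_REGIME2, m=2, seed=3)
        assert mi.n_imputed_clones == ltfu2
        # and arm-1 LTFU clones exist but are untouched
        assert (clones["censored_ltfu"] & (clones["clone_arm"] == 1)).any()

    def test_m_below_two_rejected(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        with pytest.raises(ValueError, match="m must be"):
            run_mi(res, CAR, m=1, seed=0)

    def test_total_variance_at_least_within(self, mixed_cohort):
        res = run_primary_analysis(mixed_cohort)
        mi = run_mi(res, J2OP_BOTH, m=4, seed=2)
        assert mi.total_variance >= mi.within_variance
        assert mi.between_variance >= 0
        assert mi.m == 4
        assert len(mi.per_imputation) == 4
        assert mi.ci_low <= mi.hr <= mi.ci_high
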