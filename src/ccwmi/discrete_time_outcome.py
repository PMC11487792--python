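"""Weighted discrete-time hazard model for the composite endpoint.

Pools clone-months into a single logistic regression of the monthly event
probability on a cubic baseline-time trend, the regime indicator and a
time-by-regime interaction, weighted by inverse-probability-of-censoring
weights, and summarises the regime contrast as a hazard ratio with either
model-based or patient-level-bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .trial_emulation import HORIZON

#: Default model: logit h(t) = b0 + b1 t + b2 t^2 + b3 t^3 + theta arm2 + gamma t*arm2
DEFAULT_TERMS = ("t", "t2", "t3", "arm", "t:arm")


class FitError(RuntimeError):
    """A model fit failed or would be silently degenerate."""


def build_design(df: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix (with intercept) for the term vocabulary.

    Recognised terms: ``t``/``t2``/``t3`` (month polynomials), ``arm``
    (indicator of clone_arm == 2), ``t:arm`` (interaction), ``rna_supp``
    (indicator of rna < 400); any other term is taken verbatim as a column
    of ``df``.
    """
    t = df["month"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for term in terms:
        if term == "t":
            cols[term] = t
        elif term == "t2":
            cols[term] = t**2
        elif term == "t3":
            cols[term] = t**3
        elif term == "arm":
            cols[term] = (df["clone_arm"].to_numpy() == 2).astype(float)
        elif term == "t:arm":
            cols[term] = t * (df["clone_arm"].to_numpy() == 2).astype(float)
        elif term == "rna_supp":
            cols[term] = (df["rna"].to_numpy(dtype=float) < 400.0).astype(float)
        elif term in df.columns:
            cols[term] = df[term].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown design term {term!r}")
    return pd.DataFrame(cols, index=df.index)


@dataclass
class HazardFit:
    """Fitted pooled logistic discrete-time hazard model."""

    params: pd.Series
    cov: pd.DataFrame
    n_clone_months: int
    converged: bool
    terms: tuple[str, ...]

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = build_design(df, self.terms)
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()

    def hazard(self, df: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(df))


@dataclass
class HREstimate:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    bootstrap_reps: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def fit_pooled_logistic(
    clone_months: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    weight_col: str = "weight",
) -> HazardFit:
    """Weighted MLE of the pooled logistic hazard model.

    Rows flagged ``censored_ice`` are excluded (they are not on-regime
    person-time).  Degenerate inputs — all events, no events, all-zero
    weights, or a single arm when an arm term is requested — are refused.
    """
    df = clone_months
    if "censored_ice" in df.columns:
        df = df[~df["censored_ice"].astype(bool)]
    if len(df) == 0:
        raise FitError("no usable clone-months")
    y = df["event"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise FitError("degenerate fit: no events in input")
    if y.sum() == len(y):
        raise FitError("degenerate fit: every clone-month is an event")
    if weight_col in df.columns:
        w = df[weight_col].to_numpy(dtype=float)
    else:
        w = np.ones(len(df))
    if (w < 0).any():
        raise FitError("negative weights")
    if w.sum() == 0:
        raise FitError("all weights zero")
    if any(term in ("arm", "t:arm") for term in terms):
        if df["clone_arm"].nunique() < 2:
            raise FitError("single-arm input but an arm term was requested")

    X = build_design(df, terms)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=300, tol=1e-10)
    params = pd.Series(res.params, index=X.columns)
    if not np.all(np.isfinite(params.to_numpy())):
        raise FitError("non-finite coefficients (separation or non-convergence)")
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    return HazardFit(
        params=params,
        cov=cov,
        n_clone_months=len(df),
        converged=bool(res.converged),
        terms=tuple(terms),
    )


def _arm_contrast(
    fit: HazardFit, method: str, person_time: np.ndarray | None, horizon: int
) -> tuple[float, float]:
    """(log-HR, variance) of the regime contrast under the chosen summary."""
    if "arm" not in fit.params.index:
        raise ValueError("fit has no regime term")
    if method not in ("main-effect", "time-averaged"):
        raise ValueError(f"unknown HR summary method {method!r}")
    theta = float(fit.params["arm"])
    v_theta = float(fit.cov.loc["arm", "arm"])
    if method == "main-effect" or "t:arm" not in fit.params.index:
        return theta, v_theta
    if person_time is None:
        person_time = np.ones(horizon)
    person_time = np.asarray(person_time, dtype=float)
    tbar = float(np.average(np.arange(len(person_time)), weights=person_time))
    gamma = float(fit.params["t:arm"])
    v_gamma = float(fit.cov.loc["t:arm", "t:arm"])
    c = float(fit.cov.loc["arm", "t:arm"])
    return theta + gamma * tbar, v_theta + tbar**2 * v_gamma + 2 * tbar * c


def summarise_hr(
    fit: HazardFit,
    method: str = "main-effect",
    person_time: np.ndarray | None = None,
    alpha: float = 0.05,
) -> HREstimate:
    """Collapse the fitted regime contrast to one hazard ratio.

    ``main-effect`` exponentiates the regime coefficient; ``time-averaged``
    exponentiates the person-time-weighted mean of theta + gamma*t over the
    follow-up months (uniform person-time over the horizon by default).
    Wald CI and two-sided p from the model covariance.
    """
    if not fit.converged:
        raise FitError("cannot summarise a non-converged fit")
    est, var = _arm_contrast(fit, method, person_time, HORIZON)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else (1.0 if est == 0 else 0.0)
    return HREstimate(
        hr=float(np.exp(est)),
        ci_low=float(np.exp(est - z * se)),
        ci_high=float(np.exp(est + z * se)),
        p_value=float(p),
        method=method,
    )


def bootstrap_ci(
    cohort: pd.DataFrame,
    pipeline_options,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    max_failure_fraction: float = 0.2,
) -> HREstimate:
    """Patient-level bootstrap CI for the pipeline hazard ratio.

    Patients (not clone-months) are resampled with replacement — the two
    clones of one person are not independent — and the full clone/weight/fit
    pipeline is re-run per replicate.  Returns the full-data point estimate
    with the percentile CI and a normal-approximation p-value on the log
    scale.  Deterministic for a fixed seed.
    """
    from .primary import run_primary_analysis  # deferred: avoids import cycle

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    ids = cohort["patient_id"].unique()
    if len(ids) < 2:
        raise FitError("bootstrap requires at least two patients")

    full = run_primary_analysis(cohort, pipeline_options)
    point = np.log(full.hr.hr)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grouped = dict(tuple(cohort.groupby("patient_id", sort=False)))
    log_hrs: list[float] = []
    failures = 0
    for _ in range(n_reps):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        pieces = []
        for k, pid in enumerate(chosen):
            g = grouped[pid].copy()
            g["patient_id"] = f"b{k:06d}"  # duplicates are distinct pseudo-patients
            pieces.append(g)
        resampled = pd.concat(pieces, ignore_index=True)
        try:
            rep = run_primary_analysis(resampled, pipeline_options)
            log_hrs.append(np.log(rep.hr.hr))
        except (FitError, ValueError):
            failures += 1
    if failures > max_failure_fraction * n_reps:
        raise FitError(f"bootstrap aborted: {failures}/{n_reps} replicate fits failed")

    log_hrs_arr = np.asarray(log_hrs)
    lo, hi = np.percentile(log_hrs_arr, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    se = float(np.std(log_hrs_arr, ddof=1))
    p = 2 * stats.norm.sf(abs(point) / se) if se > 0 else (1.0 if point == 0 else 0.0)
    return HREstimate(
        hr=float(np.exp(point)),
        ci_low=float(np.exp(min(lo, point))),
        ci_high=float(np.exp(max(hi, point))),
        p_value=float(p),
        method=full.hr.method,
        bootstrap_reps=len(log_hrs),
    )


def survival_curves(fit: HazardFit, horizon: int = HORIZON) -> pd.DataFrame:
    """Per-arm survival S(t) = prod_{s<t} (1 - h(s)) at reference covariates.

    Returns one row per (arm, t) for t = 0..horizon; covariates other than
    time and arm are held at zero.
    """
    if not fit.converged:
        raise FitError("cannot predict from a non-converged fit")
    frames = []
    for arm in (1, 2):
        ref = pd.DataFrame({"month": np.arange(horizon), "clone_arm": arm})
        for term in fit.terms:
            if term == "rna_supp":
                ref["rna"] = np.inf  # reference level: unsuppressed indicator 0
            elif term not in ("t", "t2", "t3", "arm", "t:arm") and term not in ref.columns:
                ref[term] = 0.0
        h = fit.hazard(ref)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - h)])
        frames.append(pd.DataFrame({"clone_arm": arm, "month": np.arange(horizon + 1), "survival": surv}))
    return pd.concat(frames, ignore_index=True)
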