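"""Reference-based multiple imputation for clones lost to follow-up.

The primary analysis treats loss to follow-up as censoring at random.  To
probe informative censoring, post-LTFU event histories are multiply imputed
from the fitted discrete-time hazard of a clinically meaningful reference
group and the per-imputation hazard-ratio estimates are pooled by Rubin's
rules with Barnard–Rubin degrees of freedom.

Scenarios
---------
``CAR``
    Cross-check: impute from each clone's own arm's on-regime hazard
    (the primary-analysis model).
``J2OP_BOTH``
    "Jump to off prophylaxis": LTFU clones on both arms adopt the hazard of
    patients who stopped prophylaxis.
``J2OP_REGIME2``
    Asymmetric post-hoc variant: only regime-2 clones jump; regime-1
    clone-months are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import discrete_time_outcome
from .discrete_time_outcome import FitError, HazardFit, build_design, fit_pooled_logistic
from .primary import PrimaryResult
from .trial_emulation import HORIZON

#: Imputation-model terms when the reference hazard is off-prophylaxis
#: behaviour pooled over arms (arm terms dropped).
J2OP_TERMS = ("t", "t2", "t3")


class ReferenceGroupError(ValueError):
    """The scenario's reference group is empty or has no events."""


@dataclass(frozen=True)
class Scenario:
    name: str  # CAR | J2OP_BOTH | J2OP_REGIME2
    reference_group: str  # "own-arm-on-regime" | "stopped-prophylaxis"
    arms_imputed: tuple[int, ...]


CAR = Scenario("CAR", "own-arm-on-regime", (1, 2))
J2OP_BOTH = Scenario("J2OP_BOTH", "stopped-prophylaxis", (1, 2))
J2OP_REGIME2 = Scenario("J2OP_REGIME2", "stopped-prophylaxis", (2,))

SCENARIOS = {"car": CAR, "j2op": J2OP_BOTH, "j2op-arm2": J2OP_REGIME2}


@dataclass
class RubinPooled:
    """Rubin's-rules combination of per-imputation estimates."""

    m: int
    pooled_estimate: float  # Qbar
    within_variance: float  # Wbar
    between_variance: float  # B
    total_variance: float  # T = Wbar + (1 + 1/m) B
    df: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class MIResult:
    scenario: str
    m: int
    per_imputation: list[tuple[float, float]]  # (log-HR Q_j, variance U_j)
    pooled_estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_imputed_clones: int


def rubin_pool(
    estimates,
    variances,
    df_complete: float | None = None,
    alpha: float = 0.05,
) -> RubinPooled:
    """Pool m >= 2 per-imputation (estimate, variance) pairs.

    T = Wbar + (1 + 1/m) B; degrees of freedom follow Barnard–Rubin when a
    complete-data df is supplied, otherwise the classic large-sample rule.
    With B = 0 the t-interval degenerates to the normal interval.
    """
    q = np.asarray(list(estimates), dtype=float)
    u = np.asarray(list(variances), dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = q.shape[0]
    if m < 2:
        raise ValueError("rubin_pool requires m >= 2 imputations")
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = wbar + (1.0 + 1.0 / m) * b

    if b > 0:
        r = (1.0 + 1.0 / m) * b
        df_old = (m - 1) * (1.0 + wbar / r) ** 2
        if df_complete is not None and np.isfinite(df_complete):
            lam = r / t_var
            df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    else:
        df = float(df_complete) if df_complete is not None else np.inf

    se = float(np.sqrt(t_var))
    if np.isfinite(df):
        crit = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else (1.0 if qbar == 0 else 0.0)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(qbar) / se) if se > 0 else (1.0 if qbar == 0 else 0.0)
    return RubinPooled(
        m=m,
        pooled_estimate=qbar,
        within_variance=wbar,
        between_variance=b,
        total_variance=t_var,
        df=float(df),
        ci_low=qbar - crit * se,
        ci_high=qbar + crit * se,
        p_value=float(p),
    )


def fit_imputation_model(
    clone_months: pd.DataFrame,
    scenario: Scenario,
    outcome_terms: tuple[str, ...] = discrete_time_outcome.DEFAULT_TERMS,
    pool_arms: bool = True,
    terms: tuple[str, ...] | None = None,
) -> HazardFit:
    """Fit the reference-group hazard model the imputations draw from.

    CAR: the primary-analysis model (arm terms retained, IPC weights used)
    over all on-regime clone-months.  Jump-to-off-prophylaxis: the same
    formula family with arm terms dropped, fitted unweighted to the
    off-prophylaxis patient-months of eligible patients (de-duplicated
    across clones; per-arm fitting available via ``pool_arms=False``).
    """
    df = clone_months[~clone_months["censored_ice"].astype(bool)]
    if scenario.reference_group == "own-arm-on-regime":
        ref = df
        terms = terms if terms is not None else outcome_terms
    else:
        ref = df[~df["on_prophylaxis"].astype(bool)]
        if pool_arms:
            ref = ref.drop_duplicates(subset=["patient_id", "month"])
            default = J2OP_TERMS
        else:
            default = J2OP_TERMS + ("arm", "t:arm")
        terms = terms if terms is not None else default
        ref = ref.drop(columns=["weight"], errors="ignore")  # reference fit is unweighted
    if len(ref) == 0:
        raise ReferenceGroupError(
            f"scenario {scenario.name}: empty reference group ({scenario.reference_group})"
        )
    if ref["event"].astype(bool).sum() == 0:
        raise ReferenceGroupError(
            f"scenario {scenario.name}: reference group contains no events"
        )
    return fit_pooled_logistic(ref, terms=terms)


def draw_parameters(fit: HazardFit, rng: np.random.Generator) -> pd.Series:
    """One draw from the MVN approximation to the coefficient distribution."""
    cov = fit.cov.to_numpy()
    mean = fit.params.to_numpy()
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValueError("covariance matrix is not positive semi-definite")
    if np.allclose(cov, 0.0):
        return fit.params.copy()
    draw = rng.multivariate_normal(mean, cov, method="svd")
    return pd.Series(draw, index=fit.params.index)


def impute_event_times(
    ltfu_clones: pd.DataFrame,
    parameter_draw: pd.Series,
    rng: np.random.Generator,
    terms: tuple[str, ...],
    horizon: int = HORIZON,
    off_prophylaxis: bool = True,
) -> pd.DataFrame:
    """Complete post-LTFU follow-up for each clone in ``ltfu_clones``.

    ``ltfu_clones`` holds one row per LTFU clone: its terminal (censoring)
    month ``c < horizon`` with last-observed covariates.  For months
    c+1..horizon-1 a Bernoulli event indicator is drawn with probability
    expit of the drawn reference model's linear predictor; follow-up ends at
    the first imputed event or the administrative horizon.  Covariates
    unavailable post LTFU are carried forward; imputed rows are flagged.
    """
    pieces = []
    beta = parameter_draw
    for row in ltfu_clones.itertuples(index=False):
        c = int(row.month)
        if c >= horizon - 1:
            continue  # censored at the horizon boundary: nothing to impute
        ts = np.arange(c + 1, horizon)
        block = pd.DataFrame(
            {
                "patient_id": row.patient_id,
                "clone_arm": row.clone_arm,
                "month": ts,
                "cd4": float(row.cd4),  # last observation carried forward
                "rna": float(row.rna),
                "on_prophylaxis": (not off_prophylaxis) and bool(row.on_prophylaxis),
            }
        )
        X = build_design(block.assign(on_prophylaxis=block["on_prophylaxis"].astype(float)), terms)
        p = expit(X.to_numpy() @ beta.reindex(X.columns).to_numpy())
        u = rng.random(len(ts))
        hits = np.flatnonzero(u < p)
        end = int(hits[0]) if hits.size else len(ts) - 1
        block = block.iloc[: end + 1].copy()
        n = len(block)
        block["event"] = False
        block["event_pcp"] = False
        block["event_death"] = False
        block["censored_ice"] = False
        block["censored_ltfu"] = False
        block["admin_end"] = False
        if hits.size:
            block.loc[block.index[-1], ["event", "event_pcp"]] = True
        else:
            block.loc[block.index[-1], "admin_end"] = True
        block["imputed"] = True
        block["weight"] = 1.0
        pieces.append(block)
    if not pieces:
        return pd.DataFrame()
    return pd.concat(pieces, ignore_index=True)


def _ltfu_terminal_rows(clone_months: pd.DataFrame, arms: tuple[int, ...]) -> pd.DataFrame:
    rows = clone_months[clone_months["censored_ltfu"].astype(bool)]
    return rows[rows["clone_arm"].isin(arms)]


def _mi_from_single_fit(scenario: Scenario, m: int, fit: HazardFit, method: str) -> MIResult:
    """Degenerate MI (no missing data): every imputation equals the primary fit."""
    est, var = discrete_time_outcome._arm_contrast(fit, method, None, HORIZON)
    pooled = RubinPooled(
        m=m,
        pooled_estimate=est,
        within_variance=var,
        between_variance=0.0,
        total_variance=var,
        df=np.inf,
        ci_low=est - stats.norm.ppf(0.975) * np.sqrt(var),
        ci_high=est + stats.norm.ppf(0.975) * np.sqrt(var),
        p_value=float(2 * stats.norm.sf(abs(est) / np.sqrt(var))),
    )
    return _assemble(scenario, [(est, var)] * m, pooled, 0)


def _assemble(scenario: Scenario, per_imp, pooled: RubinPooled, n_imputed: int) -> MIResult:
    return MIResult(
        scenario=scenario.name,
        m=pooled.m,
        per_imputation=list(per_imp),
        pooled_estimate=pooled.pooled_estimate,
        within_variance=pooled.within_variance,
        between_variance=pooled.between_variance,
        total_variance=pooled.total_variance,
        df=pooled.df,
        hr=float(np.exp(pooled.pooled_estimate)),
        ci_low=float(np.exp(pooled.ci_low)),
        ci_high=float(np.exp(pooled.ci_high)),
        p_value=pooled.p_value,
        n_imputed_clones=n_imputed,
    )


def run_mi(
    primary: PrimaryResult,
    scenario: Scenario,
    m: int = 25,
    seed: int = 0,
    hr_method: str | None = None,
    max_failure_fraction: float = 0.2,
) -> MIResult:
    """Multiply impute LTFU clones under ``scenario`` and pool by Rubin's rules.

    Each imputation draws reference-model coefficients from their MVN
    sampling distribution, completes post-LTFU follow-up for the scenario's
    designated clones (imputed months carry weight 1 — IPC weights are only
    defined over observed follow-up), re-fits the weighted outcome model on
    the completed data, and records the log-HR and its variance.  With zero
    LTFU clones imputation is a no-op and the result equals the primary
    analysis exactly.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    method = hr_method or primary.options.hr_method
    ltfu = _ltfu_terminal_rows(primary.clone_months, scenario.arms_imputed)
    ltfu = ltfu[ltfu["month"] < HORIZON - 1]
    if len(ltfu) == 0:
        return _mi_from_single_fit(scenario, m, primary.fit, method)

    imp_fit = fit_imputation_model(
        primary.weighted, scenario, outcome_terms=primary.options.outcome_terms
    )
    off = scenario.reference_group == "stopped-prophylaxis"

    estimates: list[float] = []
    variances: list[float] = []
    failures = 0
    children = np.random.SeedSequence(seed).spawn(m)
    for j in range(m):
        rng = np.random.default_rng(children[j])
        beta = draw_parameters(imp_fit, rng)
        imputed = impute_event_times(
            ltfu, beta, rng, terms=imp_fit.terms, off_prophylaxis=off
        )
        completed = pd.concat([primary.weighted, imputed], ignore_index=True)
        try:
            fit_j = fit_pooled_logistic(completed, terms=primary.options.outcome_terms)
            est_j, var_j = discrete_time_outcome._arm_contrast(fit_j, method, None, HORIZON)
            estimates.append(est_j)
            variances.append(var_j)
        except FitError:
            failures += 1
    if failures > max_failure_fraction * m:
        raise FitError(f"MI aborted: {failures}/{m} imputation fits failed")
    df_complete = primary.fit.n_clone_months - len(primary.fit.params)
    pooled = rubin_pool(estimates, variances, df_complete=df_complete)
    return _assemble(scenario, list(zip(estimates, variances)), pooled, len(ltfu))
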