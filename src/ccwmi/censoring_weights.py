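"""Stabilized inverse-probability-of-censoring weights for the ICE.

Artificial censoring of clones at first non-compliance with their assigned
regime induces selection on the very covariates the regimes condition on.
Per arm, a pooled logistic model of remaining uncensored given current
covariates (denominator) and a baseline-time-only model (numerator) give
stabilized per-patient-month weights as cumulative numerator/denominator
ratios, optionally truncated at a percentile cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .discrete_time_outcome import build_design

#: Denominator covariates: the variables the regimes condition on, plus the
#: cubic baseline-time trend.  Numerator: baseline time only.
DEFAULT_DENOMINATOR_COVARIATES = ("cd4", "rna_supp", "on_prophylaxis")
TIME_TERMS = ("t", "t2", "t3")

POSITIVITY_FLOOR = 1e-6


class WeightFitError(RuntimeError):
    """Censoring-model fitting failed for an arm."""


class PositivityError(RuntimeError):
    """A denominator probability fell below the positivity floor."""


@dataclass
class CensoringFit:
    """Fitted per-arm censoring models (or the trivial no-censoring case)."""

    arm: int
    denominator_terms: tuple[str, ...]
    numerator_terms: tuple[str, ...]
    denominator: object | None  # statsmodels results; None when nothing is censored
    numerator: object | None
    n_censored: int

    def _predict(self, res, terms: tuple[str, ...], df: pd.DataFrame) -> np.ndarray:
        if res is None:
            return np.ones(len(df))
        X = build_design(self._prepare(df), terms)
        return np.asarray(res.predict(X))

    @staticmethod
    def _prepare(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        if "on_prophylaxis" in out.columns:
            out["on_prophylaxis"] = out["on_prophylaxis"].astype(float)
        return out

    def p_uncensored_denominator(self, df: pd.DataFrame) -> np.ndarray:
        return self._predict(self.denominator, self.denominator_terms, df)

    def p_uncensored_numerator(self, df: pd.DataFrame) -> np.ndarray:
        return self._predict(self.numerator, self.numerator_terms, df)


def _fit_uncensored_model(df: pd.DataFrame, terms: tuple[str, ...], arm: int):
    y = 1.0 - df["censored_ice"].to_numpy(dtype=float)
    X = build_design(CensoringFit._prepare(df), terms)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise WeightFitError(f"arm {arm}: censoring model failed for terms {terms}: {exc}") from exc
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise WeightFitError(f"arm {arm}: non-finite censoring-model coefficients for terms {terms}")
    return res


def fit_censoring_model(
    clone_months: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_DENOMINATOR_COVARIATES,
    arm: int = 1,
) -> CensoringFit:
    """Fit the per-arm probability-of-remaining-uncensored models.

    All of the arm's retained clone-months enter, with outcome 1 unless the
    row is the arm's ICE-censoring month.  When the arm has no ICE censoring
    at all the fit is the trivial identity (probability 1 everywhere).
    """
    df = clone_months[clone_months["clone_arm"] == arm]
    if len(df) == 0:
        raise WeightFitError(f"arm {arm}: no clone-months")
    den_terms = tuple(covariates) + TIME_TERMS
    num_terms = TIME_TERMS
    n_censored = int(df["censored_ice"].astype(bool).sum())
    if n_censored == 0:
        return CensoringFit(arm, den_terms, num_terms, None, None, 0)
    den = _fit_uncensored_model(df, den_terms, arm)
    num = _fit_uncensored_model(df, num_terms, arm)
    return CensoringFit(arm, den_terms, num_terms, den, num, n_censored)


def compute_stabilized_weights(
    fits: dict[int, CensoringFit],
    clone_months: pd.DataFrame,
    truncation_percentile: float | None = 99.0,
    positivity_floor: float = POSITIVITY_FLOOR,
    stabilize: bool = True,
) -> pd.DataFrame:
    """Join stabilized IPC weights onto the uncensored clone-months.

    weight(t) = prod_{s<=t} num(s)/den(s) per clone (numerator 1 when
    ``stabilize`` is off).  Rows censored at the ICE are dropped — they are
    not on-regime person-time.  Weights above the truncation percentile are
    capped and flagged.
    """
    out = clone_months[~clone_months["censored_ice"].astype(bool)].copy()
    out = out.sort_values(["clone_arm", "patient_id", "month"], kind="stable")
    p_den = np.ones(len(out))
    p_num = np.ones(len(out))
    for arm, fit in fits.items():
        mask = (out["clone_arm"] == arm).to_numpy()
        if not mask.any():
            continue
        sub = out[mask]
        d = fit.p_uncensored_denominator(sub)
        if (d < positivity_floor).any():
            worst = float(d.min())
            raise PositivityError(
                f"arm {arm}: denominator probability {worst:.3g} below positivity floor "
                f"{positivity_floor:g}"
            )
        p_den[mask] = d
        p_num[mask] = fit.p_uncensored_numerator(sub) if stabilize else 1.0
    out["p_uncensored_denominator"] = p_den
    out["p_uncensored_numerator"] = p_num
    ratio = out["p_uncensored_numerator"] / out["p_uncensored_denominator"]
    out["weight"] = ratio.groupby(
        [out["clone_arm"], out["patient_id"]], sort=False
    ).cumprod()
    out["truncated"] = False
    if truncation_percentile is not None:
        cap = float(np.percentile(out["weight"].to_numpy(), truncation_percentile))
        over = out["weight"] > cap
        out.loc[over, "weight"] = cap
        out.loc[over, "truncated"] = True
    return out.sort_index()


def weight_summary(weighted: pd.DataFrame) -> pd.DataFrame:
    """Min/percentile/max of the weights per month (run-log aid)."""
    def q(s, p):
        return float(np.percentile(s, p))

    rows = []
    for month, grp in weighted.groupby("month"):
        w = grp["weight"].to_numpy()
        rows.append(
            {
                "month": month,
                "n": len(w),
                "min": float(w.min()),
                "p1": q(w, 1),
                "p50": q(w, 50),
                "mean": float(w.mean()),
                "p99": q(w, 99),
                "max": float(w.max()),
            }
        )
    return pd.DataFrame(rows)
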