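"""Synthetic longitudinal cohort generator with known ground truth.

Generates one record per patient per month (CD4, HIV-RNA, prophylaxis,
cART, event and loss-to-follow-up indicators) following configurable
per-month stochastic rules, so that every downstream stage of the
clone-censor-weight pipeline can be tested against a known regime effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .trial_emulation import COHORT_COLUMNS, REGIME_1, REGIME_2, required_prophylaxis

#: RNA level emitted while unsuppressed / once suppressed (copies/ml).
#: Values sit safely on either side of the 400 copies/ml regime threshold.
UNSUPPRESSED_RNA = 10000.0
SUPPRESSED_RNA = 50.0

#: Prophylaxis behaviour codes carried in the optional ``behaviour`` column.
BEHAVIOUR_RANDOM_STOP = 0
BEHAVIOUR_REGIME_1 = 1
BEHAVIOUR_REGIME_2 = 2


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the per-month stochastic data-generating process.

    The composite PcP-or-death event fires each month with probability
    ``expit(log_hazard_intercept + log_hr_off_prophylaxis * off_proph
    + log_hr_regime * regime2_behaviour)``; LTFU fires with probability
    ``ltfu_monthly_probability`` on the logit scale inflated by
    ``ltfu_informative_log_or`` for off-prophylaxis months (0 keeps the
    censoring mechanism independent of the event process: CAR by
    construction).
    """

    n_patients: int
    max_months: int = 60
    baseline_cd4_mean: float = 120.0  # places mass below the 200 cells/uL threshold
    baseline_cd4_sd: float = 60.0
    cd4_recovery_rate: float = 15.0  # mean monthly CD4 increase on cART
    cd4_noise_sd: float = 20.0
    rna_suppression_probability: float = 0.15  # per-month chance of crossing below 400
    log_hazard_intercept: float = -6.0
    log_hr_off_prophylaxis: float = 0.0
    log_hr_regime: float = 0.0
    ltfu_monthly_probability: float = 0.0
    ltfu_informative_log_or: float = 0.0  # 0 = CAR
    behaviour_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)  # regime1, regime2, random
    random_stop_probability: float = 0.05  # monthly stop chance for random stoppers
    pcp_fraction: float = 0.5  # composite events recorded as PcP rather than death
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.max_months < 1:
            raise ValueError("max_months must be >= 1")
        for name in (
            "rna_suppression_probability",
            "ltfu_monthly_probability",
            "random_stop_probability",
            "pcp_fraction",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        w = np.asarray(self.behaviour_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("behaviour_weights must be 3 non-negative numbers summing to 1")
        if self.baseline_cd4_sd < 0 or self.cd4_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # per-patient substream: stable under changes to n_patients
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _simulate_patient(config: CohortConfig, index: int) -> dict:
    rng = _patient_rng(config.seed, index)
    m = config.max_months

    # fixed draw order keeps trajectories byte-identical across runs
    u_behaviour = rng.random()
    cd4_0 = max(5.0, rng.normal(config.baseline_cd4_mean, config.baseline_cd4_sd))
    cd4_steps = config.cd4_recovery_rate + rng.normal(0.0, config.cd4_noise_sd, size=m - 1)
    u_supp = rng.random(m)
    u_stop = rng.random(m)
    u_event = rng.random(m)
    u_type = rng.random(m)
    u_ltfu = rng.random(m)

    w1, w2, _ = config.behaviour_weights
    if u_behaviour < w1:
        behaviour = BEHAVIOUR_REGIME_1
    elif u_behaviour < w1 + w2:
        behaviour = BEHAVIOUR_REGIME_2
    else:
        behaviour = BEHAVIOUR_RANDOM_STOP

    cd4 = np.maximum(5.0, np.concatenate([[cd4_0], cd4_0 + np.cumsum(cd4_steps)]))

    # viral load: unsuppressed at entry, suppresses from month >= 1 with the
    # configured monthly probability and stays suppressed
    supp_hits = np.flatnonzero(u_supp[1:] < config.rna_suppression_probability)
    suppressed_from = int(supp_hits[0]) + 1 if supp_hits.size else m
    rna = np.where(np.arange(m) >= suppressed_from, SUPPRESSED_RNA, UNSUPPRESSED_RNA)

    if behaviour == BEHAVIOUR_REGIME_1:
        on_proph = required_prophylaxis(cd4, REGIME_1)
    elif behaviour == BEHAVIOUR_REGIME_2:
        on_proph = required_prophylaxis(rna, REGIME_2)
    else:
        stop_hits = np.flatnonzero(u_stop[1:] < config.random_stop_probability)
        stop_from = int(stop_hits[0]) + 1 if stop_hits.size else m
        on_proph = np.arange(m) < stop_from

    off = (~on_proph).astype(float)
    p_event = expit(
        config.log_hazard_intercept
        + config.log_hr_off_prophylaxis * off
        + config.log_hr_regime * float(behaviour == BEHAVIOUR_REGIME_2)
    )
    p_l = config.ltfu_monthly_probability
    if 0.0 < p_l < 1.0:
        p_ltfu = expit(logit(p_l) + config.ltfu_informative_log_or * off)
    else:
        p_ltfu = np.full(m, p_l)

    event_pcp = np.zeros(m, dtype=bool)
    event_death = np.zeros(m, dtype=bool)
    ltfu_after = np.zeros(m, dtype=bool)
    n_rows = m
    for t in range(m):
        if u_event[t] < p_event[t]:
            if u_type[t] < config.pcp_fraction:
                event_pcp[t] = True
            else:
                event_death[t] = True
            n_rows = t + 1
            break
        if u_ltfu[t] < (p_ltfu[t] if np.ndim(p_ltfu) else p_ltfu):
            ltfu_after[t] = True
            n_rows = t + 1
            break

    return {
        "patient_id": f"p{index:06d}",
        "n_rows": n_rows,
        "cd4": cd4,
        "rna": rna,
        "on_prophylaxis": on_proph,
        "event_pcp": event_pcp,
        "event_death": event_death,
        "ltfu_after": ltfu_after,
        "behaviour": behaviour,
    }


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the long-format cohort table.

    One row per patient-month with the :data:`~ccwmi.trial_emulation.COHORT_COLUMNS`
    schema plus a ``behaviour`` column recording which stopping behaviour the
    patient follows (ground-truth metadata; downstream stages ignore it).
    Reproducible: identical config (including seed) gives identical output,
    and per-patient substreams make patient ``i`` invariant to ``n_patients``.
    """
    config.validate()
    cols: dict[str, list] = {c: [] for c in COHORT_COLUMNS + ("behaviour",)}
    for i in range(config.n_patients):
        sim = _simulate_patient(config, i)
        n = sim["n_rows"]
        cols["patient_id"].append(np.repeat(sim["patient_id"], n))
        cols["month"].append(np.arange(n, dtype=np.int64))
        cols["cd4"].append(np.round(sim["cd4"][:n], 1))
        cols["rna"].append(sim["rna"][:n].astype(float))
        cols["on_prophylaxis"].append(sim["on_prophylaxis"][:n])
        cols["on_cart"].append(np.ones(n, dtype=bool))
        cols["event_pcp"].append(sim["event_pcp"][:n])
        cols["event_death"].append(sim["event_death"][:n])
        cols["ltfu_after"].append(sim["ltfu_after"][:n])
        cols["behaviour"].append(np.full(n, sim["behaviour"], dtype=np.int64))
    if not cols["month"]:
        return pd.DataFrame(columns=list(COHORT_COLUMNS) + ["behaviour"])
    return pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})


def true_marginal_hr(config: CohortConfig) -> float:
    """Ground-truth regime-2 vs regime-1 hazard ratio, ``exp(log_hr_regime)``."""
    config.validate()
    return float(np.exp(config.log_hr_regime))


def as_person_months(cohort: pd.DataFrame) -> pd.DataFrame:
    """RCT-style person-period view for calibration checks.

    Treats each patient's behaviour group (regime 1 vs regime 2 follower) as
    a directly randomised arm: one row per patient-month with ``clone_arm``
    set to the behaviour code and ``event`` the composite indicator.  Only
    meaningful for cohorts whose behaviour mix contains no random stoppers.
    """
    if "behaviour" not in cohort.columns:
        raise ValueError("cohort lacks the behaviour ground-truth column")
    sub = cohort[cohort["behaviour"].isin([BEHAVIOUR_REGIME_1, BEHAVIOUR_REGIME_2])].copy()
    sub["clone_arm"] = sub["behaviour"].astype(int)
    sub["event"] = sub["event_pcp"].astype(bool) | sub["event_death"].astype(bool)
    sub["weight"] = 1.0
    return sub


_BOOL_COLUMNS = ("on_prophylaxis", "on_cart", "event_pcp", "event_death", "ltfu_after")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as comma-separated text with a header row."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort` (or any table with the
    same delimited-text schema)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    for col in _BOOL_COLUMNS:
        if df[col].dtype != bool:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            )
            if df[col].isna().any():
                raise ValueError(f"column {col} contains non-boolean values")
            df[col] = df[col].astype(bool)
    return df
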