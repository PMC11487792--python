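"""Clone-censor trial emulation.

Screens eligibility, defines time 0, duplicates each eligible patient into
both prophylaxis-stopping regimes, evaluates per-month compliance with the
assigned regime, and emits the censored clone-month table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Maximum follow-up per clone, in months (5-year study window).
HORIZON = 60

#: Core input schema for a longitudinal cohort (one row per patient-month).
COHORT_COLUMNS = (
    "patient_id",
    "month",
    "cd4",
    "rna",
    "on_prophylaxis",
    "on_cart",
    "event_pcp",
    "event_death",
    "ltfu_after",
)

#: Schema of the clone-month table emitted by :func:`clone_and_follow`.
CLONE_COLUMNS = (
    "patient_id",
    "clone_arm",
    "month",
    "event",
    "censored_ice",
    "censored_ltfu",
    "admin_end",
    "on_prophylaxis",
    "cd4",
    "rna",
    "event_pcp",
    "event_death",
)


@dataclass(frozen=True)
class RegimeSpec:
    """A deterministic prophylaxis-stopping strategy.

    Prophylaxis is required until ``confirmation`` consecutive monthly
    records of the driving lab marker qualify (``direction`` side of
    ``threshold``); from the confirming record onward prophylaxis must be
    stopped.  If ``restart_on_rebound`` the requirement reactivates as soon
    as the marker rebounds to the non-qualifying side of the threshold, and
    a fresh confirmation run is needed to stop again.
    """

    regime_id: int
    lab: str  # cohort column driving the stopping rule ("cd4" or "rna")
    threshold: float
    confirmation: int  # consecutive qualifying records before stopping fires
    direction: str  # "above": qualify when lab > threshold; "below": lab < threshold
    restart_on_rebound: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if self.confirmation < 1:
            raise ValueError("confirmation must be >= 1")

    def qualifies(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == "above":
            return values > self.threshold
        return values < self.threshold

    def rebounds(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == "above":
            return values < self.threshold
        return values > self.threshold


#: Current guideline: stop once CD4 has been above 200 cells/uL for more
#: than 3 consecutive monthly records (first satisfied at the 4th record).
REGIME_1 = RegimeSpec(regime_id=1, lab="cd4", threshold=200.0, confirmation=4, direction="above")

#: New strategy: stop once viral suppression is confirmed by two
#: consecutive HIV-RNA measurements below 400 copies/ml.
REGIME_2 = RegimeSpec(regime_id=2, lab="rna", threshold=400.0, confirmation=2, direction="below")

DEFAULT_REGIMES = (REGIME_1, REGIME_2)


def required_prophylaxis(values: Iterable[float], regime: RegimeSpec) -> np.ndarray:
    """Per-month required prophylaxis state implied by a lab trajectory.

    Returns a boolean array: True where the regime requires the patient to
    be on prophylaxis at that month, False where it requires them off.
    """
    values = np.asarray(list(values), dtype=float)
    qual = regime.qualifies(values)
    reb = regime.rebounds(values)
    required = np.ones(values.shape[0], dtype=bool)
    run = 0
    stopped = False
    for t in range(values.shape[0]):
        qualifies, rebound = qual[t], reb[t]
        if stopped and rebound and regime.restart_on_rebound:
            stopped = False
            run = 0
        if not stopped:
            run = run + 1 if qualifies else 0
            if run >= regime.confirmation:
                stopped = True
        required[t] = not stopped
    return required


def first_noncompliant_month(
    on_prophylaxis: Iterable[bool],
    required: Iterable[bool],
    grace: int = 1,
) -> int | None:
    """First month at which observed behaviour constitutes the ICE.

    Stopping prophylaxis while it is still required is immediately
    non-compliant.  Failing to stop once stopping is required is tolerated
    for ``grace`` consecutive months before the ICE fires.
    """
    on_prophylaxis = np.asarray(list(on_prophylaxis), dtype=bool)
    required = np.asarray(list(required), dtype=bool)
    if on_prophylaxis.shape != required.shape:
        raise ValueError("on_prophylaxis and required must have equal length")
    run = 0
    for t in range(required.shape[0]):
        if on_prophylaxis[t] == required[t]:
            run = 0
            continue
        if required[t] and not on_prophylaxis[t]:
            return t
        run += 1
        if run > grace:
            return t
    return None


@dataclass(frozen=True)
class ComplianceStatus:
    required_on: bool
    compliant: bool
    first_noncompliant_month: int | None


def compliance_status(history: pd.DataFrame, regime: RegimeSpec, grace: int = 1) -> ComplianceStatus:
    """Evaluate a clone's compliance with ``regime`` over months 0..t.

    ``history`` holds one row per month (0-based, consecutive) with the
    regime's lab column and ``on_prophylaxis``.  The returned status refers
    to the final month of the history.
    """
    if len(history) == 0:
        raise ValueError("history must be non-empty")
    required = required_prophylaxis(history[regime.lab].to_numpy(), regime)
    ice = first_noncompliant_month(history["on_prophylaxis"].to_numpy(), required, grace=grace)
    last = len(history) - 1
    return ComplianceStatus(
        required_on=bool(required[last]),
        compliant=ice is None or ice > last,
        first_noncompliant_month=ice,
    )


@dataclass(frozen=True)
class EligibilityCriteria:
    """Configurable screening criteria; the calendar criteria of the source
    design are represented by the ``on_cart`` flag in the cohort schema."""

    require_cart: bool = True
    require_prophylaxis: bool = True
    max_cd4: float | None = None  # optionally require CD4 below this at entry


def _patient_segments(visits: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(patient ids, segment starts, segment stops) for a validated table."""
    pid = visits["patient_id"].to_numpy()
    new = np.ones(len(pid), dtype=bool)
    new[1:] = pid[1:] != pid[:-1]
    starts = np.flatnonzero(new)
    stops = np.append(starts[1:], len(pid))
    return pid[starts], starts, stops


def validate_visits(visits: pd.DataFrame) -> None:
    """Raise ValueError on schema, ordering or duplication problems."""
    missing = [c for c in COHORT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if len(visits) == 0:
        return
    pid = visits["patient_id"].to_numpy()
    month = visits["month"].to_numpy(dtype=np.int64)
    new = np.ones(len(pid), dtype=bool)
    new[1:] = pid[1:] != pid[:-1]
    if (month[new] != 0).any():
        raise ValueError("months must be consecutive integers per patient starting at 0")
    cont = ~new
    cont[0] = False
    if (month[cont] != month[np.flatnonzero(cont) - 1] + 1).any():
        raise ValueError(
            "months must be consecutive integers per patient starting at 0 "
            "(unsorted or duplicated (patient, month) records)"
        )
    seg_pids = pid[new]
    if len(pd.unique(seg_pids)) != len(seg_pids):
        raise ValueError("duplicate or non-contiguous patient_id blocks")


def screen_eligibility(
    visits: pd.DataFrame,
    criteria: EligibilityCriteria = EligibilityCriteria(),
) -> dict:
    """Map each eligible patient to their time-0 month.

    Time 0 is the first month at which every configured criterion holds
    simultaneously; patients never meeting all criteria are absent.
    """
    validate_visits(visits)
    time0: dict = {}
    if len(visits) == 0:
        return time0
    ok = np.ones(len(visits), dtype=bool)
    if criteria.require_cart:
        ok &= visits["on_cart"].to_numpy(dtype=bool)
    if criteria.require_prophylaxis:
        ok &= visits["on_prophylaxis"].to_numpy(dtype=bool)
    if criteria.max_cd4 is not None:
        ok &= visits["cd4"].to_numpy(dtype=float) < criteria.max_cd4
    month = visits["month"].to_numpy(dtype=np.int64)
    pids, starts, stops = _patient_segments(visits)
    for pid, s, e in zip(pids, starts, stops):
        hits = np.flatnonzero(ok[s:e])
        if hits.size:
            time0[pid] = int(month[s + hits[0]])
    return time0


def _clone_end(
    window: dict,
    regime: RegimeSpec,
    grace: int,
    horizon: int,
) -> tuple[int, str]:
    """Terminal month (re-indexed) and reason for one clone."""
    n = min(window["n"], horizon)
    required = required_prophylaxis(window[regime.lab][:n], regime)
    t_ice = first_noncompliant_month(window["on_prophylaxis"][:n], required, grace=grace)

    ev = window["event_pcp"][:n] | window["event_death"][:n]
    ev_hits = np.flatnonzero(ev)
    ltfu_hits = np.flatnonzero(window["ltfu_after"][:n])

    candidates = [(n - 1, "admin_end")]
    if ltfu_hits.size:
        candidates.append((int(ltfu_hits[0]), "censored_ltfu"))
    if ev_hits.size:
        candidates.append((int(ev_hits[0]), "event"))
    if t_ice is not None:
        candidates.append((t_ice, "censored_ice"))
    # at equal months: censoring at the ICE precedes the event (the
    # discordant month is no longer on-regime person-time); the event
    # precedes LTFU and administrative end.
    priority = {"censored_ice": 0, "event": 1, "censored_ltfu": 2, "admin_end": 3}
    return min(candidates, key=lambda c: (c[0], priority[c[1]]))


def clone_and_follow(
    visits: pd.DataFrame,
    time0_map: Mapping,
    regimes: tuple[RegimeSpec, RegimeSpec] = DEFAULT_REGIMES,
    grace: int = 1,
    horizon: int = HORIZON,
) -> pd.DataFrame:
    """Duplicate each eligible patient into both regimes and censor.

    Each clone's follow-up runs from time 0 (re-indexed to month 0) until
    the earliest of the composite event, LTFU, the first non-compliance
    with the assigned regime, or month ``horizon - 1``.
    """
    validate_visits(visits)
    cols: dict[str, list] = {c: [] for c in CLONE_COLUMNS}
    if len(visits) and time0_map:
        arrays = {
            "cd4": visits["cd4"].to_numpy(dtype=float),
            "rna": visits["rna"].to_numpy(dtype=float),
            "on_prophylaxis": visits["on_prophylaxis"].to_numpy(dtype=bool),
            "event_pcp": visits["event_pcp"].to_numpy(dtype=bool),
            "event_death": visits["event_death"].to_numpy(dtype=bool),
            "ltfu_after": visits["ltfu_after"].to_numpy(dtype=bool),
        }
        pids, starts, stops = _patient_segments(visits)
        bounds = {pid: (int(s), int(e)) for pid, s, e in zip(pids, starts, stops)}
        for pid in sorted(time0_map, key=str):
            t0 = time0_map[pid]
            if pid not in bounds or t0 >= bounds[pid][1] - bounds[pid][0]:
                raise ValueError(f"patient {pid!r} has no visit record at time0={t0}")
            s, e = bounds[pid]
            window = {"n": e - s - t0}
            for name, arr in arrays.items():
                window[name] = arr[s + t0 : e]
            for regime in regimes:
                t_end, reason = _clone_end(window, regime, grace, horizon)
                m = t_end + 1
                terminal = np.zeros(m, dtype=bool)
                terminal[-1] = True
                is_event = reason == "event"
                cols["patient_id"].append(np.repeat(pid, m))
                cols["clone_arm"].append(np.full(m, regime.regime_id, dtype=np.int64))
                cols["month"].append(np.arange(m, dtype=np.int64))
                cols["event"].append(terminal if is_event else np.zeros(m, dtype=bool))
                cols["censored_ice"].append(
                    terminal if reason == "censored_ice" else np.zeros(m, dtype=bool)
                )
                cols["censored_ltfu"].append(
                    terminal if reason == "censored_ltfu" else np.zeros(m, dtype=bool)
                )
                cols["admin_end"].append(
                    terminal if reason == "admin_end" else np.zeros(m, dtype=bool)
                )
                cols["on_prophylaxis"].append(window["on_prophylaxis"][:m])
                cols["cd4"].append(window["cd4"][:m])
                cols["rna"].append(window["rna"][:m])
                # event indicators inside retained follow-up only count when
                # the clone actually terminates with the event
                cols["event_pcp"].append(
                    window["event_pcp"][:m] if is_event else np.zeros(m, dtype=bool)
                )
                cols["event_death"].append(
                    window["event_death"][:m] if is_event else np.zeros(m, dtype=bool)
                )
    if not cols["month"]:
        return pd.DataFrame(columns=list(CLONE_COLUMNS))
    return pd.DataFrame({c: np.concatenate(cols[c]) for c in CLONE_COLUMNS})


def swap_regimes(regimes: tuple[RegimeSpec, RegimeSpec]) -> tuple[RegimeSpec, RegimeSpec]:
    """Exchange arm labels (regime 2 becomes the reference arm 1)."""
    a, b = regimes
    return (replace(b, regime_id=1), replace(a, regime_id=2))
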