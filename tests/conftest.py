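"""Shared fixtures: hand-scripted cohorts and simulated test cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ccwmi import CohortConfig, generate_cohort


def make_visits(patients: dict) -> pd.DataFrame:
    """Build a cohort table from {patient_id: {column: per-month list}}.

    Columns not given default to: cd4 150, rna 10000, on_prophylaxis True,
    on_cart True, all indicators False.  Length is taken from the longest
    provided column (or ``n_months``).
    """
    rows = []
    for pid, spec in patients.items():
        n = spec.get("n_months")
        if n is None:
            n = max(len(v) for k, v in spec.items() if isinstance(v, (list, tuple)))
        defaults = {
            "cd4": 150.0,
            "rna": 10000.0,
            "on_prophylaxis": True,
            "on_cart": True,
            "event_pcp": False,
            "event_death": False,
            "ltfu_after": False,
        }
        for t in range(n):
            row = {"patient_id": pid, "month": t}
            for col, dflt in defaults.items():
                v = spec.get(col, dflt)
                row[col] = v[t] if isinstance(v, (list, tuple)) else v
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def mixed_cohort() -> pd.DataFrame:
    """Simulated cohort with ICE censoring, LTFU and events in both arms."""
    cfg = CohortConfig(
        n_patients=800,
        seed=11,
        log_hazard_intercept=-5.0,
        log_hr_off_prophylaxis=0.6,
        log_hr_regime=-0.4,
        ltfu_monthly_probability=0.01,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def no_ltfu_cohort() -> pd.DataFrame:
    """Simulated cohort with events and ICE censoring but zero LTFU."""
    cfg = CohortConfig(
        n_patients=600,
        seed=7,
        log_hazard_intercept=-5.0,
        log_hr_off_prophylaxis=0.5,
        log_hr_regime=-0.3,
        ltfu_monthly_probability=0.0,
    )
    return generate_cohort(cfg)
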