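"""Run orchestration and Table-style reporting.

Chains simulate → emulate → weight → fit → impute → pool into one
reproducible run with a config echo, a line-oriented log, a descriptive
block (per-arm counts, percentages and chi-square p-values) and one results
row per analysis (primary IPW, CAR-MI, jump-to-off-prophylaxis variants).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_chisquare

from . import __version__
from .censoring_weights import weight_summary
from .discrete_time_outcome import bootstrap_ci
from .primary import PipelineOptions, PrimaryResult, run_primary_analysis
from .reference_mi import SCENARIOS, MIResult, run_mi
from .synthetic_cohort import CohortConfig, generate_cohort, read_cohort

ANALYSIS_LABELS = {
    "primary": "Primary analysis: HR under CAR (IPW)",
    "car": "Supplementary analysis: HR under CAR (IPW and MI for LTFU)",
    "j2op": 'Sensitivity analysis 1: HR under "jump to off prophylaxis" (IPW and MI)',
    "j2op-arm2": 'Sensitivity analysis 2: HR under "jump to off prophylaxis", regime-2 LTFU only (IPW and MI)',
}


def percent(count: int, n: int) -> float:
    """Percentage count/n*100 rounded to one decimal (as printed in reports)."""
    if n == 0:
        return float("nan")
    return round(100.0 * count / n, 1)


def two_proportion_chisq(count1: int, n1: int, count2: int, n2: int) -> float:
    """Two-sided p-value of the two-proportion chi-square test.

    No continuity correction (declared default for determinism of the
    one-decimal rounded report values).
    """
    if count1 == count2 and n1 == n2:
        return 1.0
    _, p, _ = proportions_chisquare(
        count=np.array([count1, count2]), nobs=np.array([n1, n2])
    )
    return float(p)


def format_p(p: float, decimals: int = 3) -> str:
    threshold = 10.0**-decimals
    if p < threshold:
        return f"< {threshold:.{decimals}f}"
    return f"{p:.{decimals}f}"


def descriptive_table(clone_months: pd.DataFrame) -> pd.DataFrame:
    """Per-arm baseline counts and follow-up outcome proportions.

    One row each for baseline N, PcP diagnoses, deaths and LTFU, with
    count, percentage of baseline N (one decimal) and the two-proportion
    chi-square p-value comparing the arms (one decimal).
    """
    out_rows = []
    baseline = clone_months[clone_months["month"] == 0]
    n = {arm: int((baseline["clone_arm"] == arm).sum()) for arm in (1, 2)}
    out_rows.append(
        {
            "row": "Total patients",
            "arm1_count": n[1],
            "arm1_pct": np.nan,
            "arm2_count": n[2],
            "arm2_pct": np.nan,
            "p_value": np.nan,
        }
    )
    terminal = {
        "Event: PcP diagnosis": "event_pcp",
        "Event: Died": "event_death",
        "Lost to follow-up (LTFU)": "censored_ltfu",
    }
    for label, col in terminal.items():
        c = {
            arm: int(
                clone_months[(clone_months["clone_arm"] == arm)][col].astype(bool).sum()
            )
            for arm in (1, 2)
        }
        p = (
            round(two_proportion_chisq(c[1], n[1], c[2], n[2]), 1)
            if n[1] and n[2]
            else np.nan
        )
        out_rows.append(
            {
                "row": label,
                "arm1_count": c[1],
                "arm1_pct": percent(c[1], n[1]),
                "arm2_count": c[2],
                "arm2_pct": percent(c[2], n[2]),
                "p_value": p,
            }
        )
    return pd.DataFrame(out_rows)


@dataclass(frozen=True)
class RunConfig:
    """Complete, reproducible description of one pipeline run."""

    cohort: CohortConfig | str  # config to simulate from, or path to a cohort file
    options: PipelineOptions = field(default_factory=PipelineOptions)
    scenarios: tuple[str, ...] = ("car", "j2op", "j2op-arm2")
    m: int = 25
    bootstrap_reps: int = 0
    seed: int = 0
    out_dir: str | None = None


@dataclass
class RunResult:
    primary: PrimaryResult
    mi_results: dict[str, MIResult]
    results_table: pd.DataFrame
    descriptive: pd.DataFrame
    log_lines: list[str]


def _stamp(lines: list[str], msg: str) -> None:
    lines.append(f"{_dt.datetime.now().isoformat(timespec='seconds')} | {msg}")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all configured stages and assemble the report tables.

    Two runs with identical config produce identical tables; a run record
    (config echo, seed, package version) always goes to the log.
    """
    log: list[str] = []
    _stamp(log, f"ccwmi {__version__} run start (seed={config.seed})")
    log.append(f"config: {config!r}")

    if isinstance(config.cohort, CohortConfig):
        _stamp(log, f"stage simulate: n_patients={config.cohort.n_patients}")
        cohort = generate_cohort(config.cohort)
    else:
        _stamp(log, f"stage load: {config.cohort}")
        cohort = read_cohort(config.cohort)

    _stamp(log, "stage emulate+weight+fit (primary analysis)")
    try:
        primary = run_primary_analysis(cohort, config.options)
    except Exception as exc:
        _stamp(log, f"stage primary FAILED: {exc}")
        raise
    _stamp(log, f"eligible patients: {len(primary.time0)}; clone-months: {len(primary.clone_months)}")
    log.append("weight summary per month:\n" + weight_summary(primary.weighted).to_string(index=False))

    if config.bootstrap_reps >= 2:
        _stamp(log, f"stage bootstrap: {config.bootstrap_reps} replicates")
        hr_primary = bootstrap_ci(cohort, config.options, config.bootstrap_reps, config.seed)
    else:
        hr_primary = primary.hr

    rows = [
        {
            "analysis": ANALYSIS_LABELS["primary"],
            "hr": hr_primary.hr,
            "ci_low": hr_primary.ci_low,
            "ci_high": hr_primary.ci_high,
            "p_value": hr_primary.p_value,
            "p_formatted": format_p(hr_primary.p_value),
        }
    ]
    mi_results: dict[str, MIResult] = {}
    for token in config.scenarios:
        scenario = SCENARIOS[token]
        _stamp(log, f"stage MI: scenario={scenario.name}, m={config.m}")
        try:
            res = run_mi(primary, scenario, m=config.m, seed=config.seed + 1)
        except Exception as exc:
            _stamp(log, f"stage MI ({scenario.name}) FAILED: {exc}")
            raise
        mi_results[token] = res
        rows.append(
            {
                "analysis": ANALYSIS_LABELS[token],
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "p_formatted": format_p(res.p_value),
            }
        )
    results = pd.DataFrame(rows)
    descriptive = descriptive_table(primary.clone_months)
    _stamp(log, "run complete")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        descriptive.to_csv(out / "descriptive.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return RunResult(
        primary=primary,
        mi_results=mi_results,
        results_table=results,
        descriptive=descriptive,
        log_lines=log,
    )
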