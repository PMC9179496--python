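"""Survival analysis of simulated cohorts and the experiment-preset catalog.

Replicates are summarised as right-censored time-to-progression records
(times reported in days = steps/24). Kaplan-Meier curves use the product-limit
estimator; two-arm comparisons use Cox proportional-hazards regression with a
single arm indicator, Efron tie handling and Wald 95% intervals (heavy ties
are expected because the effective time resolution of progression is coarse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .cells import CellType
from .engine import RunResult, SimulationConfig


@dataclass
class KMCurve:
    """Product-limit estimate for one arm: survival after each event time."""

    times: np.ndarray  # distinct observed event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk at each event time


@dataclass
class HazardRatioEstimate:
    """Cox comparison of one arm against a reference arm."""

    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    reference: str
    comparison: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hr <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


def kaplan_meier(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier curve for one arm (columns ``time_days``, ``event``)."""
    if len(records) == 0:
        raise ValueError("need at least one survival record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], records["event"])
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    survival = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in times]
    )
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    return KMCurve(times=times, survival=survival, at_risk=at_risk)


def cox_hazard_ratio(records: pd.DataFrame, reference: str) -> HazardRatioEstimate:
    """Two-arm Cox proportional-hazards fit with ``reference`` as baseline.

    Efron tie handling and a Wald 95% interval (the lifelines defaults, which
    are the fixed contract here).
    """
    arms = sorted(records["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly two arms, got {arms}")
    if reference not in arms:
        raise ValueError(f"reference arm {reference!r} not present in {arms}")
    if int(records["event"].sum()) == 0:
        raise ValueError("no events in either arm; hazard ratio is not estimable")
    comparison = next(a for a in arms if a != reference)
    df = pd.DataFrame(
        {
            "time_days": records["time_days"].astype(float),
            "event": records["event"].astype(bool),
            "treated": (records["arm"] == comparison).astype(float),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_days", event_col="event")
    row = cph.summary.loc["treated"]

    def _exp(x: float) -> float:
        try:
            return float(math.exp(x))
        except OverflowError:
            return float("inf")

    return HazardRatioEstimate(
        hr=_exp(row["coef"]),
        ci_low=_exp(row["coef lower 95%"]),
        ci_high=_exp(row["coef upper 95%"]),
        p_value=float(row["p"]),
        reference=reference,
        comparison=comparison,
    )


def drug_usage_fraction(
    arm_results: list[RunResult], st_results: list[RunResult]
) -> tuple[float, float]:
    """Mean cumulative administered dose per drug, relative to the reference
    cohort, accounted over the full simulated horizon."""
    if not arm_results or not st_results:
        raise ValueError("both cohorts must be non-empty")
    fracs = []
    for attr in ("cumulative_dose1", "cumulative_dose2"):
        ref = float(np.mean([getattr(r, attr) for r in st_results]))
        if ref == 0:
            raise ValueError("reference cohort administered no drug; fraction undefined")
        fracs.append(float(np.mean([getattr(r, attr) for r in arm_results])) / ref)
    return fracs[0], fracs[1]


def _with_rates(
    cfg: SimulationConfig,
    division: tuple[float, float, float, float],
    death: float,
) -> SimulationConfig:
    pop = replace(
        cfg.population,
        division_rates={
            CellType.DOUBLY_SENSITIVE: division[0],
            CellType.RES_DRUG1: division[1],
            CellType.RES_DRUG2: division[2],
            CellType.DOUBLY_RESISTANT: division[3],
        },
        background_death_rate=death,
    )
    return replace(cfg, population=pop)


def experiment_presets() -> dict[str, SimulationConfig]:
    """Named configurations for the supported parameter sweeps.

    Every preset is a full default configuration with one knob moved: fitness
    cost (net growth of sensitive vs doubly resistant cells), turnover
    (death/division rescaled at fixed net growth), tenfold-slow kinetics,
    replacement probability, Delta Tumor, Delta Dose, vacation threshold
    (fractions of the 5000-cell initiation burden), the FD-Intermittent stop
    threshold, and the no-reverse-mutation variant. The protocol is selected
    separately per arm.
    """
    base = SimulationConfig()
    presets: dict[str, SimulationConfig] = {"defaults": base}
    # fitness-cost presets: 5x is the default (0.06/0.04/0.04/0.02)
    presets["cost_3x"] = _with_rates(base, (0.04, 0.03, 0.03, 0.02), 0.01)
    # turnover presets keep every type's net growth rate (hence doubling time)
    presets["low_turnover"] = _with_rates(base, (0.055, 0.035, 0.035, 0.015), 0.005)
    presets["high_turnover"] = _with_rates(base, (0.07, 0.05, 0.05, 0.03), 0.02)
    presets["slow_kinetics"] = _with_rates(base, (0.006, 0.004, 0.004, 0.002), 0.001)
    # replacement presets
    for pct, r in (("0", 0.0), ("50", 0.5), ("100", 1.0)):
        pop = replace(base.population, replacement_probability=r)
        presets[f"replacement_{pct}"] = replace(base, population=pop)
    # burden-sensitivity presets
    for pct in (5, 10, 20, 40):
        presets[f"delta_tumor_{pct}"] = replace(
            base, protocol=replace(base.protocol, delta_tumor=pct / 100.0)
        )
    # dose-adjustment presets
    for pct in (25, 50, 75):
        presets[f"delta_dose_{pct}"] = replace(
            base, protocol=replace(base.protocol, delta_dose=pct / 100.0)
        )
    # vacation thresholds as fractions of the 5000-cell initiation burden
    for pct in (10, 50, 80):
        presets[f"vacation_{pct}pct"] = replace(
            base,
            protocol=replace(base.protocol, vacation_threshold=5000.0 * pct / 100.0),
        )
    # FD-Intermittent stop thresholds (fraction of initiation burden)
    for pct in (50, 80, 90, 95):
        presets[f"fd_stop_{pct}"] = replace(
            base, protocol=replace(base.protocol, fd_stop_fraction=pct / 100.0)
        )
    # genetic (irreversible) resistance variant
    pop = replace(base.population, allow_reverse_mutations=False)
    presets["no_reverse_mutations"] = replace(base, population=pop)
    return presets
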