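"""The six treatment controllers and their shared machinery.

Tumor burden is measured (with Gaussian noise) once every 3 days; treatment
starts at MTD when the measured burden first reaches half of carrying
capacity. Dose-modulation (DM) protocols multiply the dose up/down by Delta
Dose when the measured burden changes by more than Delta Tumor, take a
treatment vacation while the burden sits at or below a stop-dosing threshold,
and never administer a nonzero dose below the minimum formulable dose.
Fixed-dose (FD) protocols hold the dose at 75% of the cocktail MTD and either
skip applications (dose-skipping) or toggle dosing on/off at burden
thresholds relative to the initiation burden (intermittent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np


class Protocol(str, Enum):
    ST = "ST"
    DM_COCKTAIL = "DM_COCKTAIL"
    DM_PP_ALT = "DM_PP_ALT"
    DM_PP_PROG = "DM_PP_PROG"
    FD_SKIP = "FD_SKIP"
    FD_INT = "FD_INT"

    @property
    def is_dose_modulation(self) -> bool:
        return self in (Protocol.DM_COCKTAIL, Protocol.DM_PP_ALT, Protocol.DM_PP_PROG)

    @property
    def is_ping_pong(self) -> bool:
        return self in (Protocol.DM_PP_ALT, Protocol.DM_PP_PROG)


class Response(Enum):
    GREW = "grew"
    SHRANK = "shrank"
    STABLE = "stable"


class DoseDecision(NamedTuple):
    """Doses (units per drug) for each daily application in the coming cycle."""

    dose1: float
    dose2: float


@dataclass
class ProtocolConfig:
    """A treatment controller's parameters (package defaults)."""

    protocol: Protocol = Protocol.ST
    delta_tumor: float = 0.10
    delta_dose: float = 0.50
    vacation_threshold: float = 2500.0
    fd_dose: float = 2.25
    fd_stop_fraction: float = 0.5
    fd_restart_fraction: float = 1.0
    measurement_period: int = 72
    measurement_noise_sd: float = 5.0
    initiation_threshold: float = 5000.0
    mtd_single: float = 5.0
    mtd_combo: float = 3.0
    min_dose: float = 0.5
    #: When True, a measured burden above the running maximum counts as
    #: growth for the DM protocols (forcing a dose increase). Off by default:
    #: a controlled tumor drifts toward its crowding-limited density, and
    #: escalating the dose on every new maximum during that benign
    #: densification locks the controller at MTD and forfeits the competitive
    #: control the dose-modulation strategy exists to exploit. FD
    #: Dose-Skipping always uses its running-maximum trigger.
    max_burden_override: bool = False

    def __post_init__(self) -> None:
        self.protocol = Protocol(self.protocol)
        if self.protocol.is_dose_modulation and not (
            self.delta_tumor > 0 and self.delta_dose > 0
        ):
            raise ValueError("DM protocols require positive delta_tumor and delta_dose")
        if self.vacation_threshold >= self.initiation_threshold:
            raise ValueError("vacation threshold must lie below the initiation threshold")
        if self.measurement_period <= 0:
            raise ValueError("measurement_period must be positive")

    @property
    def mtd(self) -> float:
        """Applicable per-drug MTD: single-drug cap for ping-pong protocols,
        cocktail cap otherwise."""
        return self.mtd_single if self.protocol.is_ping_pong else self.mtd_combo


@dataclass
class ControllerState:
    """A controller's evolving memory between measurement cycles."""

    treatment_started: bool = False
    initiation_burden: float | None = None
    last_measured: float | None = None
    max_burden: float | None = None
    # Per-drug last administered nonzero dose; None = drug never used.
    last_dose: list[float | None] = field(default_factory=lambda: [None, None])
    # Measured burden when each drug last started a cycle (ping-pong alternate).
    measured_when_given: list[float | None] = field(default_factory=lambda: [None, None])
    active_drug: int = 1
    fd_dosing_on: bool = False
    on_vacation: bool = False


def measure_burden(true_count: float, sd: float, rng: np.random.Generator) -> int:
    """Noisy burden measurement: Gaussian, rounded, clamped at zero."""
    if true_count < 0:
        raise ValueError("true cell count must be non-negative")
    if sd == 0:
        return int(round(true_count))
    return max(0, int(round(rng.normal(true_count, sd))))


def classify_response(previous: float, current: float, delta_tumor: float) -> Response:
    """GREW if burden rose by more than Delta Tumor, SHRANK if it fell by at
    least Delta Tumor, STABLE otherwise."""
    if previous <= 0:
        raise ValueError("previous burden must be positive to classify a response")
    change = (current - previous) / previous
    if change > delta_tumor:
        return Response.GREW
    if -change >= delta_tumor:
        return Response.SHRANK
    return Response.STABLE


def _response(state: ControllerState, measured: float, cfg: ProtocolConfig) -> Response:
    """Response since the last measurement; with the optional
    maximum-tolerable-burden override, exceeding the running maximum counts
    as growth."""
    if cfg.max_burden_override and measured > state.max_burden:
        return Response.GREW
    if state.last_measured is None or state.last_measured <= 0:
        # Degenerate case (measured burden fell to 0 under treatment): any
        # nonzero regrowth registers as growth.
        return Response.GREW if measured > 0 else Response.STABLE
    return classify_response(state.last_measured, measured, cfg.delta_tumor)


def _clamp(dose: float, cfg: ProtocolConfig) -> float:
    """Clamp a proposed dose into ``{0} U [min_dose, applicable MTD]``."""
    if dose <= 0:
        return 0.0
    return min(max(dose, cfg.min_dose), cfg.mtd)


def apply_vacation_and_clamp(
    decision: DoseDecision,
    measured: float,
    cfg: ProtocolConfig,
    state: ControllerState,
) -> DoseDecision:
    """DM protocols only: zero the cycle's doses while the measured burden is
    at/below the stop-dosing threshold; otherwise clamp nonzero doses into
    ``[min_dose, MTD]``."""
    if cfg.protocol.is_dose_modulation and measured <= cfg.vacation_threshold:
        state.on_vacation = True
        return DoseDecision(0.0, 0.0)
    state.on_vacation = False
    return DoseDecision(_clamp(decision.dose1, cfg), _clamp(decision.dose2, cfg))


def decide_st(state: ControllerState, cfg: ProtocolConfig) -> DoseDecision:
    """Standard treatment: both drugs at cocktail MTD, every cycle, forever."""
    if not state.treatment_started:
        return DoseDecision(0.0, 0.0)
    return DoseDecision(cfg.mtd_combo, cfg.mtd_combo)


def decide_dm_cocktail(
    state: ControllerState, measured: float, cfg: ProtocolConfig
) -> tuple[DoseDecision, ControllerState]:
    """DM Cocktail Tandem: both doses adjusted together by Delta Dose.

    The modulation bookkeeping (response classification and the last-dose
    memory) runs every cycle; a treatment vacation only suppresses the
    administered doses for the cycle.
    """
    resp = _response(state, measured, cfg)
    dose = state.last_dose[0]
    if resp is Response.GREW:
        dose *= 1.0 + cfg.delta_dose
    elif resp is Response.SHRANK:
        dose *= 1.0 - cfg.delta_dose
    dose = _clamp(dose, cfg)
    state.last_dose = [dose, dose]
    return apply_vacation_and_clamp(DoseDecision(dose, dose), measured, cfg, state), state


def decide_dm_pingpong_alternate(
    state: ControllerState, measured: float, cfg: ProtocolConfig
) -> tuple[DoseDecision, ControllerState]:
    """DM Ping-Pong Alternate Every Cycle: drugs switch each cycle; the
    incoming drug's dose is adjusted by the tumor's response since that drug
    last started a cycle (two cycles earlier). First use is at MTD. As for the
    cocktail, a vacation only suppresses administration."""
    incoming = 2 if state.active_drug == 1 else 1
    idx = incoming - 1
    prev = state.last_dose[idx]
    if prev is None:
        dose = cfg.mtd
    else:
        reference = state.measured_when_given[idx]
        if cfg.max_burden_override and measured > state.max_burden:
            resp = Response.GREW
        elif reference is None or reference <= 0:
            resp = Response.GREW if measured > 0 else Response.STABLE
        else:
            resp = classify_response(reference, measured, cfg.delta_tumor)
        dose = prev
        if resp is Response.GREW:
            dose *= 1.0 + cfg.delta_dose
        elif resp is Response.SHRANK:
            dose *= 1.0 - cfg.delta_dose
    dose = _clamp(dose, cfg)
    state.active_drug = incoming
    state.last_dose[idx] = dose
    state.measured_when_given[idx] = measured
    decision = DoseDecision(dose, 0.0) if incoming == 1 else DoseDecision(0.0, dose)
    return apply_vacation_and_clamp(decision, measured, cfg, state), state


def decide_dm_pingpong_progression(
    state: ControllerState, measured: float, cfg: ProtocolConfig
) -> tuple[DoseDecision, ControllerState]:
    """DM Ping-Pong on Progression: stay on the active drug while the tumor is
    stable (same dose) or shrinking (dose down); on growth switch to the other
    drug at Delta Dose above its last-used dose (MTD on first use). As for the
    cocktail, a vacation only suppresses administration."""
    resp = _response(state, measured, cfg)
    if resp is Response.GREW:
        other = 3 - state.active_drug
        prev = state.last_dose[other - 1]
        dose = cfg.mtd if prev is None else prev * (1.0 + cfg.delta_dose)
        state.active_drug = other
    else:
        dose = state.last_dose[state.active_drug - 1]
        if resp is Response.SHRANK:
            dose *= 1.0 - cfg.delta_dose
    dose = _clamp(dose, cfg)
    state.last_dose[state.active_drug - 1] = dose
    decision = (
        DoseDecision(dose, 0.0) if state.active_drug == 1 else DoseDecision(0.0, dose)
    )
    return apply_vacation_and_clamp(decision, measured, cfg, state), state


def decide_fd_doseskip(
    state: ControllerState, measured: float, cfg: ProtocolConfig
) -> tuple[DoseDecision, ControllerState]:
    """FD Dose-Skipping: apply the fixed cocktail dose only if the tumor grew
    by more than Delta Tumor or exceeded its previous maximum; otherwise skip."""
    if measured > state.max_burden:
        return DoseDecision(cfg.fd_dose, cfg.fd_dose), state
    resp = _response(state, measured, cfg)
    if resp is Response.GREW:
        return DoseDecision(cfg.fd_dose, cfg.fd_dose), state
    return DoseDecision(0.0, 0.0), state


def decide_fd_intermittent(
    state: ControllerState, measured: float, cfg: ProtocolConfig
) -> tuple[DoseDecision, ControllerState]:
    """FD Intermittent: hysteresis on the absolute burden. Dosing stops once
    the measured burden falls to the stop fraction of the initiation burden and
    restarts once it regrows to the restart fraction of the initiation burden."""
    if measured <= cfg.fd_stop_fraction * state.initiation_burden:
        state.fd_dosing_on = False
    elif measured >= cfg.fd_restart_fraction * state.initiation_burden:
        state.fd_dosing_on = True
    if state.fd_dosing_on:
        return DoseDecision(cfg.fd_dose, cfg.fd_dose), state
    return DoseDecision(0.0, 0.0), state


def _initial_decision(
    state: ControllerState, measured: float, cfg: ProtocolConfig
) -> DoseDecision:
    """Doses for the cycle in which treatment is initiated."""
    p = cfg.protocol
    if p in (Protocol.ST, Protocol.DM_COCKTAIL):
        state.last_dose = [cfg.mtd_combo, cfg.mtd_combo]
        return DoseDecision(cfg.mtd_combo, cfg.mtd_combo)
    if p.is_ping_pong:
        state.active_drug = 1
        state.last_dose[0] = cfg.mtd
        state.measured_when_given[0] = measured
        return DoseDecision(cfg.mtd, 0.0)
    if p is Protocol.FD_INT:
        state.fd_dosing_on = True
    # FD protocols start at the fixed 75%-of-MTD cocktail dose.
    return DoseDecision(cfg.fd_dose, cfg.fd_dose)


_DISPATCH = {
    Protocol.DM_COCKTAIL: decide_dm_cocktail,
    Protocol.DM_PP_ALT: decide_dm_pingpong_alternate,
    Protocol.DM_PP_PROG: decide_dm_pingpong_progression,
    Protocol.FD_SKIP: decide_fd_doseskip,
    Protocol.FD_INT: decide_fd_intermittent,
}


def controller_update(
    state: ControllerState,
    true_burden: float,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
) -> tuple[DoseDecision, ControllerState]:
    """One measurement-cycle update: measure with noise, initiate treatment
    when the measured burden first reaches the initiation threshold, then
    dispatch to the protocol's decision rule.

    Controllers act on noisy measurements throughout (initiation, response
    classification, vacations, the running maximum); true counts are used only
    for progression scoring by the engine.
    """
    if not isinstance(cfg.protocol, Protocol):
        raise ValueError(f"unknown protocol: {cfg.protocol!r}")
    measured = measure_burden(true_burden, cfg.measurement_noise_sd, rng)
    if not state.treatment_started:
        if measured >= cfg.initiation_threshold:
            state.treatment_started = True
            state.initiation_burden = measured
            state.last_measured = measured
            state.max_burden = measured
            return _initial_decision(state, measured, cfg), state
        return DoseDecision(0.0, 0.0), state
    if cfg.protocol is Protocol.ST:
        decision = decide_st(state, cfg)
    else:
        decision, state = _DISPATCH[cfg.protocol](state, measured, cfg)
    state.last_measured = measured
    if measured > state.max_burden:
        state.max_burden = measured
    return decision, state
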