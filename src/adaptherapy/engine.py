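"""The per-step scheduler, progression scoring, and the replicate runner.

Each 1-hour step updates the drug field first (dosing at scheduled daily
application hours once treatment is active, then diffusion and decay) and then
visits every cell occupied at the start of the step in a fresh uniform random
order: the cell dies with its local death probability, and survivors may
divide; daughters can mutate and are not revisited within the step.

A run is scored as progressed at the first step where the rolling 500-step
mean of total burden reaches 98% of carrying capacity or the rolling mean of
the doubly resistant count reaches 20% of carrying capacity. Simulations
always run to the full horizon; progression is a recorded event, not a
stopping rule, so drug usage is accounted over the same amount of time in
every arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .cells import CellPopulationParams, CellType, Lattice, mutation_targets, seed_tumor
from .drugs import DrugField, DrugParams, drug_update
from .protocols import (
    ControllerState,
    DoseDecision,
    Protocol,
    ProtocolConfig,
    controller_update,
)


@dataclass
class SimulationConfig:
    """Full configuration of one run (package defaults)."""

    width: int = 100
    height: int = 100
    duration: int = 5000
    progression_window: int = 500
    progression_burden_fraction: float = 0.98
    progression_resistant_fraction: float = 0.20
    seeding_radius: int = 10
    seed_cell_types: tuple[CellType, ...] = tuple(CellType)
    seed: int = 0
    population: CellPopulationParams = field(default_factory=CellPopulationParams)
    drugs: DrugParams = field(default_factory=DrugParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    @property
    def carrying_capacity(self) -> int:
        return self.width * self.height

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("lattice dimensions must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.progression_window <= self.duration:
            raise ValueError("progression window must lie in (0, duration]")
        for f in (self.progression_burden_fraction, self.progression_resistant_fraction):
            if not 0 < f <= 1:
                raise ValueError("progression fractions must lie in (0, 1]")
        if not self.seed_cell_types:
            raise ValueError("seed_cell_types must not be empty")

    def with_protocol(self, protocol: Protocol | str, **overrides) -> "SimulationConfig":
        """Copy of this config running a different treatment protocol."""
        proto_cfg = replace(self.protocol, protocol=Protocol(protocol), **overrides)
        return replace(self, protocol=proto_cfg)


@dataclass
class TimeSeries:
    """Per-step records (row t-1 holds the state after step t, t = 1..duration)."""

    step: np.ndarray
    n_doubly_sensitive: np.ndarray
    n_res_drug1: np.ndarray
    n_res_drug2: np.ndarray
    n_doubly_resistant: np.ndarray
    total: np.ndarray
    dose1: np.ndarray  # amount of drug 1 administered during the step
    dose2: np.ndarray

    @property
    def cum_dose1(self) -> np.ndarray:
        return np.cumsum(self.dose1)

    @property
    def cum_dose2(self) -> np.ndarray:
        return np.cumsum(self.dose2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "n_doubly_sensitive": self.n_doubly_sensitive,
                "n_res_drug1": self.n_res_drug1,
                "n_res_drug2": self.n_res_drug2,
                "n_doubly_resistant": self.n_doubly_resistant,
                "total": self.total,
                "dose1": self.dose1,
                "dose2": self.dose2,
                "cum_dose1": self.cum_dose1,
                "cum_dose2": self.cum_dose2,
            }
        )


@dataclass
class RunResult:
    """Outcome of one replicate."""

    progressed: bool
    progression_time: int | None  # step of first crossing; None if censored
    duration: int
    timeseries: TimeSeries
    cumulative_dose1: float
    cumulative_dose2: float
    seed: int

    @property
    def censored(self) -> bool:
        return not self.progressed

    @property
    def time_days(self) -> float:
        t = self.progression_time if self.progressed else self.duration
        return t / 24.0


def check_progression(series: TimeSeries, t: int, cfg: SimulationConfig) -> bool:
    """Whether the progression criteria hold at step ``t`` (1-based).

    True iff a full rolling window exists (t >= window) and the window mean of
    total burden reaches the burden fraction of capacity, or the window mean
    of the doubly resistant count reaches the resistant fraction of capacity.
    """
    if t > len(series.step):
        raise ValueError("t exceeds the recorded series length")
    w = cfg.progression_window
    if t < w:
        return False
    cap = cfg.carrying_capacity
    sl = slice(t - w, t)
    return bool(
        series.total[sl].mean() >= cfg.progression_burden_fraction * cap
        or series.n_doubly_resistant[sl].mean()
        >= cfg.progression_resistant_fraction * cap
    )


def step_cell_pass(
    grid: np.ndarray,
    conc1: np.ndarray,
    conc2: np.ndarray,
    population: CellPopulationParams,
    potency1: float,
    potency2: float,
    rng: np.random.Generator,
) -> None:
    """One full cell-update pass over ``grid`` (in place).

    Visits the sites occupied at entry in a fresh uniform random order; each
    visited cell first risks death at its local death probability and, if it
    survives, attempts division (daughters may mutate and are skipped for the
    rest of the pass).
    """
    born = np.zeros(grid.shape, dtype=np.bool_)
    _kernels.step_cells(
        grid,
        born,
        conc1,
        conc2,
        population.division_rate_array(),
        population.background_death_rate,
        potency1,
        potency2,
        _sensitivity_array(1),
        _sensitivity_array(2),
        population.replacement_probability,
        population.mutation_rate,
        *_mutation_tables(population),
        rng,
    )


def _sensitivity_array(drug: int) -> np.ndarray:
    arr = np.zeros(5, dtype=np.float64)
    for t in CellType:
        sens = t.sensitive_to_drug1 if drug == 1 else t.sensitive_to_drug2
        arr[int(t)] = 1.0 if sens else 0.0
    return arr


def _mutation_tables(population: CellPopulationParams) -> tuple[np.ndarray, np.ndarray]:
    targets = np.zeros((5, 3), dtype=np.int8)
    counts = np.zeros(5, dtype=np.int64)
    for t in CellType:
        allowed = mutation_targets(t, population.allow_reverse_mutations)
        counts[int(t)] = len(allowed)
        for j, a in enumerate(allowed):
            targets[int(t), j] = int(a)
    return targets, counts


class Simulation:
    """A single replicate: lattice + drug field + controller + schedule."""

    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.lattice = Lattice.empty(cfg.width, cfg.height)
        seed_tumor(self.lattice, cfg.seeding_radius, self.rng, cfg.seed_cell_types)
        self.field = DrugField.zeros(cfg.width, cfg.height)
        self.state = ControllerState()
        self.current_decision = DoseDecision(0.0, 0.0)
        self.treatment_start_step: int | None = None
        # cached parameter arrays for the compiled kernel
        self._div = cfg.population.division_rate_array()
        self._s1 = _sensitivity_array(1)
        self._s2 = _sensitivity_array(2)
        self._mut_targets, self._mut_counts = _mutation_tables(cfg.population)
        self._born = np.zeros((cfg.height, cfg.width), dtype=np.bool_)

    def _cell_pass(self) -> None:
        pop = self.cfg.population
        _kernels.step_cells(
            self.lattice.grid,
            self._born,
            self.field.conc1,
            self.field.conc2,
            self._div,
            pop.background_death_rate,
            self.cfg.drugs.potency1,
            self.cfg.drugs.potency2,
            self._s1,
            self._s2,
            pop.replacement_probability,
            pop.mutation_rate,
            self._mut_targets,
            self._mut_counts,
            self.rng,
        )

    def run(self) -> RunResult:
        cfg = self.cfg
        duration = cfg.duration
        window = cfg.progression_window
        cap = cfg.carrying_capacity
        burden_threshold = cfg.progression_burden_fraction * cap * window
        resistant_threshold = cfg.progression_resistant_fraction * cap * window

        counts_hist = np.zeros((duration, 4), dtype=np.int64)
        dose_hist = np.zeros((duration, 2), dtype=np.float64)
        total_hist = np.zeros(duration, dtype=np.int64)
        rolling_total = 0
        rolling_resistant = 0
        progression_time: int | None = None

        for t in range(duration):
            # measurement/decision every 3 days (includes step 0)
            if t % cfg.protocol.measurement_period == 0:
                already_started = self.state.treatment_started
                decision, self.state = controller_update(
                    self.state, self.lattice.total(), cfg.protocol, self.rng
                )
                self.current_decision = decision
                if self.state.treatment_started and not already_started:
                    self.treatment_start_step = t
            # daily drug application, anchored to treatment initiation
            dosing_now = (
                self.state.treatment_started
                and (t - self.treatment_start_step) % cfg.drugs.dosing_period == 0
            )
            doses = self.current_decision if dosing_now else (0.0, 0.0)
            drug_update(self.field, doses, dosing_now, cfg.drugs)
            if dosing_now:
                dose_hist[t, 0] = doses[0]
                dose_hist[t, 1] = doses[1]
            # stochastic cell update
            self._cell_pass()
            c = np.bincount(self.lattice.grid.ravel(), minlength=5)
            counts_hist[t] = c[1:5]
            total = int(c[1:5].sum())
            total_hist[t] = total
            # rolling progression scoring (integer sums: exact)
            rolling_total += total
            rolling_resistant += int(c[int(CellType.DOUBLY_RESISTANT)])
            if t >= window:
                rolling_total -= int(total_hist[t - window])
                rolling_resistant -= int(counts_hist[t - window, 3])
            if (
                progression_time is None
                and t + 1 >= window
                and (
                    rolling_total >= burden_threshold
                    or rolling_resistant >= resistant_threshold
                )
            ):
                progression_time = t + 1

        series = TimeSeries(
            step=np.arange(1, duration + 1),
            n_doubly_sensitive=counts_hist[:, 0],
            n_res_drug1=counts_hist[:, 1],
            n_res_drug2=counts_hist[:, 2],
            n_doubly_resistant=counts_hist[:, 3],
            total=total_hist,
            dose1=dose_hist[:, 0],
            dose2=dose_hist[:, 1],
        )
        return RunResult(
            progressed=progression_time is not None,
            progression_time=progression_time,
            duration=duration,
            timeseries=series,
            cumulative_dose1=float(dose_hist[:, 0].sum()),
            cumulative_dose2=float(dose_hist[:, 1].sum()),
            seed=cfg.seed,
        )


def run_simulation(cfg: SimulationConfig) -> RunResult:
    """Seed a tumor and run one full replicate of the configured protocol."""
    return Simulation(cfg).run()


def run_replicates(
    cfg: SimulationConfig,
    n: int,
    base_seed: int,
    arm: str = "arm",
) -> tuple[list[RunResult], pd.DataFrame]:
    """Run ``n`` independent replicates with seeds ``base_seed + i``.

    Returns the run results and a survival table with one row per replicate
    (columns: replicate, arm, time_days, event); censoring is administrative
    at the full horizon.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    results = [run_simulation(replace(cfg, seed=base_seed + i)) for i in range(n)]
    table = pd.DataFrame(
        {
            "replicate": np.arange(n),
            "arm": arm,
            "time_days": [r.time_days for r in results],
            "event": [r.progressed for r in results],
        }
    )
    return results, table
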