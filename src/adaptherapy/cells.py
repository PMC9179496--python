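"""Discrete tumor-cell state and the stochastic birth/death/mutation rules.

The tumor lives on a 2-D square lattice with at most one cell per site. Four
phenotypes are modelled for a two-drug regimen: doubly sensitive, singly
resistant to either drug, and doubly resistant. Resistance carries a fitness
cost expressed as a lower division rate; all types share one background death
rate, and drug exposure adds to the death probability of sensitive types only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Mapping

import numpy as np

#: Lattice code for an unoccupied site.
EMPTY = 0


class CellType(IntEnum):
    """The four tumor phenotypes of the two-drug model."""

    DOUBLY_SENSITIVE = 1
    RES_DRUG1 = 2
    RES_DRUG2 = 3
    DOUBLY_RESISTANT = 4

    @property
    def sensitive_to_drug1(self) -> bool:
        return self not in (CellType.RES_DRUG1, CellType.DOUBLY_RESISTANT)

    @property
    def sensitive_to_drug2(self) -> bool:
        return self not in (CellType.RES_DRUG2, CellType.DOUBLY_RESISTANT)

    @property
    def resistances(self) -> frozenset[int]:
        """The set of drugs (1 and/or 2) this phenotype resists."""
        res = set()
        if not self.sensitive_to_drug1:
            res.add(1)
        if not self.sensitive_to_drug2:
            res.add(2)
        return frozenset(res)


#: Default division rates (probability per hour): the doubly
#: sensitive type divides fastest, resistance costs division speed.
DEFAULT_DIVISION_RATES: dict[CellType, float] = {
    CellType.DOUBLY_SENSITIVE: 0.06,
    CellType.RES_DRUG1: 0.04,
    CellType.RES_DRUG2: 0.04,
    CellType.DOUBLY_RESISTANT: 0.02,
}


@dataclass
class CellPopulationParams:
    """Per-type division rates and the shared stochastic-process parameters.

    Parameters
    ----------
    division_rates
        Probability per hour of division for each :class:`CellType`. Must obey
        the fitness-cost ordering ``S >= R1 == R2 >= R12``.
    background_death_rate
        Drug-independent death probability per hour, identical for all types.
    replacement_probability
        Probability ``r`` that a dividing cell with no empty neighbor replaces
        a neighbor instead (``r = 0`` is contact inhibition, ``r = 1`` is
        neighbor killing).
    mutation_rate
        Probability ``mu`` per cell division that the daughter switches to any
        one particular other type (so total switching probability ``3 mu``).
    allow_reverse_mutations
        When False, transitions that would remove a resistance are forbidden.
    """

    division_rates: Mapping[CellType, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVISION_RATES)
    )
    background_death_rate: float = 0.01
    replacement_probability: float = 0.5
    mutation_rate: float = 1e-3
    allow_reverse_mutations: bool = True

    def __post_init__(self) -> None:
        self.division_rates = {CellType(k): float(v) for k, v in self.division_rates.items()}
        if set(self.division_rates) != set(CellType):
            raise ValueError("division_rates must cover all four cell types")
        rates = [
            self.background_death_rate,
            self.replacement_probability,
            self.mutation_rate,
            *self.division_rates.values(),
        ]
        if any(not (0.0 <= x <= 1.0) for x in rates):
            raise ValueError("all rates and probabilities must lie in [0, 1]")
        if 3.0 * self.mutation_rate > 1.0:
            raise ValueError("mutation rate too large: 3*mu must not exceed 1")
        d = self.division_rates
        if not (
            d[CellType.DOUBLY_SENSITIVE]
            >= d[CellType.RES_DRUG1]
            == d[CellType.RES_DRUG2]
            >= d[CellType.DOUBLY_RESISTANT]
        ):
            raise ValueError(
                "division rates must satisfy the fitness-cost ordering S >= R1 == R2 >= R12"
            )

    def division_rate(self, cell_type: CellType) -> float:
        return self.division_rates[CellType(cell_type)]

    def division_rate_array(self) -> np.ndarray:
        """Division rates indexed by lattice code (index 0 = empty = 0.0)."""
        arr = np.zeros(5, dtype=np.float64)
        for t, v in self.division_rates.items():
            arr[int(t)] = v
        return arr


@dataclass
class Lattice:
    """A rectangular grid holding at most one cell (by type code) per site.

    Sites are addressed as ``(row, col)``; ``grid`` stores ``EMPTY`` (0) or a
    :class:`CellType` value.
    """

    grid: np.ndarray

    @classmethod
    def empty(cls, width: int, height: int) -> "Lattice":
        return cls(np.zeros((height, width), dtype=np.int8))

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def counts(self) -> dict[CellType, int]:
        c = np.bincount(self.grid.ravel(), minlength=5)
        return {t: int(c[int(t)]) for t in CellType}

    def total(self) -> int:
        return int(np.count_nonzero(self.grid))

    def in_bounds(self, site: tuple[int, int]) -> bool:
        y, x = site
        return 0 <= y < self.height and 0 <= x < self.width


_MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def moore_neighbors(lattice: Lattice, site: tuple[int, int]) -> list[tuple[int, int]]:
    """In-bounds subset of the 8 sites surrounding ``site`` (no wrap-around)."""
    if not lattice.in_bounds(site):
        raise ValueError(f"site {site} outside lattice bounds")
    y, x = site
    return [
        (y + dy, x + dx)
        for dy, dx in _MOORE_OFFSETS
        if lattice.in_bounds((y + dy, x + dx))
    ]


def death_probability(
    cell_type: CellType,
    conc1: float,
    conc2: float,
    params: CellPopulationParams,
    potency1: float,
    potency2: float,
) -> float:
    """Hourly death probability: background plus drug kill of sensitive types.

    ``p = background + S1*[Drug1]*Psi1 + S2*[Drug2]*Psi2`` with S1, S2 the
    binary sensitivity indicators. Clamped at 1 as a safety contract.
    """
    if conc1 < 0 or conc2 < 0:
        raise ValueError("drug concentrations must be non-negative")
    if potency1 < 0 or potency2 < 0:
        raise ValueError("drug potencies must be non-negative")
    t = CellType(cell_type)
    p = params.background_death_rate
    if t.sensitive_to_drug1:
        p += conc1 * potency1
    if t.sensitive_to_drug2:
        p += conc2 * potency2
    return min(p, 1.0)


class DivisionOutcome(Enum):
    NO_DIVISION = "no_division"
    PLACED = "placed"
    REPLACED = "replaced"


def attempt_division(
    lattice: Lattice,
    site: tuple[int, int],
    params: CellPopulationParams,
    rng: np.random.Generator,
) -> tuple[DivisionOutcome, tuple[int, int] | None]:
    """One division attempt for the cell at ``site``.

    With probability equal to the type's division rate the cell divides: the
    daughter is placed uniformly at random in an empty Moore-neighbor site; if
    none is empty, with probability ``r`` a uniformly chosen neighbor is
    replaced by the daughter. The daughter initially inherits the parent type
    (mutation is a separate step, see :func:`mutate_daughter`); the lattice is
    updated in place.

    Returns the outcome and the daughter's site (or None).
    """
    t = lattice.grid[site]
    if t == EMPTY:
        raise ValueError(f"site {site} is empty; only occupied cells can divide")
    t = CellType(t)
    if rng.random() >= params.division_rate(t):
        return DivisionOutcome.NO_DIVISION, None
    neighbors = moore_neighbors(lattice, site)
    empties = [s for s in neighbors if lattice.grid[s] == EMPTY]
    if empties:
        daughter = empties[int(rng.integers(len(empties)))]
        lattice.grid[daughter] = int(t)
        return DivisionOutcome.PLACED, daughter
    if rng.random() < params.replacement_probability:
        victim = neighbors[int(rng.integers(len(neighbors)))]
        lattice.grid[victim] = int(t)
        return DivisionOutcome.REPLACED, victim
    return DivisionOutcome.NO_DIVISION, None


def mutation_targets(parent_type: CellType, allow_reverse: bool) -> tuple[CellType, ...]:
    """Phenotypes reachable from ``parent_type`` in one division.

    With ``allow_reverse`` every other type is reachable. Otherwise only
    transitions that preserve every existing resistance are allowed (so the
    doubly resistant type is absorbing, and R1<->R2 swaps are forbidden since a
    swap drops one resistance).
    """
    parent = CellType(parent_type)
    targets = []
    for t in CellType:
        if t == parent:
            continue
        if allow_reverse or parent.resistances <= t.resistances:
            targets.append(t)
    return tuple(targets)


def mutate_daughter(
    parent_type: CellType,
    mu: float,
    allow_reverse: bool,
    rng: np.random.Generator,
) -> CellType:
    """Type of a newborn daughter: each permitted target with probability ``mu``.

    The parent type is retained with the remaining probability. Only the
    daughter can mutate; the parent never changes type.
    """
    if not 0.0 <= 3.0 * mu <= 1.0:
        raise ValueError("mutation rate must satisfy 0 <= 3*mu <= 1")
    targets = mutation_targets(parent_type, allow_reverse)
    u = rng.random()
    for j, t in enumerate(targets):
        if u < mu * (j + 1):
            return t
    return CellType(parent_type)


def net_growth_rate(cell_type: CellType, params: CellPopulationParams) -> float:
    """Division rate minus background death rate (per hour)."""
    return params.division_rate(CellType(cell_type)) - params.background_death_rate


def doubling_time(cell_type: CellType, params: CellPopulationParams) -> float:
    """Population doubling time ``ln 2 / net growth rate`` in hours."""
    g = net_growth_rate(cell_type, params)
    if g <= 0:
        raise ValueError("doubling time undefined for non-positive net growth rate")
    return math.log(2.0) / g


def seed_tumor(
    lattice: Lattice,
    radius: int,
    rng: np.random.Generator,
    types: tuple[CellType, ...] = tuple(CellType),
) -> Lattice:
    """Seed a disc of cells at the lattice center, types drawn uniformly.

    A site belongs to the disc when its squared Euclidean distance from the
    center site is at most ``radius**2``. Each seeded cell's type is drawn
    uniformly from ``types`` (by default all four).
    """
    cy, cx = lattice.height // 2, lattice.width // 2
    if (
        cy - radius < 0
        or cx - radius < 0
        or cy + radius >= lattice.height
        or cx + radius >= lattice.width
    ):
        raise ValueError("seeding disc exceeds lattice bounds")
    ys, xs = np.mgrid[0 : lattice.height, 0 : lattice.width]
    mask = (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2
    n = int(mask.sum())
    choices = np.array([int(t) for t in types], dtype=np.int8)
    lattice.grid[mask] = choices[rng.integers(len(choices), size=n)]
    return lattice
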