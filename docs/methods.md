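# Model and methods

`adaptherapy` simulates the evolution of drug resistance in a tumor treated
with two drugs under six treatment-scheduling strategies, and scores the
strategies by time to progression (TTP) over replicate cohorts with
Kaplan–Meier and Cox proportional-hazards analysis.

## The agent-based model

**Cells.** The tumor is a set of cells on a 100×100 square lattice, at most
one cell per site, with four phenotypes for a two-drug regimen: doubly
sensitive (S), resistant to drug 1 only (R1), resistant to drug 2 only (R2),
and doubly resistant (R12). Resistance is binary and carries a fitness cost
expressed through the division rates (defaults, probability per hour):

| type | division | net growth (− death 0.01/h) | doubling time |
|------|----------|------------------------------|---------------|
| S    | 0.06     | 0.05                         | 13.86 h       |
| R1, R2 | 0.04   | 0.03                         | 23.1 h        |
| R12  | 0.02     | 0.01                         | 69.3 h        |

**Per-step schedule** (1 step = 1 h). The drug field is updated first
(dosing, diffusion, decay), then every cell occupied at the start of the step
is visited in a fresh uniform random order. A visited cell dies with
probability

```
p_death = background + S1·[Drug1]·Ψ1 + S2·[Drug2]·Ψ2      (clamped at 1)
```

where S1, S2 are binary sensitivity indicators and Ψ1 = Ψ2 = 0.04 per unit
concentration per hour. A survivor divides with its type's division
probability: the daughter is placed uniformly at random in an empty Moore
neighbor site; if none is empty, with probability *r* = 0.5 (replacement) a
uniformly chosen neighbor is killed and the daughter takes its site. A
daughter switches to each of the three other phenotypes with probability
μ = 10⁻³ (optionally restricted so that no transition removes a resistance);
daughters act from the next step onward.

Note the discrete-time process grows at `ln((1−d)(1+b))` per hour, slightly
below the nominal `b − d` (0.0482 vs 0.05 for S); the doubling times above
are the nominal continuous-time values and the calibration tests allow for
the offset.

**Drugs.** Delivery is spatially uniform (a well-perfused tumor): one bolus
per drug every 24 h adds the dose to every site. Ten percent of each drug
decays per hour, and the field diffuses (D = 2.0 lattice²/step) under a
Peaceman–Rachford ADI solve with zero-flux boundaries. Because uniform
dosing keeps an initially uniform field exactly uniform, diffusion is inert
in production runs and is skipped when the field is uniform; the solver is
exercised directly by the tests. A single ADI solve at D = 2 is stable but
oscillatory on sharp sources, so each unit step is internally sub-stepped to
keep the half-step coefficient ≤ 1/4, which keeps point-source solutions
nonnegative and within a few percent of a fine-step explicit reference.
Within a step the order is dose → diffuse → decay.

**Treatment controllers.** Burden is measured every 72 h with Gaussian noise
(SD 5 cells, rounded, clamped at 0); treatment starts at MTD when the
measured burden first reaches 50% of carrying capacity (5000 cells). MTD is
5 units for a drug given singly and 3 units per drug in a cocktail.

- **ST** — both drugs at cocktail MTD (3 + 3) daily, forever.
- **DM Cocktail Tandem** — both doses together ×(1+ΔD) after >ΔT growth,
  ×(1−ΔD) after ≥ΔT shrinkage, unchanged otherwise (ΔT = 10%, ΔD = 50%);
  nonzero doses clamped to [0.5, 3].
- **DM Ping-Pong Alternate** — one drug at a time, switching every cycle;
  the incoming drug's dose is adjusted by the response since that drug last
  started a cycle; first use at MTD 5.
- **DM Ping-Pong on Progression** — stays on the active drug while the tumor
  is stable/shrinking (stepping the dose down on shrinkage); growth switches
  to the other drug at ΔD above its last-used dose (MTD 5 first).
- **FD Dose-Skipping** — fixed 2.25 + 2.25 (75% of cocktail MTD) applied
  only on cycles where the tumor grew >ΔT or exceeded its previous measured
  maximum; otherwise skipped.
- **FD Intermittent** — fixed 2.25 + 2.25 with hysteresis on the absolute
  burden: off once the burden falls to 50% of the initiation burden, on
  again once it regrows to 100% of it.

DM protocols take a *treatment vacation* (no administration for the cycle)
whenever the measured burden is at or below 2500 cells. The modulation
bookkeeping — response classification and the per-drug last-dose memory —
runs every cycle regardless; a vacation suppresses only the administered
doses. This keeps the remembered dose tracking the tumor's trajectory, so
dosing resumes from a sensible level; freezing the memory instead makes
every controller re-enter at MTD after each vacation and behave like
intermittent maximum dosing.

An optional *maximum-tolerable-burden override*
(`ProtocolConfig.max_burden_override`, default off) treats any measurement
above the running maximum as growth. It is off by default because a
controlled tumor drifts slowly toward its crowding-limited density; with the
override on, nearly every cycle of that benign densification sets a new
measured maximum, so the controller ratchets the dose to MTD, eradicates the
sensitive competitors, and reproduces exactly the competitive release that
dose modulation is meant to prevent. FD Dose-Skipping keeps its
running-maximum trigger unconditionally — there it defines the protocol.

Controllers see only noisy measurements (initiation, classification,
vacations, the running maximum); true counts are used only for progression
scoring.

**Initialization and progression.** The tumor is seeded as a disc of radius
10 (317 sites, each type with equal probability) at the lattice center. Runs
last 5000 steps (~208 days). A run is scored *progressed* at the first step
where the rolling 500-step mean of total burden reaches 98% of carrying
capacity or the rolling mean of the R12 count reaches 20% of capacity;
simulations always continue to the full horizon (progression is an event,
not a stopping rule), so drug usage is accounted over the same time in every
arm. Censoring is administrative at 5000 steps.

A structural note: with the default rates the untreated crowding equilibrium
is `(1 − death/division)^(1/8) ≈ 97.7%` of capacity — marginally below the
98% burden criterion — so in practice progression is driven by the doubly
resistant population. The `no_drug` test fixture lowers the burden fraction
to 95% so that saturation registers as progression in structural tests.

## Dynamics worth knowing about

Under ST, continuous MTD eradicates the sensitive (and singly resistant)
populations within days; the pre-existing R12 cells then expand into the
emptied lattice without competition and the run progresses by the R12
criterion (competitive release). Dose-modulation protocols instead let the
burden settle into a crowding-limited quasi-steady state at a low dose;
there, R12 clones are boxed in by dense faster-dividing neighbors whose
crowded divisions replace them, which slows the resistant expansion
substantially and extends TTP. The weeks immediately after treatment
initiation — when the MTD starting dose crashes the burden and the tumor
regrows through a porous low-density phase — are when most resistant
expansion happens in the DM arms.

## Random numbers and determinism

Each replicate uses one seeded `numpy.random.Generator` (PCG64) for
everything: measurement noise, the per-step visit order (in-kernel
Fisher–Yates), and all Bernoulli/choice draws, consumed on demand inside the
compiled step kernel. A replay from the same configuration and seed is
bit-exact; `run_replicates` derives replicate seeds as `base_seed + index`.
The per-cell loop is compiled with numba; a naive order-explicit Python
implementation built from the public cell-level operations serves as a
distributional cross-check in the tests.

## Survival analysis

Progression times are reported in days (steps/24). Kaplan–Meier curves use
the product-limit estimator and two-arm comparisons a Cox
proportional-hazards fit with a single arm indicator, Efron tie handling
(ties are common at the coarse effective resolution of progression) and Wald
95% intervals, both via lifelines. Tests cross-check them against a
hand-computed product-limit table and a direct partial-likelihood
maximization. Drug usage is the mean cumulative administered dose per drug
over the full horizon, expressed relative to the ST cohort.

## Experiment presets

`experiment_presets()` returns the sweep catalog: fitness cost 3× (division
0.04/0.03/0.03/0.02) vs the 5× default; low turnover (death 0.005/h,
division 0.055/0.035/0.035/0.015) and high turnover (death 0.02/h, division
0.07/0.05/0.05/0.03), both preserving each type's net growth rate and hence
its doubling time; tenfold-slowed kinetics; replacement r ∈ {0, 0.5, 1};
ΔT ∈ {5, 10, 20, 40}%; ΔD ∈ {25, 50, 75}%; vacation thresholds at
{10, 50, 80}% of the 5000-cell initiation burden ({500, 2500, 4000} cells);
FD-Intermittent stop thresholds at {50, 80, 90, 95}% of the initiation
burden; and the no-reverse-mutation (irreversible resistance) variant.

## Problem sizes in the tests

The full-size comparisons (50 replicates/arm on the 100×100 grid over 5000
steps) are reserved for the cohort-level acceptance checks and the
acceptance script. Unit and property tests use scaled-down configurations —
20×20 to 50×50 grids, hundreds to ~1500 steps, with the initiation and
vacation thresholds kept at 50%/25% of the scaled capacity — and calibration
tests use many isolated ancestors on a sparse lattice over short horizons so
growth stays in the exponential regime. Scaled tests exercise the same code
paths at identical per-cell rates; they do not probe full-grid saturation
time scales.

## Known limitations

- Two drugs, binary resistance, no explicit vasculature, immune compartment
  or 3-D structure; drug delivery is spatially uniform.
- The burden progression criterion is effectively inert at default
  parameters (see above); outcomes hinge on the resistant-count criterion.
- Cell motility and pushing are absent; spatial competition acts only
  through site occupancy and replacement.
- The division placement rule ("any empty neighbor") makes interior
  suppression of resistant clones weaker than rules whose division success
  scales with local emptiness; the controlled regime therefore sits at high
  lattice occupancy.
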