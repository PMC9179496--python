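# adaptherapy

Agent-based simulation of **two-drug adaptive cancer therapy**, with a
replicate survival-analysis harness.

Tumors treated continuously at the maximum tolerated dose (MTD) often evolve
resistance by *competitive release*: the drug eradicates the sensitive cells
that were competing with resistant clones for space, and the resistant
population then expands unopposed. Adaptive therapy instead modulates dosing
against tumor burden to keep sensitive cells alive as competitors.
`adaptherapy` is a simulation laboratory for comparing such strategies with
two drugs: it couples a stochastic cell lattice to a diffusing, decaying
two-drug field, drives it with six treatment controllers, and scores
strategies by time to progression (TTP) over replicate cohorts with
Kaplan–Meier curves and Cox proportional-hazards regression. It is aimed at
computational-oncology and evolutionary-medicine researchers exploring
treatment-scheduling questions in silico.

## Model

Cells of four phenotypes — doubly sensitive (S), singly resistant (R1, R2),
doubly resistant (R12) — occupy a 100×100 lattice, one cell per site. Each
hourly step, every cell dies with probability

    p = d₀ + S₁·[Drug1]·Ψ₁ + S₂·[Drug2]·Ψ₂

(background d₀ = 0.01/h, potencies Ψ = 0.04 per unit per hour, S₁/S₂ binary
sensitivities), and survivors divide with type-specific rates (0.06, 0.04,
0.04, 0.02 per hour — resistance costs division speed) into an empty Moore
neighbor, or replace a neighbor with probability r = 0.5 when crowded.
Daughters mutate between phenotypes at 10⁻³ per division per target type.
Drugs are dosed uniformly once a day, decay 10%/h, and diffuse (ADI solver,
zero-flux boundaries).

Six controllers are implemented: continuous MTD cocktail (**ST**), dose
modulation of both drugs in tandem (**DM Cocktail**), single-drug ping-pong
schedules (**DM Ping-Pong Alternate** / **on Progression**), and fixed-dose
protocols with drug holidays (**FD Dose-Skipping**, **FD Intermittent**).
A run *progresses* when the rolling 500-h mean of total burden reaches 98%
of capacity or the doubly resistant count reaches 20% of capacity.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Python API — one replicate per arm at full scale takes ~1 s:

```python
import pandas as pd
from adaptherapy import SimulationConfig, run_replicates, cox_hazard_ratio

cfg = SimulationConfig()
_, st = run_replicates(cfg.with_protocol("ST"), 10, base_seed=0, arm="ST")
_, dm = run_replicates(cfg.with_protocol("DM_COCKTAIL"), 10, base_seed=100, arm="DM")
est = cox_hazard_ratio(pd.concat([st, dm]), reference="ST")
print(f"HR={est.hr:.2f} [{est.ci_low:.2f}-{est.ci_high:.2f}] p={est.p_value:.3g}")
```

```
HR=0.19 [0.06-0.55] p=0.00211
```

A hazard ratio below 1 means the dose-modulation arm progresses more slowly
than standard treatment — here, roughly a five-fold lower progression hazard
in a small 10-replicate pilot.

The CLI runs a whole experiment manifest and writes per-run time series,
the cohort survival table, hazard-ratio and drug-usage summaries:

```bash
cat > demo.yaml <<'YAML'
experiment: demo
replicates: 10
base_seed: 1
output_dir: demo_out
arms:
  - {label: ST, protocol: ST}
  - {label: DM Cocktail, protocol: DM_COCKTAIL}
YAML
adaptherapy run demo.yaml
adaptherapy analyze demo_out/survival.csv --reference ST
```

```
ST: n=10 events=10
  KM survival at last event time: 0.000
DM Cocktail: n=10 events=10
  KM survival at last event time: 0.000
DM Cocktail vs ST: HR=0.266 [0.100-0.707] p=0.00796
```

`adaptherapy presets` lists the named parameter presets (fitness-cost,
turnover, replacement, Delta-Tumor/Delta-Dose, vacation-threshold and
FD-stop-threshold grids) and the `figure4_defaults` six-arm manifest preset.

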