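# abtau

Simulator for an inflammation-driven network model of preclinical
Alzheimer's disease (AD).

PET scans of AD patients show spatial patterns of amyloid-β plaques and
tau tangles: some brains are amyloid-dominant, others tau-dominant.
`abtau` implements a mechanistic explanation: two reactive-oxygen-species
inflammation drivers — `R(x, y, t)` feeding intraneural amyloid-β and
`R̄(x, y, t)` feeding tau hyperphosphorylation — ramp up over years as
`R(x, y) · (t/γ)/(K + t)` and drive a seven-variable reaction network of
neurons (N), microglia (M), astrocytes (A), amyloid-β inside and outside
neurons (Aβi, Aβo), tau (τ) and neurofibrillary tangles
(F_i = 0.6 (τ − τ_ss)⁺).  The package is for modellers and
longitudinal-study planners who want to generate PET-like spatial
patterns from hypothesized inflammation maps, and to quantify, in
silico, how much an amyloid/tau-lowering drug delays the day a
trajectory reaches average-AD levels.

It provides:

* **Well-mixed (ODE) runs** of the network with a stiff adaptive solver,
  from healthy initial conditions, under any uniform ramped drivers;
* **2-D spatial (PDE) runs** adding diffusion and flux-limited
  microglial chemotaxis on rectangular or masked grids with no-flux
  boundaries, driven by seeded pixel-class inflammation maps
  (amyloid-biased / tau-biased / non-biased / zero pixels with exact
  class fractions);
* **Treatment scenarios** in which a drug multiplies three production
  terms by saturating factors `1/(1 + w D* s(t))`,
  `s(t) = (t−t₀)/(K_D + (t−t₀))`, and threshold-crossing analytics on a
  100-day imaging cadence;
* a **calibrated default parameter set**: production rates pinned
  exactly by the healthy equilibrium, remaining constants fitted once
  (scripts in `scripts/`) to published clinical anchor values and
  frozen.

## Worked example

Run the baseline disease scenario — uniform drivers at the reference
amplitudes R* = 1.85×10⁻⁶, R̄* = 4.13×10⁻¹⁰ g/(cm³·d), fast ramp
(K = 100 d), ten years — and read off the endpoint state:

```sh
abtau presets --name disease-baseline --out run.yaml
abtau run-ode run.yaml
```

```
final state at t=3650 d:
  abi = 1.977e-06 g/cm3
  abo = 6.668e-06 g/cm3
  tau = 4.812e-10 g/cm3
    M = 1.552e-02 g/cm3
    A = 3.973e-02 g/cm3
    N = 4.012e-02 g/cm3
wrote out/disease-baseline/trajectory.csv
```

Amyloid-β outside neurons has risen from its healthy 1.0×10⁻⁶ to
≈ 6.7×10⁻⁶ g/cm³ and tau from 1.37×10⁻¹⁰ to ≈ 4.8×10⁻¹⁰ g/cm³ — the
average clinical AD levels — while a third of the neurons
(6.00×10⁻² → 4.0×10⁻²) have died; microglia roughly double.  With both
drivers at zero the state stays at the healthy equilibrium
indefinitely.

The same model run in 2-D with a random non-biased inflammation map
(40% amyloid-biased, 40% tau-biased, 15% non-biased, 5% zero pixels):

```sh
abtau make-map --nx 10 --ny 10 --seed 0 --out map.csv
abtau run-pde <(abtau presets --name nonbiased-map-pde)   # or copy the preset
```

produces per-variable CSV snapshots whose Aβo and τ fields reproduce the
pixel layout — amyloid high where R is high, tau high where R̄ is high —
smoothed by diffusion; these are the PET-like patterns.  A treatment
run (`abtau run-treatment`, preset `treatment-early`) reports, for drug
start at day 2000 versus no drug, the days on which Aβo and τ cross
their average-AD thresholds and the delay the drug buys.

Library use mirrors the CLI:

```python
from abtau import (HealthReference, default_params, InflammationField,
                   integrate_ode, detect_crossing)

ref = HealthReference()
p = default_params(ref)
field = InflammationField.uniform(K=1000.0, gamma=1/1.4)  # slow ramp
traj = integrate_ode(p, ref, field, t_end=3650.0)
print(detect_crossing(traj, "abo", 6.70e-6, cadence=100.0))  # 2500.0
```

See `docs/methods.md` for the model equations, the calibration
procedure, numerical schemes and their validation, and known
limitations.

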