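# Methods

## The model

`abtau` simulates the preclinical progression of Alzheimer's disease as
a seven-variable reaction network over brain tissue.  The dynamical
variables, all densities in g/cm³, are neurons `N`, microglia `M`,
astrocytes `A`, amyloid-β inside neurons `Aβi`, amyloid-β in the
extraneural space `Aβo`, and tau `τ`; neurofibrillary tangles `F_i` are
algebraic, a fixed fraction of the tau excess over its healthy level:

    F_i = 0.6 (τ − τ_ss)⁺

The disease is driven by two inflammation (reactive-oxygen-species)
fields: `R` feeds intraneural amyloid production, `R̄` feeds tau
hyperphosphorylation.  Both ramp in time and vary in space:

    R(x, y, t) = R(x, y) · (t/γ)/(K + t)

with half-time `K` (100 d in the fast scenarios, 1000 d with
1/γ = 1.4 in the slow longitudinal ones).  The reaction network is:

    ∂Aβi/∂t − D_Aβi ∇²Aβi = [R + λ_Aβi − d_Aβi·Aβi] · N/N₀
    ∂Aβo/∂t − D_Aβo ∇²Aβo = λ_Aβo − λ_AβoN·(1/N)(∂N/∂t)·Aβi
                             − d_AβoM·M·Aβo − d_Aβo·Aβo + λ_AβoA·A·Aβo
    ∂τ/∂t − D_τ ∇²τ = [R̄ + λ_τ + λ_τAβi·(Aβi − Aβi_ss)⁺ − d_τ·τ] · N/N₀
    ∂M/∂t + δ_MAβo ∇·(M ∇Aβo/(K_∇Aβo + |∇Aβo|)) − D_M ∇²M
        = λ_M + M·(λ_MAβo·h(Aβo) + λ_MFi·g(F_i)) − d_M·M
    dA/dt = λ_A + λ_AM·M/(K_M + M)·A − d_A·A
    ∂N/∂t = −d_NFi·g(F_i)·N − d_NAβo·h(Aβo)·N

with the saturating activations h(Aβo) = (Aβo − Aβo_ss)⁺ / (K_Aβo +
(Aβo − Aβo_ss)⁺) and g(F_i) = F_i/(K_Fi + F_i).  The `N/N₀` factor on
the intraneural brackets is the bidomain-style homogenization: intra-
and extraneural space are co-located continua and intraneural kinetics
scale with the surviving neuron fraction.  Neuron death is first order
in `N`, so the necrosis-leak source of `Aβo` uses the relative death
rate `−(1/N) ∂N/∂t`, which is formed directly from the death terms —
well defined as `N → 0`, and never by numerical differentiation.

Modelling conventions adopted where the printed equations leave room:

* `F_i` is evaluated algebraically from `τ` (not integrated) and
  floored at zero — a tau deficit cannot produce negative tangles.
* The astrocytic term `λ_AβoA·A·Aβo` is implemented exactly as written
  (bilinear); the health calibration absorbs it into `λ_Aβo`.
* In the drug-modified equations each factor multiplies its own
  production term (necrosis leak with weight 1, astrocytic production
  with weight μ, amyloid-driven tau production with weight μ*); the
  printed grouping is ambiguous and this per-term multiplicative
  reading is the one implemented.

## Health calibration and parameters

The healthy state (N₀ = 6.00×10⁻², M₀ = 7.20×10⁻³, A₀ = 2.88×10⁻²,
Aβi_ss = Aβo_ss = 1.00×10⁻⁶, τ_ss = 1.37×10⁻¹⁰ g/cm³; protein values
converted from 1000 ng/g and 137 pg/ml at 1 g/cm³ tissue density) must
be an exact equilibrium when `R = R̄ = 0`.  That pins all five
zeroth-order production rates (`calibrate_health_fixed_point`), e.g.
`λ_Aβi = d_Aβi·Aβi_ss` and `λ_Aβo = (d_AβoM·M₀ + d_Aβo −
λ_AβoA·A₀)·Aβo_ss`; a parameter set in which an implied production rate
would be negative is rejected as inconsistent.

The clearance, coupling and saturation constants are not fixed by the
clinical anchor values.  The shipped defaults were calibrated once
(`scripts/fit_defaults.py`, refined by `scripts/polish_crossing.py`)
by weighted least squares against the published well-mixed outcomes:
the 3650-day endpoints of the three disease scenarios
(R*, R̄*) = (1.85×10⁻⁶, 4.13×10⁻¹⁰) g/(cm³·d) and its 1.5×/0.5×
biased variants, the zero-inflammation run, the slow-ramp trajectory
checkpoints at 2000/2300/2500/3600 d, and the slow-ramp longitudinal
average series approximated by its pixel-class mixture (the
zero-diffusion limit of the domain average).  Endpoint residuals at the
optimum are below 1% per variable.  Two structural constraints are part
of the calibration:

* **Local stability of health.**  For plausible constants the
  necrosis-leak feedback (`λ_AβoN · d_NAβo/K_Aβo · Aβi_ss` against net
  amyloid clearance) can make the healthy equilibrium linearly
  unstable, in which case rounding noise grows and an uninflamed brain
  would drift into disease.  The fit constrains the largest real
  eigenvalue of the one-sided Jacobian at health (neuron direction
  excluded — it is neutrally stable by construction) to be negative.
* **Crossing-day edges.**  The untreated slow-ramp trajectory reaches
  the AD-average thresholds (6.70×10⁻⁶, 4.90×10⁻¹⁰) at the 2500-day
  imaging visit and not at the 2400-day one; these are one-sided
  penalty terms, since a symmetric fit can land a fraction of a percent
  on the wrong side of the knife edge.

Constants the clinical anchor arithmetic does not constrain at all —
diffusivities and chemotaxis — are package defaults chosen for the
stated regime rather than fitted: `D_Aβo = D_M = 10⁻⁶`,
`D_Aβi = D_τ = 10⁻⁷` cm²/d keep diffusion lengths over 500 d
(≈ 0.04–0.14 cm) at or below the default 0.1 cm pixel size so spatial
patterns retain pixel contrast, and `δ_MAβo = 10⁻⁴` cm/d with
`K_∇Aβo = 10⁻⁵` g/cm⁴ (the typical inter-pixel gradient) gives
flux-limited microglial drift of a few pixel widths over a simulated
decade.  All constants can be overridden from a delimited parameter
table (`load_param_table`), after which production rates are
re-derived and the equilibrium re-verified.

The drug regimen defaults (D* = dose, K_D = effect saturation time, μ,
μ* = term weights) were fitted once (`scripts/fit_drug.py`) so that on
the 100-day cadence the treated runs starting at 2000 d cross the
amyloid/tau thresholds at 3100/2900 d and at 2300 d cross at
2800/2700 d, using continuously interpolated crossing times aimed at
cadence-bin midpoints (grid crossing days are step functions of the
parameters and cannot be differentiated through).

## Numerics

**Well-mixed runs** use `scipy.integrate.solve_ivp` (LSODA) at relative
tolerance 10⁻⁹ with per-variable absolute tolerances scaled from the
health state (the state spans eight orders of magnitude).  Treated runs
are split at the treatment start so the solver never steps over the
kink in the drug factors.  Halving the tolerances moves 3650-day
endpoints by far less than 0.1%.

**Spatial runs** use a cell-centered grid (default: unit square,
50×50; the published experiments state neither domain size nor
resolution, so both are configurable) with no-flux boundaries and IMEX
operator splitting per step: a two-stage explicit (Heun) update of
reactions plus upwinded flux-limited chemotaxis, then backward-Euler
diffusion of the four mobile species with cached sparse LU
factorizations.  The face-centered chemotactic speed is
`δ·∂Aβo/∂n / (K_∇ + |∇Aβo|)`, bounded by `δ` for arbitrarily steep
gradients; microglia are donor-cell upwinded, and boundary/mask faces
carry zero flux, so both transport operators conserve mass to solver
precision.  The step size obeys an advective CFL bound (0.5·h/δ) and is
halved automatically (with a logged report) if an explicit stage would
produce a negative density — clamping is never used.  Masked domains
treat mask edges exactly like the outer boundary, and averages use
active cells only.  Correctness is anchored to the well-mixed oracle:
with spatially uniform drivers every grid cell reproduces the ODE
trajectory (the transport operators are inert), to within 0.5% at the
default Δt = 0.25 d.  The numerical scheme behind the reference results is not publicly
documented; this scheme is the package's own, validated by that
equivalence and by mass-conservation and refinement checks.

**Inflammation maps** place an exact largest-remainder multiset of
pixel classes (amyloid-biased 1.5R*/0.5R̄*, tau-biased 0.5R*/1.5R̄*,
non-biased, zero) by a seeded permutation, so realized class fractions
never drift from the requested ones and a seed fully determines the
map.  Map pixels expand to blocks of grid cells (default 10×10 map,
5×5-cell blocks), decoupling map from solver resolution.

## What the simulated scenarios do and do not show

The longitudinal average series is a stochastic target: only class
fractions are published, not the arrangement, so comparisons average
over several map seeds; with the default weak diffusion the domain
average sits within a fraction of a percent of the seed-independent
pixel-class mixture, which is why seed-to-seed scatter is small.
Diffusion raises that average by up to +0.2–0.3% above the mixture at
early times (chemotaxis contributes about −0.03%; with all transport
off the spatial solution equals the per-cell ODE to round-off), a
measured offset the calibration's band margins account for.  The
model reproduces the published endpoint tables by construction of its
calibration, so agreement there validates the calibration machinery,
not the biology; the untouched degrees of freedom are the trajectory
shapes between anchors and all spatial structure.  Real PET data enter
nowhere: inflammation maps are synthetic pixel layouts, not inferred
from images, and the model says nothing about plaque/tangle formation
mechanisms.

One printed robustness remark does not carry over exactly: raising the
fast-ramp half-time K from 100 to 500/1000 d lowers the ramp multiplier
at 3650 d from 0.973 to 0.880/0.785, and because the kinetics are
linear in the drivers the protein endpoint excesses shift by up to
the same proportion (about 5–10%), not by <2%.  The package implements
the equations as printed and asserts the honest version (endpoint
shifts bounded by the driver shift, early-time profiles differ).

## Default problem sizes

Shipped analyses use the published scenario horizons (3650/3600 d), a
50×50 grid for spatial runs, 10-day trajectory sampling, 100-day
imaging cadence for crossing detection, Δt = 0.25 d (0.5 d for the
decade-long longitudinal runs) and three map seeds for seed-averaged
spatial summaries.
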