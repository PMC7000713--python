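# Methods

## Size-spectrum model

All predictions derive from truncated power-law size spectra. A plant
assemblage is summarised by the stem-radius density `f(r) = c_n r^(-η)` on
`(0, r_max]` with the individual-mass allometry `m(r) = c_m r^(8/3)`; an
animal trophic level by the mass density `f(m) = c_a m^(-ε)` on `(0, m_max]`.
Totals are integrals of a per-individual quantity against the spectrum:

| total | integrand | closed form (lower cutoff → 0) |
|---|---|---|
| plant biomass | `m(r) f(r)` | `(3/5) c_n c_m r_max^(5/3)` |
| animal biomass | `m f(m)` | `(4/5) c_a m_max^(5/4)` |
| plant flux | `τ κ_i⁻¹ B_0 r² f(r)` | `τ κ_i⁻¹ B_0 c_n r_max` |
| animal flux | `τ κ_i⁻¹ B_0 ×` biomass | `∝ m_max^(5/4)` |

NPP is related back to standing biomass by
`NPP = b_0 c_m^(8/5) c_n^(2/5) (5/3 M_Tot)^(3/5)`; composed with the biomass
closed form this is linear in `r_max`, consistent with the direct flux
integral — an internal consistency check the tests assert.

Two conventions were genuinely open and are fixed as follows:

- **One mass constant.** The tree-mass allometry is written `m = c_m r^(8/3)`
  with a single multiplicative constant (the literature sometimes raises the
  constant to the 8/3 as well). Every testable quantity — ratios and
  exponents — is invariant to this choice; the closed-form coefficients above
  are stated in this convention.
- **Lower cutoffs.** Spectra carry strictly positive lower limits
  (`r_min`, `m_min`); the closed forms are the limit of the integral as the
  lower limit → 0, which exists because every integrand above is integrable
  at 0. The quadrature branch (scipy.integrate.quad over the finite range) is
  the general path for non-canonical exponents and the cross-check for the
  closed forms: with lower limit = 1e-6 × upper the two agree to relative
  1e-4, asserted in tests.

Flux constants `τ, κ_i, B_0, b_0` are not pinned by any ratio prediction, so
they default to 1; all reported fold-changes and exponents are independent of
them.

**Extinction risk.** Risk compounds three allometries — mortality under
extreme events (`m^b`), inverse fecundity (`m^c`), and minimum viable area
(`m^d`) — into `E_λ ∝ m^(b+c+d)`. The component magnitudes (b ~ 1, c ~ 0.25,
d ~ 1) sum to 2.25, while the widely quoted rule of thumb uses 2.5 ("10× the
mass, ~316× the risk"). The default `ExtinctionScaling` carries
`composite_override = 2.5` so the headline number is reproduced exactly;
setting the override to `None` uses the component sum, making the tension
between the two explicit rather than hidden.

**Metabolic rate.** `B = N m^(3/4) × exp(E/k (1/310 − 1/T))`, a mass power
law times a Boltzmann–Arrhenius factor normalised to 1 at 310 K. `N` is the
field normalization when active, basal when inactive; endotherms evaluate the
temperature factor at their regulated body temperature (default 310 K)
regardless of ambient, ectotherms at ambient. The activation parameter `E/k`
is in Kelvin and defaults to 0 (temperature-neutral), since only
rate *ratios* enter any prediction here.

## Power-law fitting

Exponents are estimated by linear fits on natural-log axes. Ordinary least
squares is the default; standardized major axis
(slope = sign(r) · sd(log y)/sd(log x)) is provided for data with error in
both variables, and the two coincide on noiseless power laws. Confidence
intervals: analytic t-based (Warton's interval for SMA), or nonparametric
case-resampling bootstrap (2000 replicates, percentile method, seed
required). The fitted exponent is invariant to the log base and to separate
rescalings of x and y; both invariances are tested.

## Nutrient diffusivity and downsizing scenarios

Per-cohort lateral diffusivity is `ϕ(m) = k m^1.17` (km² yr⁻¹): the exponent
compounds day-range, gut-passage and intake allometries of large herbivores.
The community aggregate is a **density-weighted linear sum**
`Φ = Σ (d_i / d_ref) ϕ(m_i)` with reference density 1 km⁻². This aggregation
rule is a modelling choice of this package: the per-cohort allometry does not
dictate one, and a linear sum preserves the 1.17 exponent within cohorts,
makes Φ homogeneous of degree 1 in densities, and renders calibration
well-posed — `k` is rescaled in closed form so the reference community
reproduces Φ = 4.4 km² yr⁻¹, the documented community value for a full
Pleistocene-like South American fauna. Downsizing is expressed as size
thresholds: threshold T removes every cohort with mass > T, so Φ is
nonincreasing as T decreases, reaching 0 below the smallest cohort.

## Diffusion–loss steady state

Soil-nutrient redistribution is `∂P/∂t = ∇·(Φ∇P) − λP` on a regular grid
(cell-centred, row-major, dx in km), with P fixed at the source concentration
on floodplain cells (Dirichlet) and no-flux faces at land/non-land and outer
boundaries. The first-order loss λ is the minimal sink that gives a
nonuniform steady state with an analytic oracle; its default 4.4e-6 yr⁻¹ is
chosen so the decay length `√(Φ/λ)` is ~1000 km at Φ = 4.4 km² yr⁻¹ —
basin-scale fertility gradients. Fertility outcomes are summarised as the
mean concentration over non-source land cells, as a percent of the
full-fauna baseline.

Discretisation is 5-point finite differences with face diffusivities the
arithmetic mean of adjacent cells. Two solvers share it:

- **direct** (default): sparse linear solve of the steady-state system —
  deterministic, exact for the discretisation, used in experiment sweeps;
- **explicit**: forward-Euler with `dt = 0.2 dx²/max(Φ)` (capped at 0.2/λ),
  inside the stability bound; a user-supplied dt beyond the bound is
  rejected. Convergence is declared when the maximum per-step change,
  measured relative to the source concentration (a fixed scale, avoiding 0/0
  on cells still near zero), drops below the tolerance (default 1e-7).

The two agree to <1e-6 on the test fixture. Verification: the 1-D strip
steady state matches `P₀ exp(−x√(λ/Φ))` to <1% at dx = 0.1 decay lengths
(and is O(dx²) against the exact finite-strip cosh solution); pure diffusion
with no source conserves the spatial sum to relative 1e-8; the maximum
principle (0 ≤ P ≤ P₀ on land) is asserted on every solver run. Advection
(directional transport) is deliberately not modelled.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume; they are the package's study conditions, not tuning knobs.

- **Forest plots** (the scaling-regression fixture): per plot, `r_max` is
  drawn log-uniformly (even leverage across decades of largest-tree mass),
  2500 stem radii are drawn from the truncated `r^(-2)` spectrum by analytic
  inverse-CDF sampling, masses follow `c_m r^(8/3)`, and the plot total gets
  multiplicative lognormal noise (sd 0.2 on natural logs) — the residual
  structure of log–log biomass regressions. The noisy total is floored at
  the largest stem mass so records satisfy `m_tot ≥ m_max`. Defaults
  (200 plots; radii 0.01 m to a per-plot maximum in 0.1–1.5 m;
  c_m = 8000 kg m^(-8/3)) emulate a few-hundred-plot compilation spanning
  ~3 decades of largest-tree mass, sized so the finite-stem sampling noise in
  the per-plot maximum does not bias the fitted exponent.
- **Animal communities**: deterministic log-spaced cohort masses with
  densities ∝ m^(-3/4) (energetic equivalence), normalised to a total of
  25 individuals km⁻². The "Pleistocene-like" fixture spans 10–10,000 kg in
  16 cohorts; it is explicitly synthetic — no real species list is asserted.
- **Basin grid**: an all-land 60 × 40 rectangle at dx = 50 km
  (3000 × 2000 km, basin order of magnitude) with a western-edge or interior
  source band standing in for a river floodplain.

What passing tests show — and do not. The generators realise the theory's own
assumptions plus idealised noise, so the test suite demonstrates *internal*
consistency and correct parameter recovery: e.g. the synthetic-plot
regression recovers the 5/8 biomass exponent within ±0.05 with ≥90% CI
coverage over 50 seeds. They do not emulate real geography, species lists,
measurement error structure, or deviations from power-law spectra; the
empirical exponent from real plot compilations (0.62, CI 0.58–0.66) and
quantitative fertility-reduction bands (20–40% basin-wide, ~10% at a 5000 kg
threshold) depend on real data and constants outside this package and are
reproduced only qualitatively (monotone decline, correct endpoints).

## Problem sizes and determinism

Default experiment sizes (200 plots × 2500 stems; 60 × 40 grid; 16 cohorts;
2000 bootstrap replicates) run the full pipeline in seconds on one CPU. All
randomness flows from a single integer seed through numpy Generators;
identical seeds give byte-identical output tables, and the diffusion solvers
are seed-free and bit-deterministic.
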