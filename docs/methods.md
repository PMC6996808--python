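# Methods

This note records the modelling choices behind `lencom`: the update
rules, the defaults and their units, where the design was genuinely
open and what was decided, and what the synthetic test communities do
and do not show about real systems.

## State, grid, and time

The state is a matrix *N*ⱼᵢ of numbers of individuals per length class
*j* and species *i* on one shared grid of half-open classes
[lⱼ, uⱼ) in cm.  By default the grid has 32 equal-width classes
spanning (0, max *L*∞].  A fish "in class *j*" is treated as having
the midpoint length, and the midpoint weight *w* = *W*ₐ·mid^*W*ᵦ in
grams, for every weight-based quantity (SSB, suitability, catch
weight).  This single convention keeps all the derived structures
mutually consistent; it slightly coarsens quantities that vary
strongly within a class, which is the usual price of a length-binned
model.

The time step `phi_min` is interpreted directly as *δt* in years
(default 0.1, i.e. 10 steps per year), rather than being re-derived
from the fastest growth transition.  Growth proportions
φ = *δt*/transit are capped at 1 with a warning when a species could
traverse a class in less than one step; the remedy is a finer grid or
a smaller *δt*, and the cap only biases very fast-growing species on
coarse grids.  Keeping *δt* fixed makes steps-per-year integral and
runs comparable across parameterisations.

## Growth

Transit times follow von Bertalanffy growth d*L*/d*t* = *k*(*L*∞ − *L*):
*t*ⱼᵢ = (1/*k*ᵢ) ln((*L*∞ᵢ − lⱼ)/(*L*∞ᵢ − uⱼ)).  A class whose upper
bound reaches *L*∞ cannot be traversed, so its φ is 0 and it acts as
the species' terminal plus-class.  A species whose *L*∞ falls inside
the first class cannot grow on the grid at all and is rejected at
validation.

## Recruitment

Recruitment is annual: recruits computed from the spawning-stock
biomass at the start of the year enter the first length class at the
year's first step.  Start-of-year SSB is the only unambiguous snapshot
once recruitment, mortality, and growth all act within the year; using
it also makes one simulated year exactly reproducible by chaining the
public step functions, which the test suite exploits.  Five
stock–recruitment families are provided (hockey-stick, Ricker,
Beverton–Holt, linear, constant), all parameterised as *R* in numbers
against SSB in grams.

## Mortality and catch accounting

Total mortality *Z* = *M1* + *M2* + *F* (all yr⁻¹) acts as exponential
survival over *δt*.  Deaths are partitioned by the Baranov shares: gear
*k* receives fraction *F*ₖ/*Z* of deaths in each cell, the remainder
being natural.  The partition sums to the total deaths exactly (to
floating-point), which the suite asserts at 1e-10.

Background mortality families:

- `constant` — one rate everywhere (units yr⁻¹);
- `linear` — declines linearly in midpoint length from a juvenile rate
  at length 0 to 0 at *L*∞;
- `std_RNM` (default; rate 0.8 yr⁻¹, cutoff 0.75) — a capped-constant
  residual natural mortality: the rate applies to classes with midpoint
  at most the cutoff fraction of *L*∞ and is 0 above.  Both knobs are
  exposed per species.  This is the simplest testable realisation of a
  residual-mortality schedule that spares the largest fish; note that a
  species with no predators and no fishing then has *no* mortality in
  its top classes, so communities meant to equilibrate unfished should
  either carry predators for every species or use one of the other two
  families (the bundled generator does the latter).

## Predation mortality

Predation follows a rations argument.  Each predator class needs

  *I*ₙₘ = (per-step weight increment) / *g*eff grams per step,

where the increment is φₙₘ·(wₙ₊₁,ₘ − wₙₘ) (the expected gain from
advancing a class) and the conversion efficiency declines linearly
from *g*₀ at length zero to 0 at *L*∞: *g*eff = *g*₀(1 − *w*/*w*∞).
Classes that cannot grow demand nothing.  The demand is spread over
the predator's available food — suitable prey biomass plus the fixed
"other food" pool — so each prey cell receives the per-capita rate

  *M2*ⱼᵢ = Σₘₙ *I*ₙₘ *N*ₙₘ suitₘₙᵢⱼ / (other + Σ suitₘₙ·· *N*·· *w*··)

converted to yr⁻¹.  A predator whose available food is zero contributes
nothing (guarded division).  Suitability is
τₘᵢ · exp(−(ln(*w*pred/*w*prey) − ln μ)²/(2σ²)), zeroed when the prey
weighs at least as much as the predator; it depends on weights only
through their ratio.  The kernel uses natural logarithms and is not
otherwise truncated; the predator–prey mass ratio μ = 30, width σ = 1,
and efficiency *g*₀ = 0.5 are species-independent defaults of the
conventional size-spectrum magnitude, all configurable.  The whole
term sits behind one function (`calc_M2`) so an alternative ration or
denominator convention can be swapped in without touching the engine.

Consequences worth knowing: *M2* scales inversely with the other-food
pool, so "other" is the single most effective dial for overall
predation intensity; and because rations derive from growth demand,
predators that have stopped growing exert no predation pressure —
a deliberate simplification (no maintenance ration).

## Fishing

Catchability curves per species × gear — logistic(η, L50),
log-Gaussian(Lμ, σ), knife-edge(Lmin) — are evaluated at class
midpoints, zeroed on classes the species can never occupy, and
rescaled to unit maximum.  Gear effort is therefore the fishing
mortality (yr⁻¹) on the most-selected class, which makes effort
directly comparable across gears and parameterisations; a raw
catchability array is accepted verbatim for users who want their own
scaling.  Effort is piecewise-constant within a year (one row per year
per gear).  Knife-edge gears model retention above a minimum landing
size with discards surviving: fish below the edge take no fishing
mortality at all.

## Initialisation

`get_N0` seeds each species and then burns in (default 10 years,
unfished).  The seed is the exact fixed point of the engine's own
linearised year map: for fixed per-cell mortality the year update is a
linear operator (10 × growth∘survival plus the recruitment pulse), and
the steady state solves a small linear system per species.  Mortality
in the seed is background plus a predation field evaluated at the
current seed, iterated twice, and floored at 0.2 yr⁻¹ so terminal
classes stay finite.  Starting at this fixed point rather than an
ad-hoc profile means the burn-in only absorbs the nonlinear predation
residual: on the bundled 21-species community a second 10-year
unfished run changes every species' SSB by ~3 × 10⁻⁵ relative, and the
choice of floor is immaterial to the post-burn-in state.

## Indicators

All indicators are computed per step, with optional annual averaging
(steps assigned to the year they fall in).  LFI is the community
biomass fraction in classes with midpoint above a threshold (40 cm
conventionally).  MML is the biomass-weighted mean of species' *L*∞.
TyL is the biomass-weighted geometric mean of class midpoints,
aggregated at class level (species enter only through their biomass
per class).  Length quantiles interpolate linearly within the crossing
class, giving continuous series; LQ(1) is the top occupied class's
upper bound.  CPUE is CPG/effort and is reported as NaN — undefined,
not zero — where effort is zero.

## Reference points

Long-term yield is operationalised as the mean annual catch over the
final `avg_years` of a `years`-long constant-F run from a common
burnt-in state; the package defaults are 10 of 50, and analyses on
small exploratory communities (as in the test suite) scale both down
together (5 of 20), which is past the settling time of those
communities.  F enters through one unit-normalised logistic gear per
species (L50 at maturity length, steepness matching the maturity
ogive), so the F axis is effort.

`calc_fmsy` scans a grid (default 0–2 yr⁻¹ step 0.1) and refines
between the best point's neighbours with a bounded scalar minimiser
(tolerance 0.005 yr⁻¹); flat profiles return the smallest maximiser
with a warning.  `calc_nash` iterates best responses species-by-species
until a full sweep moves no component by more than 0.01 yr⁻¹ (at most
50 sweeps, non-convergence flagged).  Best-response iteration
implements the equilibrium definition directly; it finds one
equilibrium, and like any such scheme it is not guaranteed to converge
in principle — on size-ordered predation topologies it settles in a
few sweeps because dependence is nearly triangular.  The tolerances
were chosen to resolve F to well under typical between-species
differences at reasonable cost.

Scenario grids run the full factorial of per-fleet effort levels for a
fixed horizon from one initial state.  Collapse is judged on the mean
SSB of the final simulated year (removing within-year spawning phase
effects) against the zero-effort reference run of the same length:
collapsed ⇔ SSB < 10% of unfished SSB, strictly.

## The synthetic communities

The bundled generator draws a 21-species community spanning 15–130 cm
*L*∞ (log-uniform), with maturity at 50–60% of *L*∞, growth rate
declining with size (*k* ≈ 10·*L*∞⁻⁰·⁸), near-cubic length–weight,
hockey-stick recruitment (slope 50/*w*∞ recruits per gram, breakpoint
10³·*w*∞ grams), a constant residual mortality of 0.5 yr⁻¹, a sparse
size-ordered interaction matrix (predators at least twice the prey's
*L*∞), four fleets partitioning the species by size guild, and an
other-food pool of 10⁹ g that keeps peak predation mortality near
0.4 yr⁻¹.  These magnitudes were chosen once to give a persistent,
equilibrating community with forage-fish-realistic predation pressure;
the manifest written alongside every fixture states that the values
are synthetic regularities, not calibrated estimates.

What passing tests on these communities show: the update rules
conserve what they must, the vectorised predation term matches its
definition, reference-point machinery finds genuine fixed points, and
the pipeline is deterministic end to end.  What they do not show:
realism of any particular North Sea quantity.  Real communities have
interaction matrices estimated from diet data, recruitment parameters
tuned to surveys, and non-stationary environments; none of that is
emulated.  The three-species chain used in the reference-point tests
is likewise a topology for exercising the mathematics, not an
ecosystem.

## Numerical notes and limitations

- The engine contains no randomness; identical configurations give
  bit-identical runs.  Seeds appear only in the fixture generator.
- Logistic ogives never reach exactly 0 or 1; tests and users needing
  a hard cutoff should use large steepness (the ogive underflows to
  exactly 0/1 beyond ~±40 logits).
- Degenerate inputs are rejected at construction (non-increasing
  bounds, *L*∞ ≤ *L*mat, negative rates, τ outside [0,1], effort
  column mismatches), not at run time.
- Catch in the output is recorded in grams per step per class, species
  and gear; death accounting is exact, so summed catch plus natural
  deaths reconstructs the mortality field.
- Food-dependent growth, stochastic recruitment, and within-year
  seasonality are out of scope; growth depends only on *k* and the
  grid, so strong prey depletion does not slow predator growth.
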