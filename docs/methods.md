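# Methods

This note documents the models, the synthetic study conditions, the numerical
choices, and the limitations of `coliastherm`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Heat budget

A basking butterfly's thorax is modelled as a single lumped node: a
horizontal cylinder (default D = 3.6 mm, L = 10 mm) whose ventral wing
surfaces deliver absorbed shortwave flux to the body. The steady state solves

Q_solar − Q_conv − Q_rad = 0, with

* Q_solar = α · S · a_proj · A, where α is wing solar absorptivity, S the
  total horizontal flux (W/m²), A = πDL, and a_proj the projected-area
  fraction. For the direct beam (lateral basking posture) a_proj = 0.25; for
  beam-blocked, diffuse-only conditions (tents) a smaller interception factor
  0.125 is used, reflecting the lower mean projection of a cylinder under an
  isotropic field partly shaded by the ground plane.
* Q_conv = h_tot · A · (T_b − T_air), with the setal layer and the boundary
  layer in series: 1/h_tot = 1/h_c + d_setae/k_fur, k_fur = 0.025 W/m/K,
  h_c = 0.6 · Re^0.5 · k_air/D, Re = uD/ν. Wind is floored at 0.1 m/s; free
  convection is not modelled.
* Q_rad = εσA(T_b⁴ − T_rad⁴) in kelvin, ε = 0.95. T_rad is a view-factor mix
  of sky and ground: T_rad = w·T_sky + (1−w)·T_soil with w = 0.5 and T_soil
  the measured shallow-soil temperature.

**Sky radiant temperature.** The clear-sky radiant sink is modelled as
T_sky = T_air − 15 K · (S / 1000 W m⁻²): the depression scales linearly with
insolation rather than switching on at S > 0. This keeps the equilibrium
identity exact at night (S = 0, radiant temperatures equal to air ⇒
T_b = T_air) and keeps T_b effectively linear in S over the working range —
a step-function sky would put a ~2 °C discontinuity at S → 0⁺ and break the
near-proportionality of body temperature to radiative forcing that the model
family is built on. At full clear-sky flux the depression is the
conventional 15 K.

**Solver.** Q_net is strictly decreasing in T_b, so the root is found by 64
vectorised bisection steps on [T_air − 20, T_air + 40] °C (residuals far
below 10⁻⁶ W). A missing sign change raises a domain error reporting the
bracket residuals. The solver broadcasts over individuals × checks, which is
what makes whole-trial simulation cheap; a scalar Brent solve on the same
balance is the independent cross-check in the tests.

**Transient variant and time constant.** C·dT_b/dt = Q_net is integrated
with explicit ≤1 s steps, the environment held piecewise-constant per
minute. The lumped heat capacity C = 0.07 J/K was set so that the linearised
time constant τ = C/(A(h_tot + 4εσT³)) is ≈30 s at 1 m/s wind, consistent
with the sub-minute thermal response times reported for these butterflies;
the acceptance suite verifies τ < 60 s and that the closed form agrees with
a log-linear fit of the simulated relaxation within 10%. The main pipeline
uses the steady-state model only.

## 2. Flight-initiation hazard

Spontaneous initiation mixes capability and motivation. At each check
(every 2 min in cages, 1 min in tents) a not-yet-flown individual initiates
with probability q(T) = p_mot · Φ((T − μ)/σ_T); σ_T = 0 degenerates to a
sharp threshold. The hazard is re-evaluated each check (rather than drawing
one fixed threshold per individual), which makes the likelihood of a record
table exact:

log L = Σ_fliers [ Σ_{k<k*} log(1−q_k) + log q_{k*} ] + Σ_non-fliers Σ_k log(1−q_k).

A fixed-threshold simulator variant is available behind a flag for
sensitivity analysis. Fitting maximises log L over box constraints
(L-BFGS-B from the best point of a coarse grid); CIs are percentile
bootstrap over case resamples, each refit starting from the point estimate.

**Identifiability.** Under a single slow warming ramp, (μ, p_mot) lie on a
likelihood ridge — many (higher threshold, higher motivation) pairs fit
almost equally well — and the threshold estimate's replicate SD is
~0.25–0.35 °C at n = 500. Designs whose trajectories cover the threshold
region at distinct dwell patterns (several warming rates, or cohorts held at
constant temperatures spanning μ ± 3 °C) break the ridge; the recovery test
uses the constant-temperature design and reaches ~0.14 °C SD at n = 500.
This is a genuine caveat for fitting single-morning field data.

## 3. Synthetic micrometeorology

No trial-day meteorology is available to replay, so the generator produces
scenario days rather than reconstructions, at the logger's 1-min cadence:

* air temperature: piecewise cosine with minimum t_min at sunrise, maximum
  t_max two hours after the photoperiod midpoint, cosine decay overnight;
* solar: clear-sky half-sine envelope peaking at s_max, multiplied by an
  AR(1) cloud factor in [1−cloud_depth, 1] (per-minute autocorrelation 0.97);
* wind: i.i.d. log-normal around the site median;
* shallow-soil temperature: air plus a sun-driven excess (12 K per
  1000 W/m²) smoothed with a 45-min exponential lag;
* a whole-day temperature offset (SD 1.5 °C) applied per simulated day,
  shared across sites, to emulate between-day weather.

Default sites: low-elevation valley floor at 1600 m (t_min 15, t_max 33 °C,
s_max 1000 W/m², July photoperiod), a garden site at 1500 m (+0.7 °C), and a
subalpine mesa at 3300 m derived from the low site by a −6.5 K/km lapse with
s_max 1100 W/m² and breezier, cloudier conditions. Enclosures: screen cages
attenuate solar by 15% (upper bound of the field measurement) and wind by
20%; nylon tents attenuate solar by 65% (field mean), block the direct beam,
and cut wind to 10% (no published number; design default).

What the generator does **not** emulate: humidity, topographic shading,
realistic cloud fields, within-day synoptic changes, or any correlation
between wind and radiation. Passing tests therefore demonstrate internal
consistency of the pipeline under plausible forcing, not predictive skill
for any particular field day.

## 4. Experiments

* **Reciprocal transplant** (full sun): day × site × species factorial;
  each cell samples n morphologies from truncated-normal trait distributions
  (meadii 69.1 ± 3.3% absorptivity, 1.27 ± 0.23 mm setae; eriphyle
  51.8 ± 7.0%, 0.63 ± 0.18 mm), generates the day's microclimate, applies
  the cage, and simulates 2-min checks driven by the predicted body
  temperature of the 6-min mean environment before each check (partial
  windows near the record start use the available minutes).
* **Common garden** (no direct sun): one tent day per simulated day; the
  driving channel is the equilibrium temperature of a reference mimic (a
  yellow-painted epoxy model: absorptivity 0.5, no setae) under the tent's
  attenuated diffuse flux, and both species are simulated on that *same*
  trajectory with 1-min checks — morphology is recorded but cannot affect
  the driving temperature, isolating thermal sensitivity by construction.

Group summaries report the initiation proportion over all individuals and
time/temperature means over fliers only, each with 2000-replicate percentile
bootstrap CIs. The decomposition divides the no-sun initiation-time
advantage by the full-sun advantage; results are reported at full precision
and rounded to the nearest 5 percentage points (physiology rounded, the
complement taken for morphology so the pair sums to exactly 100).

## 5. Calibration of defaults

Trait distributions, the tent/cage solar attenuations, and the 0.8 °C
species offset in threshold mean (μ = 24.7 °C for the high-elevation
species, 25.5 °C for the low) are measured quantities. The remaining hazard
parameters are **calibration, not measurement**: σ_T = 1.0 °C and
p_mot = 0.3 were fixed, once, so that the pooled flier mean predicted
basking temperature at initiation in the default transplant simulation lands
inside the observed 24–26 °C field band while preserving the qualitative
site pattern (high-elevation species initiating at ~80% at the cold site,
low-elevation species at a few percent). The `defaults` CLI command prints
every default with its provenance tag. Because initiation under a hazard
accumulates below μ, the mean initiation temperature sits below the
threshold mean; this is why μ is not itself inside the band.

## 6. Determinism and problem sizes

Every random stream descends from a single master seed through
`numpy.random.SeedSequence(master, spawn_key=(stage, day, site, species))`,
with species keyed by position so that relabelling identically parameterised
species exchanges outcomes exactly. Full pipelines are bit-reproducible for
a fixed seed. Default analysis sizes — 200 individuals per cell, 2 transplant
days, 5 garden days, 2000 bootstrap replicates — give Monte-Carlo error
comfortably below the effects of interest (the garden offset is recovered to
±0.05 °C across seeds) while keeping a full acceptance run to a few seconds.

## 7. Known limitations

* Single lumped node: no separate wing/head temperatures, no behavioural
  posture adjustment, no evaporative or metabolic terms.
* The diffuse interception factor and tent wind factor are unmeasured design
  defaults; the decomposition's absolute Δt values depend on them, though
  the 15/85 worked example depends only on the published advantages.
* The hazard treats motivation as temperature-independent and memoryless;
  the μ/p_mot ridge above is the statistical face of that assumption.
* Mixed-effects inference on real field tables is out of scope; summaries
  use bootstrap CIs instead.
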