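# Methods

## Scope and design

`cwddat` simulates the decomposition of coarse woody debris (CWD) as a
deterministic daily process driven by climate, wood properties and four
decomposer guilds, and packages the surrounding workflow: climate forcing
(read or synthesised), decay-curve fitting with half-lives, performance
metrics, and two ready-made scenarios (a 30-year post-hurricane watershed
cohort and 6-year experimental-log deployments at nine study sites). The
guild kinetics are a transparent re-design rather than a port of any
existing simulator's internal equations: multiplicative first-order rates
with documented response functions, constrained by calibration to the
published outcomes of the post-hurricane application (see *Calibration*).

## Substrate representation

A simulation tracks independent sub-cohorts. In **cohort mode** a
watershed inventory (Mg ha⁻¹ by position × species group × size class) is
expanded into up to 24 sub-cohorts using size-class midpoint diameters
(class 3 → 18.75 cm); masses convert to areal carbon via
1 Mg ha⁻¹ = 100 g m⁻² and a wood carbon fraction (default 0.492, so the
130 Mg ha⁻¹ application cohort is ≈ 6,396 g C m⁻²). In **log mode** each
log is a sub-cohort with its measured diameter and kg-scale mass. Size
classes are half-open intervals [lower, upper): the class bounds repeat
boundary values, and half-open intervals resolve the tie
deterministically (7.5 cm belongs to class 2).

Two field estimates of log mass loss serve as comparison bases:
*measured* loss (whole-log field weight corrected to dry weight with disk
moisture) and *calculated* loss (disk wood-density change, which with
constant volume reduces to 1 − ρ_T6/ρ_T0). Both are clamped to [0, 1]
with a logged warning, since field data can produce small apparent gains.

## Climate forcing and activity modifiers

Daily forcing is (tmin, tmax, precipitation). The reader validates
schema, ordering and tmin ≤ tmax, and linearly interpolates isolated
missing days (more than 5% missing is an error). The synthetic generator
produces daily mean temperature as MAT + seasonal sinusoid + AR(1) noise
(ρ = 0.7, σ = 2 °C), with the seasonal amplitude from a latitude
heuristic, clip(3 + 0.25·|lat|, 4, 16) °C — about 10–12 °C at
mid-latitudes; precipitation is a Bernoulli wet-day process (p = 0.3)
with gamma amounts (shape 0.7) whose expected annual total equals MAP.
Fixed (site, years, seed) inputs give byte-identical series.

Two dimensionless modifiers in [0, 1] enter the rate law:

- **Temperature**: Gaussian `exp(−(T − T_opt)² / 2σ²)` per guild, with a
  hard activity threshold below which the ectotherm guilds (termites,
  beetles) are fully inactive. Defaults: fungi 25/10 °C, termites 28/7 °C
  (threshold 10 °C), bacteria 30/12 °C, beetles 24/8 °C (threshold 8 °C).
- **Moisture**: a single-bucket wood-moisture index in [0, 1]. Throughfall
  (precipitation × exp(−0.5·LAI), plus degree-day snowmelt at
  4 mm °C⁻¹ d⁻¹ from a snowpack accumulated at T ≤ 0 °C) recharges the
  bucket (capacity 40 mm); drying removes a fraction
  0.04·max(T, 2)/20 per day, doubled for standing snags (no ground
  contact). The response is piecewise linear and unimodal: 0 when dry,
  peak 1.0 at index 0.6, declining to 0.5 at saturation (waterlogging
  limits aeration).

Leaf area index is static per run; litterfall initialisation is exposed
as a site attribute but not used by the default kinetics.

## Guild kinetics and carbon routing

Per guild g and sub-cohort, the instantaneous rate (y⁻¹) is

    r_g = k_g · f_T · f_W · s_g(species) · (D_ref/D)^b · p(position)
            · colonization_g(t) · decline_g(t)

with `k_g` the potential rate, `s_g` a per-species substrate multiplier,
`(D_ref/D)^b` a surface-to-volume scaling (D_ref = 15 cm, b = 0.3:
larger logs lose a smaller fraction per day), `p` = 0.45 for standing
snags, `colonization` a logistic establishment ramp
1/(1 + exp(−(t − lag)/steepness)) (fungi and bacteria need time to
colonise intact wood), and `decline` = exp(−ρ·t) an exponential
resource-decline term (termite and beetle attack fades as the readily
exploitable substrate ages — the minimal mechanism reproducing the
early-termite/late-fungi succession). Within a day the total loss
compounds exactly, ΔM = M(1 − exp(−Σr_g/365)), so the daily step
introduces no step-size bias; the loss is apportioned to guilds in
proportion to their rates.

Decomposed carbon is routed in this order: a DOC fraction
(doc_leach_coeff × moisture index, the wetter the wood the more leaching)
is carved off the day's loss, of which a retention fraction (0.853)
reaches the mineral soil; the remainder splits per guild between
respiration and fragments (each guild's fragmentation share); the
fragment pool decays at forest_floor_k = 0.5 y⁻¹, releasing a POC
fraction (poc_coeff) to the soil and the rest as forest-floor
respiration. The ledger identity

    initial C = CWD + fragments + Σ respiration + DOC produced + POC

holds at every step to ~1e-15 relative (machine rounding); the test suite
enforces 1e-9 under random parameters. The engine is fully deterministic;
the only randomness in a scenario is the climate seed.

The single-day kernel (`engine.step`) and the vectorised simulator
(`engine.simulate`) implement the same update; a test pins their
equivalence to rounding error, and a constant-forcing test pins the
trajectory to the closed-form exponential to < 1e-6.

## Decay-curve fitting and half-lives

`M_t = M_0 e^(−kt)` is fitted by untransformed nonlinear least squares,
with the intercept either free or forced to the known initial mass
(forcing reflects the true starting condition; a log-linear option is
provided for comparison, since log-transformed regression biases toward
the late, low-mass points). `M_t = M_0 (t+1)^{k2} e^(−k1 t)` is fitted
for (k1, k2) with M0 fixed, from a deterministic 3×3 start grid to avoid
the k1/k2 trade-off's local minima. R² is reported as the squared Pearson
correlation of observed and fitted values. Half-life is closed-form
(ln 2 / k) for the exponential and a doubling-bracket + bisection root
(|f| < 1e-9 and bracket < 1e-9) for the power-exponential form; with
k2 = 0 the iterative root equals the closed form, which is tested. Fits
use the annual remaining-mass series including t = 0.

## Performance metrics

E = 1 − SSE/SST (Nash–Sutcliffe), PBIAS = 100·Σ(O−P)/ΣO (positive =
underprediction), RMSE with divisor n, and RSR = RMSE/SD with the
*sample* SD (divisor n − 1) — the standard combination in the model
evaluation literature; the source text gives RMSE with n and leaves the
SD convention unstated. E maps to five bands closed on the left
(< 0: not applicable; 0–0.25 poor; 0.25–0.5 fair; 0.5–0.75 good;
≥ 0.75 excellent); PBIAS is acceptable in (−25, 25)% and RSR in [0, 0.7].
Every metric is pinned to a naive loop implementation to 1e-12 on random
series.

## Calibration of the shipped defaults

The default parameter file (`src/cwddat/data/default_params.json`) is the
archived output of `scenarios.recalibrate_hugo_defaults`: a deterministic
Nelder–Mead minimisation (fixed start, two deterministically perturbed
restarts) of the weighted mean squared relative error on five targets of
the 30-year application run under seed-42 synthetic climate — remaining
mass fraction 0.016, cumulative fungal share 0.720, cumulative termite
share 0.245, other-decomposer share 0.035, and forced-intercept fitted
k = 0.132 y⁻¹ — over seven free kinetic parameters (fungal potential rate
and colonization ramp, termite rate and resource decline, bacterial and
beetle rates). The archived optimum attains a weighted RMS relative error
≈ 7e-10. The DOC and POC coefficients are then solved analytically
(both outputs are exactly linear in their coefficients because leaching
re-routes decomposed carbon without altering the mass trajectory) to
place retained DOC at 30.3 g C m⁻² and POC at 0.13 g C m⁻² over the 30
years; the implied DOC production is 35.5 g C m⁻².

Under these defaults the application run shows the expected succession:
termites dominate year 1 (~97% of annual loss) and decline strictly
thereafter; fungi take over and exceed 70% of annual loss from year 5
through year 30; bacteria rise to ~3% late; beetles contribute only in
the first two years. The calibration makes the fungal takeover somewhat
more gradual (crossing 70% in year 5) than the two-year switch the field
narrative suggests: a takeover completed by year 2 forces a near-constant
late-trajectory slope ≈ 0.14 y⁻¹ and hence a forced-intercept fit
≥ 0.145, inconsistent with the target pair (1.6% remaining, k = 0.132).
The quantitative targets were kept exact and the succession timing
absorbed the slack; the property tests assert the strict termite decline
and fungal dominance from year 5.

Scenario climate is synthesised from site MAT/MAP (observed station data
are not shipped); the Hugo guild shares vary by less than ±0.5 percentage
points across climate seeds, the remaining fraction by ~±0.001.

## What the synthetic data do and do not show

The synthetic climate reproduces annual means, seasonality, daily
autocorrelation and intermittent precipitation, but not inter-annual
variability modes, drought sequences, humidity or radiation; the moisture
bucket is a proxy for wood water content, not a hydrological model.
Passing tests therefore demonstrate internal consistency (conservation,
determinism, closed-form limits, fitted-constant recovery) and agreement
with the published application-scale outcomes — not transferability to
observed station forcing. The six-year per-log field observations are not
published per log, so log-scale predictive skill (the E/R²/RSR values of
the original evaluation) is not reproducible here; the evaluation module
is instead verified by metric identities and oracle equivalence, and the
per-log workflow is exercised end-to-end on simulated data.

## Numerical choices and degenerate inputs

- Daily time step, 365-day years (no leap handling inside the engine);
  annual reporting at day 365·y.
- Mid-day substrate age (d + 0.5 days) evaluates the lag/decline terms.
- Zero total rate on a day → zero loss and zero guild shares (no 0/0).
- Non-decaying fit inputs return a flagged fit with a warning rather than
  an error; zero observed variance, zero observed sum and constant series
  raise in the metrics that are undefined there.
- Sub-cohorts with zero initial mass report remaining fraction 1.0.
- Nelder–Mead runs with xatol 1e-5 / fatol 1e-10 and clips parameters to
  their bounds.

## Known limitations

- No standing-to-downed transitions, spatial heterogeneity, nitrogen
  cycling or inter-guild interactions beyond shared substrate.
- Guild response parameters other than the seven calibrated ones (optima,
  thresholds, substrate multipliers, fragmentation shares, the size
  exponent and the standing multiplier) are field-plausible defaults, not
  fitted values; they are exposed in the parameter file.
- The power-exponential constants fitted to the simulated trajectory
  depend on the trajectory's exact lag shape and differ from the
  published pair fitted to the original simulator's output; the package
  reproduces the published pair exactly when fitting data generated from
  that form, which is what the recovery tests pin.
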