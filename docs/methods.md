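# Methods

This note documents the models, the numerical choices and the synthetic
data underlying `tsdnorm`, and what the shipped tests do and do not
establish.

## The flexit* sex-ratio model

The probability that an egg develops as female at constant incubation
temperature `T` (°C) is

```
sr(T) = (1 + exp(4 (S + ΔS·QBT(P, T)) (P − T)))⁻¹
QBT(P, T) = (1 + exp(100 (P − T)))⁻¹
```

with pivotal temperature `P` (°C), lower-limb slope parameter `S₁ = S` and
upper-limb slope parameter `S₂ = S + ΔS` (both must be positive). The QBT
is a logistic so steep it acts as a smooth switch: the curve behaves as a
logistic with slope `4S₁` below the pivot and `4S₂` above it, the
transition being confined to roughly ±0.05 °C around `P`. `sr(P) = 0.5`
holds exactly because `QBT(P, P) = 0.5` multiplies a zero exponent.

The transitional range of temperatures (TRT) spans the sex ratios `l` to
`1 − l` (default `l = 0.05`, the conventional TRT₉₅):

```
lower = P − ln((1−l)/l) / (4 S₁),   upper = P + ln((1−l)/l) / (4 S₂)
```

These are closed-form inversions of the two limbs; we report the width as
`upper − lower`, which is positive (writing the width as the difference in
the other order, as is sometimes done, merely flips the sign). The
inversions neglect QBT blending, which is negligible provided the limits
lie outside the ±0.1 °C switching zone — true for slopes `S ≲ 7`; the
leatherback estimates (`S ≈ 2.3`) are far inside that regime, and the
property tests restrict to `S ≤ 5` accordingly.

Two edge behaviours of the parameterization are worth knowing:

* For strong *negative* asymmetry (`ΔS` close to `−S`) the QBT blend can
  produce a tiny non-monotonic ripple within ±0.05 °C of the pivot. This
  is a structural property of the model, irrelevant at fitted parameter
  values; property tests therefore sample `ΔS ≥ −S/2`.
* Celsius is an interval scale, so nothing forces the pivot to sit at the
  centre of the TRT — that freedom is exactly what `ΔS` provides.

**Likelihood.** Sexed counts are binomial in the number of females with
success probability `sr(T)`; the binomial coefficient is omitted (constant
in the parameters, so posterior shapes, likelihood ratios and
information-criterion *differences* on shared data are unaffected).
Probabilities are clipped to `[1e−15, 1 − 1e−15]` inside the likelihood
only. Intersex hatchlings are excluded by default; options count them as
female, male, or half each. Records with zero sexed hatchlings (e.g. a
temperature at which nothing could be sexed) carry no information and are
dropped by the fitters.

## The growth norm and the thermosensitive period

Instantaneous embryonic growth rate follows the four-parameter
Schoolfield-type form with low-temperature inhibition:

```
r(T) = ρ₂₅ · (T_K / 298.15) · exp[(ΔH_A/R)(1/298.15 − 1/T_K)]
       / (1 + exp[(ΔH_L/R)(1/T_½L − 1/T_K)])
```

`T_K = T + 273.15`, `R = 8.314 J mol⁻¹ K⁻¹`; `ρ₂₅` (min⁻¹) is the rate at
the 25 °C reference, `ΔH_A > 0` (J mol⁻¹) drives the increase with
temperature, `ΔH_L < 0` and `T_½L` (K) shape the low-temperature roll-off.
The high-temperature inactivation branch is deliberately absent: tropical
sea-turtle data show no sublethal growth decline at warm nest
temperatures, and the rate is monotone increasing over 25–35 °C.

Embryo size (straight carapace length, SCL) is modelled as exponential
growth at the instantaneous rate, `dSCL/dt = r(T(t))·SCL`, from
`SCL₀ = 1.7 mm` to the hatchling size (defaults 59.3 mm for Northwest
Atlantic material, 57.3 mm for Malaysia; configurable per dataset). The
exponential law is a modelling choice — every quantity the pipeline
consumes downstream (TSP timing, CTE weighting, predicted durations)
depends only on the cumulative rate integral `∫ r(T(t)) dt`, which is
invariant to monotone re-parameterizations of the size axis, so this
choice is innocuous.

**Integration.** Fixed-step trapezoidal quadrature of `r` on log-SCL
(default step 60 min) with the temperature series interpolated linearly;
the hatching instant is found by linear interpolation of the cumulative
integral. At constant temperature this reproduces the closed form
`D = ln(SCL_hatch/SCL₀)/r(T)` exactly up to crossing interpolation
(< 0.1%), and halving the step moves durations by < 0.05%.

**TSP.** The thermosensitive period is bounded by the developmental-stage
landmarks 23 and 27. The exact SCL values of those stages come from
staging tables external to this package; the defaults are the fractions
(1/3, 2/3) of hatchling SCL, explicitly flagged as placeholders and
overridable wherever a TSP is computed. Because the TSP is anchored to
embryo size rather than elapsed time, its position within incubation
shifts with the temperature history (a cold finish pulls it relatively
earlier, a warm finish later): under fluctuating temperatures it is
generally *not* a fixed fraction such as the middle third of incubation
time, which is precisely why CTEs must be computed within the TSP rather
than over the whole record.

## Constant-temperature equivalents

The CTE of a fluctuating series is the growth-rate-weighted mean
temperature within the TSP:

```
CTE = ∫_TSP T(t) r(T(t)) dt / ∫_TSP r(T(t)) dt
```

evaluated by trapezoid on a fine grid whose endpoints are the interpolated
TSP boundaries. Weights use the instantaneous rate at the recorded
temperature (not embryo size). Because the weights are positive the CTE is
bounded by the TSP temperature extremes, and because `r` increases with
temperature it is ≥ the plain time average (equality only for constant
series) — the plain average, provided as a comparator, systematically
understates the sexualizing temperature of variable nests. When posterior
growth-parameter draws are supplied, the trajectory and TSP are
re-delineated per draw and the CTE distribution summarized by its median
and 95% credible interval; for near-constant tropical nest records that
interval is very narrow, since every plausible TSP placement sees nearly
the same temperatures.

## Bayesian fitting

Both fitters use a seeded adaptive Metropolis-within-Gibbs sampler with
the chain-length defaults 1000 burn-in iterations, 10,000 sampling
iterations, thinning 10 (1000 retained draws). Proposal scales adapt in
batches of 50 during burn-in only (target component-wise acceptance 0.44)
and are frozen afterwards, so the retained chain is time-homogeneous.
Three proposal types are combined:

1. component-wise Gaussian random-walk updates;
2. one joint multivariate-normal update per sweep over the global curve
   parameters, with covariance estimated from the burn-in history
   (2.38/√d scaling) — this handles the correlation between the pivot and
   the limb slopes;
3. for hierarchical fits, interweaving moves per level and parameter: a
   *translation* (shift the global parameter, compensate all group
   deviations; likelihood-invariant) and a *rescaling* (scale the level
   SD, shrink the deviates; group effects invariant), each a valid
   Metropolis–Hastings kernel with the appropriate Jacobian correction.
   Without these, random-walk sampling of hierarchical models stalls on
   the global-vs-deviation and SD-vs-deviate ridges (effective sample
   sizes of single digits); with them the pivotal temperature's effective
   sample size exceeds 400 on the packaged datasets.

**Chain coordinates.** The TSD chain samples `(P, log S₁, log S₂)` — the
two limb slopes are nearly independent given the data whereas `(S, ΔS)`
are strongly anti-correlated — with the Jacobian correction keeping the
stated uniform priors on `S` and `ΔS`. The growth chain samples
`log₁₀ r(30 °C)` in place of `log₁₀ ρ₂₅` (a unit-Jacobian shear): duration
data pin down the rate at incubation temperatures, not at the 25 °C
reference, and the shear removes the ρ₂₅/ΔH_A ridge.

**Priors.** TSD: `P ~ U(25, 35) °C`, `S ~ U(0.05, 20)`,
`ΔS ~ U(−S + 0.05, 20)` (both limb slopes positive); random-effect SDs
half-normal with scale 1 (configurable per level and parameter). Growth:
uniform on `log₁₀ ρ₂₅ ∈ (−6.5, −2.5)` (the rate spans orders of
magnitude; uniformity on the log scale is the natural "wide uniform"
here), `ΔH_A ~ U(10⁴, 3·10⁵)`, `ΔH_L ~ U(−5·10⁵, −10⁴)`,
`T_½L ~ U(270, 310) K`.

**Random effects.** The admissible nesting structures are `1`, `(1|RMU)`,
`(1|RMU/ID)` and `(1|RMU/ID/Clutch)` (RMU = regional management unit,
ID = study identifier). Group deviations act additively and independently
on each of `P`, `S`, `ΔS` — the natural mixed-model reading — in a
non-centered parameterization (`θ_group = θ_global + σ_level·z`,
`z ~ N(0,1)`). Correlation of effects across the three parameters is not
modelled. The study-level effect absorbs, among other things, how
different experimenters scored gonads and handled intersexes.

**Growth likelihood.** Duration summaries enter as
`mean_days ~ Normal(predicted duration, sd_days/√n)` — the sampling
distribution of the observed mean under the reported per-condition SD.
Predictions use the constant-temperature closed form or full trajectory
integration for recorded series (a series too short for hatching yields
−∞, i.e. rejection).

**Determinism.** All randomness flows from one `numpy` Generator seeded
by the caller; records are sorted into a canonical order before fitting,
so permuting the input leaves the draws bit-identical.

## Model comparison

`AICc = −2·loglik + 2k + 2k(k+1)/(n − k − 1)`; Akaike weights
`wᵢ ∝ exp(−Δᵢ/2)`. Rather than plug-in values, both are evaluated at every
retained draw (each model at its own draw, models paired by draw index —
fits run with the same seed schedule) and reported as means with
across-draw standard errors. Conventions, configurable: `k` counts the
global parameters plus one per estimated random-effect SD (3 per nesting
level; conditional likelihoods given the drawn effects are used); `n` is
the number of sexed eggs for TSD models and the number of duration
observations for growth models.

## Synthetic data

The generators emulate the study designs the packaged tables come from,
and their defaults are fixed to those conditions:

* **Sexed counts:** constant-temperature grid 28–32 °C, clutches of 10
  eggs, flexit* truth `P = 29.49`, `S = 2.34`, `ΔS = 0.49` (the
  leatherback point estimates); optional among-group SDs per nesting
  level and parameter generate clutch/study/RMU heterogeneity and hence
  binomial overdispersion.
* **Nest temperature series:** mean + sinusoidal day-night cycle
  (half-range default 0.25 °C — shaded incubation boxes, so nychthemeral
  change is small) + linear drift + Gaussian logger jitter (0.05 °C),
  sampled once per day over 75 days by default (the cadence of the
  historical Malaysian records).
* **Durations:** deterministic prediction from the growth norm plus
  Gaussian noise, SD 2 days, summarized per condition; the growth truth
  (`ρ₂₅ = 2.8·10⁻⁵ min⁻¹`, `ΔH_A = 7·10⁴`, `ΔH_L = −1.4·10⁵`,
  `T_½L = 285 K`) gives ~75 d at 27 °C to ~50 d at 31 °C, matching
  leatherback incubation.

What these simulations do **not** capture: metabolic heating, beach
thermal microclimate, stage-dependent sexualizing strength within the
TSP, non-Gaussian duration errors, and digitization error in historical
series. Passing recovery tests on synthetic data therefore demonstrates
the correctness and calibration of the estimators under the stated model,
not robustness to those field realities.

Two literature-data utilities are included: SD-from-range conversion
(either `range/(2·1.96)` or the order-statistics estimator
`range / E[range of n standard normals]`, the expectation by seeded Monte
Carlo with 10⁵ replicates), and the single-sex detection probability
`(1 − p)ⁿ` quantifying why small batches cannot pin down TRT limits.

## Problem sizes used in the shipped checks

The replicated studies in the test suite are sized to be informative yet
routine to run: the clutch-effect comparison uses 20 replicates of 12
clutches × 15 eggs (true `σ_clutch,P = 0.3 °C`, temperatures spread across
the TRT) with shortened chains (500 burn-in / 2000 iterations / thin 10);
the growth-norm pooling comparison uses one replicate at the historical
sample sizes (110 constant-temperature eggs, 4 fluctuating boxes with 70
eggs); coverage checks use 15 replicates. Full-length chains (1000 /
10,000 / 10) are used everywhere a single fit is reported.

## Known limitations

* The sampler is single-chain; convergence is monitored by effective
  sample size and acceptance-rate checks rather than cross-chain R-hat.
* TRT limits are closed-form limb inversions; for hypothetical curves
  with `S > ~7` (TRT narrower than the QBT switching zone) they would be
  biased — outside any fitted regime for sea turtles.
* The stage-23/27 SCL landmarks default to placeholder fractions of
  hatchling size; analyses that hinge on absolute TSP timing should
  supply species-specific staging values.
* With one study per RMU (as in the packaged data), RMU and study effects
  are nearly inseparable; only the clutch level is well informed.
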