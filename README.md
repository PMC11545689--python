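# tsdnorm

Thermal reaction norms of **temperature-dependent sex determination (TSD)**
and embryonic growth in sea-turtle incubation data, with leatherback
(*Dermochelys coriacea*) datasets packaged as worked examples.

In species with TSD, the proportion of females produced rises with
incubation temperature through a narrow transitional range of temperatures
(TRT) around the pivotal temperature *P* (the constant temperature giving a
1:1 sex ratio). Comparing TSD patterns across populations is hard: sexed
samples are small, nest temperatures fluctuate, and study- and clutch-level
effects masquerade as population differences. This package implements the
statistical machinery needed to do it properly:

* **flexit\* sex-ratio curve** — an asymmetric sigmoid
  `sr(T) = (1 + exp(4 (S + ΔS·QBT)(P − T)))⁻¹` with pivotal temperature
  `P`, lower-limb slope `S₁ = S`, upper-limb slope `S₂ = S + ΔS`, blended
  across the pivot by the quasi-binary threshold
  `QBT = (1 + exp(100 (P − T)))⁻¹`. TRT limits are closed-form:
  `P − ln((1−l)/l)/(4S₁)` and `P + ln((1−l)/l)/(4S₂)` (default `l = 0.05`).
* **Schoolfield-type growth norm** — instantaneous embryonic growth rate
  `r(T) = ρ₂₅ (T_K/298.15) exp[(ΔH_A/R)(1/298.15 − 1/T_K)] /
  (1 + exp[(ΔH_L/R)(1/T_½L − 1/T_K)])`, integrated over a recorded nest
  temperature series to give the embryo-size trajectory and the
  thermosensitive period (TSP, stages 23–27).
* **Constant-temperature equivalents (CTE)** — the growth-rate-weighted
  mean temperature within the TSP, the single constant temperature with
  the same sexualizing effect as a fluctuating series.
* **Bayesian MCMC fitting** (`fit_tsd`, `fit_growth`) — binomial /
  Gaussian likelihoods, wide uniform priors, optional nested random
  effects (RMU / study ID / clutch) on `P`, `S` and `ΔS`, fully seeded.
* **Model comparison** — AICc and Akaike weights evaluated at every
  retained posterior draw and reported as posterior-predictive means.
* **Synthetic-data generators** — hierarchical sexed-count tables,
  near-constant tropical nest series, and duration summaries, so the whole
  pipeline is testable without any downloads.

## Worked example

Fit the flexit\* curve to all packaged leatherback counts (the East
Pacific constant-temperature table pooled with the four Malaysian nests at
their median CTE):

```bash
$ tsdnorm fit-tsd --builtin pooled --seed 1
fitting flexit* to 13 records, RE=1, seed=1, burn=1000 iters=10000 thin=10
         P: median 29.286  mean 29.305  SE 0.212  95% CI [29.026, 29.794]
         S: median 2.817  mean 4.739  SE 4.528  95% CI [0.715, 17.492]
        dS: median -1.717  mean -3.324  SE 5.230  95% CI [-16.835, 4.173]
 trt_lower: median 28.997  mean 28.985  SE 0.129  95% CI [28.619, 29.201]
 trt_upper: median 30.009  mean 30.048  SE 0.223  95% CI [29.725, 30.567]
 trt_width: median 1.040  mean 1.063  SE 0.257  95% CI [0.653, 1.614]
```

The posterior places the pivotal temperature near 29.3–29.5 °C with a TRT
of roughly a degree — leatherbacks have the steepest (thinnest-TRT) sex
ratio curve among sea turtles, so small temperature shifts move the sex
ratio a long way. Adding nested random effects
(`--re "1|RMU/ID"`) widens the pivotal-temperature and TRT-limit
uncertainty, which is the statistically honest reading of multi-study
data. Random-effect structures can be compared directly:

```bash
tsdnorm compare --builtin pooled --re 1 --re "1|RMU/ID" --seed 1 --out cmp.csv
```

The same steps are available as library calls (`tsdnorm.fit_tsd`,
`tsdnorm.posterior_model_weights`, …); `tsdnorm simulate`,
`tsdnorm fit-growth` and `tsdnorm compute-cte` cover the growth-norm and
CTE stages of the pipeline.

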