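# Methods

## The diel O₂ model

Within one day, depth-averaged dissolved O₂ (g m⁻³) is assumed to change
through three processes: gross primary production GPP (g O₂ m⁻² day⁻¹),
distributed over the day in proportion to instantaneous PAR; ecosystem
respiration ER (≤ 0, constant through the day); and air–water exchange at
rate K<sub>O₂</sub> (day⁻¹) toward the temperature- and pressure-dependent
saturation concentration. Discretized on the sensor clock (Δt = 10 min
by default):

    O2[t] = O2[t-1] + (GPP/z)·PAR[t-1]/ΣPAR + ER·Δt/z
                    + KO2·(O2sat[t-1] − O2[t-1])·Δt

with z the daily mean channel depth (m) and ΣPAR the sum of PAR over the
day. The model assumes z and K constant within a day, no groundwater O₂
exchange, and a well-mixed channel. The recursion is linear in O₂ with a
constant coefficient, i.e. a first-order IIR filter; the forward model is
evaluated with `scipy.signal.lfilter`, so a full day costs one filter
pass and a 150,000-iteration fit runs in seconds.

Sign conventions: ER is stored negative (consumption), so NEP = GPP + ER;
summaries that quote "ER magnitude" conventions must negate it at the
reporting layer. O₂ rates convert to carbon by ×12/32, assuming one mole
of CO₂ produced or consumed per mole of O₂ (respiratory and
photosynthetic quotients of 1); this quotient is a recognized source of
bias and is deliberately not tunable per day.

## Bayesian inversion

Each day is fitted independently by random-walk Metropolis over
θ = (GPP, ER, K<sub>O₂</sub>, σ), where σ is the iid Gaussian observation-error SD.
The first observation anchors the trajectory and is not a parameter.
Priors:

* GPP ~ Normal(1, 2) and ER ~ Normal(−5, 2) g O₂ m⁻² day⁻¹ — weakly
  informative values typical of Arctic streams; GPP is not hard-bounded
  at zero, but with real signal the posterior mass below zero is
  negligible;
* K<sub>O₂</sub> ~ Normal(m, s) with (m, s) from the site's K₆₀₀–discharge relation
  evaluated at the day's mean discharge and converted by Schmidt scaling
  at the day-mean temperature. The tight, data-driven K prior is the
  package's defence against equifinality: with K nearly known, the diel
  curve separates GPP from ER;
* σ ~ half-Normal(0.5 g m⁻³), a weak prior; estimating σ avoids fixing an
  arbitrary sensor error. σ is floored at 10⁻⁴ g m⁻³ so noise-free
  synthetic data cannot drive the likelihood improper.

The default schedule is 150,000 iterations keeping the last 100,000. The
proposal is a joint Gaussian whose covariance is adapted during the
discarded burn-in (Robbins–Monro scaling toward ~30% acceptance plus an
empirical-covariance update, 2.38²/d scaling) and frozen for the kept
phase, so the kept draws come from a fixed-kernel chain. A kept-phase
acceptance rate outside [0.1, 0.6] flags the fit rather than failing it.
Fits are bit-reproducible for a given seed (one `numpy` Generator drives
the chain). Initialization is at the prior means — reproducible and
always in support.

## Night-time regression and the K₆₀₀–Q relation

After sunset GPP vanishes, so dO₂/dt = ER/z + K<sub>O₂</sub>·(O₂sat − O₂): the slope
of rate against deficit is K<sub>O₂</sub> and the intercept absorbs ER/z. Because
the photoperiod shifts strongly through a high-latitude summer, each
night (sunset → next sunrise, from on-site solar geometry) is scanned
with six candidate windows; nights shorter than 2 h yield no estimate.

Design choices, made here because the exact operationalization is a
convention rather than a published formula:

* **Windows**: six equal windows spanning 2/3 of the night, starts evenly
  spaced so their union covers the whole night. Retained windows need
  R² > 0.7 and a positive slope; the best remaining R² wins (ties go to
  the longer window).
* **Differencing**: within a window the series is split into ~4 bins
  (at least 5 regression points are required); consecutive bin-mean
  differences are regressed on triangularly weighted deficit means. The
  triangular weights make the regression an exact telescoping of the
  Euler recursion — on noise-free data the slope equals K<sub>O₂</sub> to machine
  precision at any bin size — while bin averaging suppresses sensor
  noise, which raw 10-min differencing amplifies by 1/Δt. A centred
  difference was rejected because it carries a multiplicative bias of
  (1+a)/2a with a = 1 − K<sub>O₂</sub>Δt (~3% at K<sub>O₂</sub> = 8 day⁻¹) against either
  endpoint's deficit.
* Window-mean temperature converts the slope to K₆₀₀.

Nightly K₆₀₀ values are regressed linearly on daily mean discharge; the
residual SD of that fit becomes the SD of the daily K prior. At least
three nights are required; short records can inject an external relation
instead. Selection of best-R² windows gives the nightly estimator a mild
upward bias at high noise — visible in the synthetic experiments and
inherent to the filtering rules — which is why the pipeline treats the
relation's residual SD, not the nightly point estimates, as the honest
uncertainty.

The depth–discharge rating is ordinary least squares of Q on logger
depth, flagged when R² ≤ 0.85.

## Quality control

Two day-level rules, both strict inequalities, both configurable:
discard when the MAE between observed O₂ and the posterior-mean
trajectory exceeds 0.2 g m⁻³, and when the within-day depth range
exceeds 10% of the daily mean depth (depth is the proxy for K, which the
model assumes constant). The range/mean denominator is a choice (the
rule could also be read as range/min); it is exposed in the thresholds.
The historical third filter — manual visual inspection — is replaced by
the quantitative diagnostics carried on each fit (acceptance-rate flag,
MAE, posterior SDs).

## CO₂ evasion and diel metrics

E = K<sub>CO₂</sub>·z·([CO₂]w − [CO₂]a) in g C m⁻² day⁻¹ (positive = efflux), with
K<sub>CO₂</sub> per timestep from the K₆₀₀–Q relation and the concurrent Schmidt
number, and concentrations from Henry's law (Weiss 1974 freshwater K₀)
at the water temperature. The atmospheric reference is 380 ppm by
default and overridable. Diel metrics per day:

* ΔCO₂ = max − min of the day's pCO₂ (ppm);
* diel evasion change = (mean daytime rate − mean night rate) × daytime
  duration. The duration normalization is a declared convention — the
  day/night split is otherwise ill-defined when the photoperiod ranges
  from 4 h to 24 h; during polar day the metric is NaN and flagged;
* noon/midnight rates = means in 1-h bins centred on *solar* noon and
  solar midnight (clock noon at the study longitude is ~1 h off);
* CV = sample SD / mean × 100.

## Reach mass balance

For a surveyed segment, net in-channel CO₂ production (g C day⁻¹) is
P = Q<sub>out</sub>·CO₂<sub>out</sub> − Q<sub>in</sub>·CO₂<sub>in</sub> − Q<sub>GW</sub>·CO₂<sub>GW</sub> + E·A with Q<sub>GW</sub> = Q<sub>out</sub> − Q<sub>in</sub>.
In a losing segment the infiltrating water is stream water, so
CO₂<sub>GW</sub> is set automatically to the segment-mean stream concentration
(segment mean, not reach mean — a choice, since either reading is
defensible); gaining segments require a user-supplied groundwater
concentration because it cannot be inferred from stream data. Reach
summaries report P/A per segment and the area-weighted mean.

## The synthetic generator

`simulate_deployment` emulates a summer deployment in a small subarctic
stream: clear-sky PAR from solar geometry (half-sinusoid in solar
elevation, peak 1500 µmol m⁻² s⁻¹), sinusoidal diel water temperature
(8 ± 2 °C), daily log-AR(1) discharge around 0.1 m³ s⁻¹ with optional
within-day spates (to exercise the depth-stability filter), a linear
depth rating, K₆₀₀ = 2 + 100·Q (day⁻¹, Q in m³ s⁻¹) with residual SD 1,
daily GPP ~ N(0.8, 0.3) and ER ~ N(−5, 1) g O₂ m⁻² day⁻¹ (clipped to
their physical signs, ER an order of magnitude above GPP as observed in
tundra streams), iid Gaussian O₂ noise of 0.02 g m⁻³ (optical-logger
per-sample precision) and multiplicative lognormal pCO₂ noise (σ = 0.02).
CO₂ mirrors the O₂ dynamics mole for mole (NEP source × −1/32), with
K<sub>CO₂</sub> exchange toward a 380 ppm atmosphere and an optional constant
groundwater CO₂ flux uncoupled from O₂; initial conditions sit at the
heterotrophic steady state, giving the persistent supersaturation real
sites show.

What the generator does *not* emulate: sensor drift and fouling, data
gaps, temperature-dependent metabolism within or across days, hyporheic
storage, non-linear ratings, cloud cover. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-sensor pathologies.

## Numerical choices and problem sizes

* Quantile summaries use linear interpolation (`numpy` default, type 7).
* All timestamps are UTC; longitude enters only through solar geometry.
* The recovery experiments run the sampler at 30,000 iterations keeping
  20,000, and unit tests use still shorter chains (the adaptive proposal
  makes short schedules adequate for these three-parameter posteriors);
  the pipeline default remains 150,000/100,000.
* The recovery experiment draws 20 site-days with GPP ∈ [0.5, 3],
  ER ∈ [−8, −1] g O₂ m⁻² day⁻¹, K₆₀₀ ∈ [5, 60] day⁻¹, noise 0.02 g m⁻³,
  and a K prior centred on truth with 10% relative SD (the quality a
  decent site relation delivers); 95% interval coverage across the 60
  parameters is ≥ 90% and posterior means sit within 10% of truth at low
  noise (0.005 g m⁻³).
* The evasion–NEP conservation check integrates three chained noise-free
  days and evaluates the last (quasi-cyclic) one; agreement is within 2%,
  limited by the Euler discretization and residual storage drift.

## Known limitations

* Single-station logic: the footprint upstream of the sensors is assumed
  homogeneous; no routing or lag.
* The nightly K estimator's window-selection bias at high noise
  (documented above) propagates into the K₆₀₀–Q slope when the discharge
  range is narrow.
* Metabolism days are independent; no hierarchical pooling across days
  or sites.
* The CO₂ module ignores carbonate-system speciation; pCO₂ is treated as
  free dissolved CO₂ via Henry's law, appropriate for circumneutral,
  poorly buffered waters but not for high-alkalinity systems.
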