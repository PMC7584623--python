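# Methods

This note documents the models, conventions and numerical choices behind
`floatbloom`, and what its synthetic-data tests do and do not demonstrate about
real float data.

## Per-cast processing chain

Each cast (one vertical profile of T, S, bbp(700), Chl) is processed in a fixed
order: 7-point running-median smoothing of the optical channels, conversion of
backscatter to particulate organic carbon (`POC = 3.12e4 * bbp + 3.0` mg m⁻³) and
phytoplankton carbon (`C_phyto = 0.19 * POC`), subtraction of the mean 900–2000 m
C_phyto from the whole profile (so carbon asymptotes to zero at depth), masking of
negative concentrations, and only then the physical derivations. The empirical
fit uncertainties (±2.47e3 slope, ±6.8 intercept, ±8.7 on C_phyto) are carried as
metadata on `BiomassParams`; the analysis runs on point estimates.

The running median uses a centered window that shrinks symmetrically at the
profile ends, which makes monotone profiles exact fixed points of the filter. A
consequence worth knowing: a running median cannot preserve structure narrower
than about half its window, so any feature confined to ≲3 samples (on the Argo
grid, ~30 m below 100 m depth) is flattened before the growth model sees it.

**Mixed layer depth** is the shallowest depth at which potential density exceeds
its 10 m value by 0.03 kg m⁻³, linearly interpolated between samples; both the
threshold and reference depth are configurable, since winter MLDs in the Southern
Ocean are sensitive to the convention. Potential density comes from the EOS-80
one-atmosphere polynomial (pressure treated as depth, adiabatic correction
neglected — both standard for upper-ocean threshold MLDs). When the threshold is
never reached, the deepest sampled depth is returned with a `reached=False` flag.

**Euphotic depth** is the 1% light depth computed from the same
chlorophyll-dependent attenuation as the growth model; the integration horizon
for biomass stocks is `max(MLD, Zeu)`.

**Layer averages.** Two conventions coexist deliberately. Biomass statistics
(mixed-layer mean `P̄` and inventories) use a trapezoid with the shallowest sample
extended to 0 m and a linearly interpolated endpoint at the integration bottom —
C_phyto is continuous across the mixed-layer base, so interpolation is unbiased.
Water-mass properties (mu, NSI, LSI, PAR) instead use only in-layer samples, the
deepest one extended as a constant to the base: water just below the base is
stratified and systematically different, and on median-smoothed profiles the
window straddling the base is additionally distorted, so interpolating across it
leaks biased values into the layer mean (up to −1% on mu in deep winter layers).

## Growth model

Division rates follow a carbon-based productivity model:

    mu(z) = mu_max * NSI(z) * LSI(z),        mu_max = 2 d⁻¹
    NSI(z) = (Chl:C(z) − Chl:C_mu0) / (Chl:C_max − Chl:C_mu0), clamped to [0, 1]
    LSI(z) = 1 − exp(−5 · PAR(z))

with `Chl:C_mu0 = 3e-4` mg Chl (mg C)⁻¹ and
`Chl:C_max(PAR) = 0.022 + 0.023·exp(−3·PAR)`. The light field is scalar PAR
attenuated by `Kd = 0.0166 + 0.0773·Chl^0.672` m⁻¹ (Morel-type coefficients),
propagated with layer-wise trapezoidal optical depths; a spectrally resolved
treatment is out of scope and the scalar choice is absorbed into the configurable
coefficients. NSI clamping is required for the saturation-index reading of the
product form.

**Acclimation reference light.** Within the mixed layer, `Chl:C_max` is evaluated
at the *mean* mixed-layer PAR rather than the local PAR(z): cells circulating
through a mixed layer on hours-to-days timescales photoacclimate to the average
light they experience, not to the instantaneous light at their depth. Below the
mixed layer, local PAR is used. Besides the physical argument, this choice makes
in-layer chlorophyll proportional to biomass (a median-filter-faithful profile);
with local-light acclimation the theoretical Chl profile has a narrow maximum at
the layer base that no median-smoothed measurement could represent, and the
growth model would inherit a systematic low bias.

## Net rate of change and climatologies

Between consecutive casts of one float (gap ≤ 20 days; floats cycle every 5–10
days, so one missed cycle is tolerated):

    r(t + Δt/2) = (2/Δt) · (X₂ − X₁)/(X₂ + X₁)

with X the mixed-layer mean concentration when the MLD decreased and the
mixed-layer inventory otherwise (deepening or stationary). The estimator is exact
in the sense that mass-conserving deepening and concentration-conserving shoaling
both give r = 0, and for exponential growth it returns `(2/Δt)·tanh(kΔt/2)` —
within 0.5% of k for kΔt ≤ 0.2.

Annual climatologies average observations (tagged by a fixed 365-day calendar;
Feb 29 folds into day 365) into 52 weekly bins (week 53 folds into week 52),
smooth them circularly with a centered 60-day window, and interpolate linearly to
365 days. Multi-year regional time series use a 10-day moving average followed by
a 500-point moving average instead; both window sets are configurable. Temporal
derivatives are centered circular differences on the smoothed daily cycles.

Bloom initiation (BI) is the negative-to-positive zero crossing of the r
climatology that starts the longest contiguous r > 0 run (circular; secondary
runs — e.g. autumn blooms — are reported alongside), termination (BT) ends it,
and the r-minimum is the argmin of r within the negative phase preceding BI. For
non-smooth cycles the argmin can differ from the "r stops decreasing" reading;
argmin is used. Bloom magnitude is the Nov 1–Jan 31 mean minus the May 1–Jul 31
mean of mixed-layer phytoplankton carbon. Zones default to latitude bands (STZ
30–40°S, SAZ 40–50°S, PAZ 50–60°S, SIZ south of 60°S); front-based definitions
are out of scope, and user masks can override.

## Sensitivity experiment

The loss rate is modeled as the division rate lagged by an integer number of
days, fitted by RMSE of `r̂_L(t) = mu(t) − mu(t−L)` against the observed r
climatology over L = 1..10 (ties break to the smallest lag). Scenarios damp the
seasonal mu contrast by a fraction s: multiplicatively, `mu·(1−s)` above the
annual mean and `mu·(1+s)` below (the literal reading; the discontinuity at the
crossings is accepted), with an anomaly-proportional form `mu − s·(mu − mean)`
selectable. The loss is recomputed from the perturbed cycle in every scenario.
Biomass integrates by exponential daily stepping (exact for piecewise-constant r)
from the Jan-1 climatological concentration; NPP(t) = mu′(t) · P(t) · horizon(t)
with the perturbed mu by default (toggle provided) and the climatological
`max(MLD, Zeu)` horizon.

**A structural property to be aware of.** Because the loss is the perturbed mu
lagged L days, the log-biomass integral telescopes:
`ln P(t) − ln P(1) ≈ L·(mu′(t) − mu′(1))`. The modeled biomass is pinned to the
*local* perturbed division rate. Damping the mu cycle therefore flattens the
biomass cycle toward its January (austral summer) anchor: the summer peak barely
moves while the winter trough rises by roughly `exp(L·s·(mu_summer+mu_winter))`.
Bloom magnitude (summer minus winter) consequently decreases monotonically in s,
but annual-mean NPP — which weights the lifted winter biomass by the deep winter
integration horizon — *increases* with s under this closure. Within this model
family the direction is forced by the telescoping identity, not by tuning; a
reported NPP decline alongside a halved bloom magnitude at s = 0.1 is not
reachable from this construction, so comparisons with analyses that report both
declining should treat the NPP response as model-family-dependent. The package
reports both responses and the sweep diagnostics so the behavior is visible
rather than hidden.

## Synthetic float arrays

The generator builds a daily truth world per float and samples it like a float
would. Defaults are the study conditions and are frozen:

* 20 floats spread over 40–60°S, 10-day cadence (most floats), 2 output years
  after a 1-year spin-up; Argo vertical grid (5 m bins to 100 m, 10 m to 360 m,
  20 m to 400 m, 50 m to 2000 m; shallowest sample 5 m).
* Mixed layer: 150 m winter maximum (deepest around day 244, early September) to
  40 m summer minimum, sinusoidal.
* Surface PAR: annual mean 25 E m⁻² d⁻¹ at 30°S decreasing 0.25 per degree
  poleward, seasonal amplitude 15, peak at the austral summer solstice. The
  amplitude is latitude-flat so winter PAR stays positive (~2 E m⁻² d⁻¹ at 60°S,
  the observed order) and the cycle stays smooth; a poleward-growing amplitude
  would clip at the floor and inject artificial polar-night kinks.
* Nutrient saturation: NSI = 0.25 ± 0.08 (maximum in mid-January) — strong,
  HNLC-style iron limitation, chosen so the annual-mean mixed-layer mu lands near
  0.3–0.5 d⁻¹ and the seasonal biomass swing near a factor 2.5, the scales in
  situ Southern Ocean records show. mu_truth is the in-layer mean of mu(z) on the
  Argo grid (same quadrature the floats support).
* Ecology: l(t) = mu(t − lag) − δ with lag 2 days. The constant
  δ = ln(MLD_max/MLD_min)/365 closes the annual log-concentration budget that the
  zero-biomass entrainment drain would otherwise leave open (each deepening
  season dilutes by MLD_min/MLD_max while the pure lagged loss integrates to
  zero, which would collapse biomass ~4× per simulated year). δ stands in for the
  seeding/retention processes a zero-biomass entrainment ignores and vanishes for
  a constant mixed layer. One visible consequence: bloom initiation occurs
  slightly *before* the mu minimum (while mu is still declining), as in the
  observed records.
* Emission contracts: bbp(700) inverts the carbon relations exactly (plus a
  constant 0.57 mg C m⁻³ deep offset, which keeps deep bbp non-negative and
  exercises the offset correction); Chl follows the photoacclimation relation so
  the growth model recovers mu_truth; T/S place a linear density ramp
  (0.003 kg m⁻³ m⁻¹ from 10 m above the truth MLD) so the threshold MLD estimate
  interpolates exactly to truth on any grid; measurement noise is multiplicative
  lognormal with sigma 0.1 on both bbp and Chl (typical float optical scatter);
  floats south of 60°S lose positions (and hence PAR matchups) inside the
  June–September ice window.
* `TruthConfig.closure()` is the self-consistent configuration for the ecological
  closure test: a constant mixed layer removes entrainment entirely, making
  d ln P̄/dt = mu − l exact, so the s = 0 reconstruction error measures only the
  lag fit and smoothing distortion (measured: < 0.5% pointwise against a 5%
  requirement).

What the generator does **not** emulate: mesoscale variability and advection,
multi-species ecology, ice-albedo light attenuation, spectral light, realistic
T/S climatology (the density ramp is a construction, not a water mass), NPQ or
fluorescence-calibration artifacts (Chl is emitted already corrected), and
iron-explicit physiology (nutrient stress enters only through the prescribed NSI
cycle). Passing the recovery tests therefore demonstrates the correctness of the
processing chain under the stated assumptions — not that the assumptions hold in
any particular ocean.

## Numerical and degenerate-input conventions

* Vertical integrals drop missing samples, extend the shallowest sample to 0 m
  and the deepest constant beyond the last sample.
* Zero surface PAR (polar night, under ice) yields euphotic depth 0 with a
  darkness flag and no division-rate estimate; casts without positions get no
  matchups, never imputed values.
* Casts with fewer than 5 valid upper-200 m samples, all-negative carbon, or no
  usable T/S raise a typed `UnusableCastError` and are logged and dropped.
* Pairs with Δt > 20 days or a vanishing biomass sum are skipped in the r series.
* Weekly climatologies with under 26 populated bins warn; all-empty input raises.
* The flat-mu loss-lag fit is reported as degenerate with the smallest lag.
* Determinism: all randomness flows from one `numpy` Generator seeded from the
  config; identical configs give byte-identical emitted arrays.

## Known limitations

* The EOS-80 surface polynomial ignores pressure effects on density; for
  threshold MLDs above ~500 m this is standard practice, but absolute deep
  densities are not meaningful.
* Division rates are undefined where PAR matchups are missing, so under-ice
  winter mu climatologies in the seasonal ice zone rest on few casts — mirroring
  the real sampling limitation.
* The multiplicative perturbation's discontinuities at anomaly sign changes
  produce brief spikes in the modeled r; the anomaly-proportional form avoids
  them at the cost of a less literal reading.
* The NPP response direction in the sensitivity sweep is a property of the
  lagged-loss model family (see above), and bloom magnitude can go negative at
  large s as the lifted winter biomass overtakes the damped summer peak.
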