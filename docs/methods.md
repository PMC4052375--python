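# Methods

## Gating model

N-type inactivation is modelled as a reversible linear four-state chain
`C1 <-> C2 <-> O <-> I` in the state order (C1, C2, O, I), with row-vector
occupancy dynamics `dp/dt = p Q`. The six rates (s⁻¹) are the activation
pathway `a1, b1, a2, b2` and the gate binding/unbinding rates
`k_on, k_off`. Macroscopic current is `I(t) = iN · P_O(t)` with `iN` (pA)
the lumped channel-count × unitary-current scale. Voltages on the
protocol are provenance only: the model describes a single strong
depolarisation and no rate depends on voltage. Times are milliseconds
externally; rates stay in s⁻¹ (the conversion is internal and tested).

At a step to +60 mV the deactivation rates are negligible, so the
defaults are `b1 = b2 = 0` with the reversible chain still fully
representable for workflows that need them. The default activation rates
are `a1 = a2 = 3000 s⁻¹`. Two considerations fix this value: activation
must be clearly faster than the fastest inactivation analysed
(`k_on ≈ 430 s⁻¹` for a four-gate channel), both because that is the
physiological regime for Shaker at +60 mV (activation τ well under 1 ms)
and because the analysis constrains `iN ≤ 3 × max observed current` — if
activation were comparable to inactivation the peak open probability
falls to ~0.3 and the true `iN` of a simulated trace would violate the
very constraint used to fit it. Activation rates are configuration
values; `estimate_activation_rates` re-estimates them from reference
currents.

## Occupancy propagation

`propagate_occupancy` uses the spectral decomposition of the generator
(exact for diagonalisable Q, vectorised over the whole time grid) and
falls back to per-step matrix exponentials when the eigenvector matrix
is ill-conditioned. Because probability conservation is exact in the
model, the row-sum error of the spectral solution is used as its
accuracy certificate: if any row deviates from 1 by more than 1e-12 the
propagator switches to the `expm` route. Occupancies are clipped to
[0, 1] only to remove ~1e-15 round-off excursions.

Two independent oracles validate the propagator in the test suite: a
fixed-step 4th-order explicit integrator at dt = 1e-4 ms (agreement to
1e-6) and exact event-driven Gillespie simulation of 10⁵ independent
channels (agreement within binomial counting error; see "Statistical
renderings" below). The Gillespie simulator operates on aggregate state
counts with exponential waiting times and shares no code with the
deterministic propagator.

## Trace fitting

`fit_inactivation` minimises the squared residual between the model
current and a baseline-subtracted trace with only `(k_on, k_off, iN)`
free, using MINPACK Levenberg–Marquardt via lmfit. Positivity and the
box constraints — `k_on` within user bounds (typically a reference
cohort's mean ± SD) and `iN ≤ 3 × max |observed current|`, evaluated per
trace — are enforced throughout by lmfit's internal bound
transformation, which keeps the LM algorithm while respecting the box;
estimates within 0.1% of a bound are reported in `active_constraints`.
Convergence: gradient/objective tolerance 1e-8, step tolerance 1e-10,
at most 2000 function evaluations. Default initial guesses come from a
log-linear fit of the relaxation tail (decay rate `k_on + k_off`, split
by the observed extent of inactivation) and the peak current; a guess
outside the bounds is projected onto them with a warning.

If the trace records the low-pass filter it went through, the same
causal 4-pole Bessel filter is applied to the model current before
computing residuals. This matched-filter fitting removes the small
systematic bias the recording filter would otherwise imprint on the rate
estimates; unfiltered traces are fitted with the raw model.

The fit window defaults to step onset → end of trace, with the baseline
estimated from the pre-step samples. Cohorts are fitted per trace
(patches differ in channel count, so `iN` is always per-trace) and
summarised as mean ± SD of `k_on` and `k_off`; failed traces are flagged
and excluded from the summary, never dropped silently.

`estimate_activation_rates` frees all six rates plus one `iN` per trace.
A single macroscopic trace determines at most six waveform quantities
(three eigenvalues, two amplitude ratios, one scale), so this
seven-parameter problem is degenerate along a one-dimensional manifold,
and `a1`/`a2` are exactly exchangeable (a forward cascade is a
convolution, which is order-invariant). `fix_deactivation=True` pins
`b1, b2` at their supplied values (zero at +60 mV), making the remaining
rates identifiable up to the `a1 <-> a2` exchange; estimates should be
interpreted as the unordered pair.

`sensitivity_analysis` refits after scaling each frozen activation rate
by (1 ± p) and reports relative changes in `k_on`, `k_off` and the
extent of inactivation. The perturbation response falls with the
activation/inactivation timescale separation: at 10× separation a 20%
activation perturbation still moves fitted `k_on` by ~7%, dropping below
2% near 50× and below 1% at 100×. The suite asserts this decay rather
than a fixed threshold at 10×.

`extent_of_inactivation` is `1 − steady/peak` on data (steady = mean of
the trailing 5% of post-onset samples) and `k_on/(k_on + k_off)` on
fitted rates when deactivation is zero; the two coincide in the
timescale-separated limit only, since a finite activation rate lowers
the observed peak.

## Energetics and the four-site binding model

`K_eq = k_on/k_off` and `ΔG = −ln K_eq` in RT units, so stronger
inactivation is more negative (the sign is a convention flag on
`free_energy`). With `n` of the four cavity sites carrying the
isoleucine→valine substitution,

```
K(n) = (4 − n) · K_I · (1 + ε)ⁿ + n · K_V
```

the single gate binds one site, so per-site constants add; each valine
boosts only the remaining isoleucine sites, multiplicatively by default
(`(1+ε)ⁿ`; the additive `1 + nε` form is available and differs by <2%
for n ≤ 3 at ε = 0.08). Only the valine count enters — position-labelled
measurements are pooled by count, mirroring the observation that
single-subunit substitutions are indistinguishable by position. The
endpoints `K(0) = 4K_I` and `K(4) = 4K_V` are ε-invariant; the per-site
constants are taken as the endpoint group means divided by 4 (using
`K_site = K_total` instead would rescale `K_I, K_V` jointly without
changing ε or the curve shape). ε is then estimated by least squares on
the intermediate counts, in ΔG space by default (`space="keq"` fits the
equilibrium constants instead; on noiseless data both recover ε
exactly). Note that even at ε = 0 the curve `−ln K(n)` is not linear in
n; ε quantifies curvature beyond that independent-site baseline.

## Synthetic data generator

The generator emulates inside-out patch recordings as the analysis
assumes them:

* protocol: −80 mV holding, +60 mV step, 10 kHz sampling, a short
  pre-step baseline; durations are chosen per construct so the slowest
  relaxation (`k_on + k_off`) is covered ~6 time constants;
* bandwidth: causal 4-pole Bessel low-pass at 2 kHz applied to the model
  current and to the noise (instrumentation noise is band-limited too);
  filtered noise is rescaled so its sample SD equals the requested
  amplitude;
* noise: Gaussian, default 2% of the noiseless peak;
* patch structure: patch-level `k_on, k_off` drawn once per patch,
  lognormal with mean equal to the generative value and CV 15%
  (mean-parameterised so cohort averages are unbiased); `iN` lognormal
  with median 200 pA and CV 0.5; traces within a patch share rates and
  `iN` and differ only in noise;
* free-energy datasets: for each valine count 0…4 and each construct
  label of the valine series (WT; 1V…4V; 1V4V, 2V4V; 1V2V3V, 2V3V4V;
  1V2V3V4V), `ΔG(n)` plus Gaussian noise of SD 0.1 RT, 10 values per
  construct by default.

Noise amplitude and patch scatter are not reported for the original
recordings; the defaults are calibrated so replicate-fit SDs land in the
range of the reported legend SDs (≈19% CV on `k_on`) and are exposed in
configuration — they are emulation choices, not ground truth. All
generators are bit-reproducible from a single integer seed via
`numpy.random.SeedSequence` child streams.

What the generator does **not** emulate: capacitive transients, series
resistance, leak subtraction, C-type inactivation (absent in the
T449V background the constructs share), drift, or any voltage dependence
of the rates. Passing recovery tests therefore demonstrates estimator
correctness under the stated statistical structure, not robustness to
these artifacts.

## Statistical renderings in the test suite

* **Cohort recovery** is judged against the realized patch-level rates
  recorded in the generator manifest, not the nominal population value:
  comparing to the nominal value at 1 SEM would conflate estimator error
  with the finite-sample scatter of the cohort draw itself and fail ~32%
  of the time for a perfect estimator.
* **Estimator bias** under 2% noise is measured with antithetic noise
  pairs (+ε/−ε): the first-order noise contribution to the mean error
  cancels exactly, so the mean error estimates genuine bias with
  variance far below the SEM it is compared against.
* **Gillespie agreement** normalises deviations by the binomial SE.
  Because all grid points share the same channels, single ensembles
  routinely show ~3.5 SE excursions spanning neighbouring samples; the
  test therefore pools four independent replicate ensembles per rate set
  and requires unit-scale counting noise (pooled mean z² < 2, calibrated
  range ≈ 0.7–1.4 across replicates; a sustained 3-SE bias would add ≈ 9)
  plus a hard 5-SE cap on the replicate-mean deviation.

## Problem sizes

Defaults keep every analysis interactive: traces are 10 kHz × tens of
ms (300–1300 samples), cohorts tens of traces, the Gillespie oracle 10⁵
channels, cooperativity recovery 200 Monte-Carlo datasets. The
acceptance script mirrors the reported per-construct cohort sizes
(5 patches/43 traces, 7/68, 10/114) and completes in well under a
minute.

## Known limitations

* Single-channel dwell-time analysis, voltage-dependent rate laws and
  C-type inactivation are out of scope.
* No profile-likelihood or bootstrap uncertainties on fits; cohort SDs
  are the dispersion measure.
* The binding-model fit treats the endpoint groups as exact anchors for
  `K_I`/`K_V`; endpoint noise propagates into them rather than into ε.
* Two-valine arrangements (adjacent vs diagonal) are not distinguished;
  the model depends on the count only.
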