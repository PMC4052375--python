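# kvinact

Kinetic and energetic analysis of **N-type (ball-and-chain) inactivation**
in Shaker-type voltage-gated K⁺ channels, for electrophysiologists and
modellers working with macroscopic current recordings.

After a depolarising step, Shaker channels activate and then inactivate
within milliseconds as a cytoplasmic N-terminal "ball" binds in the open
pore. The package models this with a reversible four-state Markov chain

```
C1 <-> C2 <-> O <-> I          (states: closed, closed, open, inactivated)
```

with macroscopic current `I(t) = iN · P_O(t)`, where `iN` is channel
count × unitary current. The open↔inactivated rates `k_on`, `k_off`
define the inactivation equilibrium

```
K_eq = k_on / k_off,      ΔG = −ln(K_eq)   [RT units]
```

and the mean dwell time of the ball in the pore is `1/k_off`.

On top of the kinetics sit two analyses:

* **Constrained trace fitting** — Levenberg–Marquardt estimation of
  `(k_on, k_off, iN)` from voltage-step traces with the activation rates
  held fixed, box bounds on `k_on` (e.g. a reference mean ± SD) and the
  cap `iN ≤ 3 × max observed current`, plus a sensitivity analysis of
  the frozen activation rates.
* **Four-site cooperative binding model** — a single gate binds one of
  the four subunit sites lining the intracellular cavity. With `n`
  subunits carrying the cavity I470V substitution,

  ```
  K(n) = (4 − n) · K_I · (1 + ε)ⁿ + n · K_V
  ```

  each valine boosting the apparent affinity of the remaining isoleucine
  sites by the fraction ε. `ΔG(n) = −ln K(n)` is fitted to grouped
  free-energy measurements keyed by valine count.

Because the original recordings are not deposited, a synthetic-data
module (`kvinact.synth`) emulates inside-out patch cohorts — 10 kHz
sampling, 4-pole 2 kHz low-pass filtering, band-limited Gaussian noise,
lognormal patch-to-patch scatter — and provides an exact Gillespie
ensemble simulator used as an independent oracle for the deterministic
propagator.

## Worked example

```python
from kvinact import (DEFAULT_ACTIVATION, BindingModel, FitConstraints,
                     default_rates, equilibrium_constant, extent_of_inactivation,
                     fit_cohort, fit_cooperativity, mean_dwell_time)
from kvinact.synth import PatchCohortSpec, generate_cohort, generate_dg_dataset

# 7 synthetic patches x 10 traces of a one-gate (concatemer) channel
spec = PatchCohortSpec(rates=default_rates(k_on=108.0, k_off=40.0),
                       n_patches=7, traces_per_patch=10, seed=42)
fit = fit_cohort(generate_cohort(spec),
                 FitConstraints(fixed_activation=DEFAULT_ACTIVATION))
print(f"k_on  = {fit.k_on:6.1f} +- {fit.k_on_sd:4.1f} s^-1   (n = {fit.n_traces} traces)")
print(f"k_off = {fit.k_off:6.1f} +- {fit.k_off_sd:4.1f} s^-1")
eq = equilibrium_constant(fit.k_on, fit.k_off)
print(f"K_eq  = {eq.K_eq:.2f}, dG = {eq.delta_G:+.3f} RT")
print(f"extent of inactivation = {extent_of_inactivation(fit):.3f}")
print(f"mean inactivated dwell time = {mean_dwell_time(fit.k_off):.1f} ms")

# free-energy vs valine-count data from the four-site model, refit
model = BindingModel(K_I=2.70 / 4, K_V=0.552 / 4, epsilon=0.08)
data = generate_dg_dataset(model, n_per_group=10, dg_noise_sd=0.1, seed=42)
print(f"epsilon = {fit_cooperativity(data).epsilon:.3f}")
```

prints

```
k_on  =  106.7 +- 12.9 s^-1   (n = 70 traces)
k_off =   41.4 +-  6.7 s^-1
K_eq  = 2.58, dG = -0.946 RT
extent of inactivation = 0.720
mean inactivated dwell time = 24.1 ms
epsilon = 0.051
```

The cohort mean recovers the generative one-gate rates (108, 40 s⁻¹)
within the patch-to-patch scatter (15% CV); the channel inactivates by
~72% at steady state and the gate stays bound for ~24 ms on average.
The cooperativity estimate from a single noisy dataset scatters around
the generative ε = 0.08; averaging over many datasets converges on it
(see the test suite).

A `kvinact` console command wraps the same pipeline for shell use:
`kvinact simulate`, `kvinact fit` (with `--sensitivity`),
`kvinact energetics` and `kvinact recover`, all driven by JSON configs;
traces are plain two-column CSV (`time_ms,current_pA`) with a JSON
sidecar.

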