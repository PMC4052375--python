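"""Constrained Levenberg–Marquardt estimation of inactivation kinetics
from macroscopic current traces.

Only ``k_on``, ``k_off`` and the scale factor ``iN`` are free when
fitting a trace; the activation rates (a1, b1, a2, b2) are held fixed,
having been estimated once from channels whose activation is directly
observable (homotetramers and the wild-type concatemer).  Constraints
mirror recording practice: ``k_on`` may be boxed to the wild-type
concatemer mean ± SD, and ``iN`` is capped at a multiple (default 3) of
the largest observed current of the trace being fit.

If a trace records the low-pass filter it went through
(``CurrentTrace.filter_cutoff``), the same causal filter is applied to
the model current before computing residuals, so the filter does not
bias the rate estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .kinetics import CurrentTrace, RateSet, propagate_occupancy, steady_state

__all__ = [
    "FitConstraints",
    "FitResult",
    "ActivationEstimate",
    "estimate_activation_rates",
    "fit_inactivation",
    "fit_cohort",
    "extent_of_inactivation",
    "sensitivity_analysis",
]

logger = logging.getLogger(__name__)

#: LM stopping tolerances (gradient, step) and evaluation budget.
_GTOL = 1e-8
_XTOL = 1e-10
_MAX_NFEV = 2000

#: Relative closeness to a box bound at which a parameter estimate is
#: reported as constraint-limited.
_BOUND_TOL = 1e-3


@dataclass(frozen=True)
class FitConstraints:
    """Box constraints and fixed parameters for an inactivation fit.

    ``k_on_bounds`` is ``(lo, hi)`` in s^-1 or ``None`` for a free k_on;
    ``iN_max_multiplier`` caps iN at that multiple of the trace's own
    maximum absolute current; ``fixed_activation`` is ``(a1, b1, a2, b2)``
    in s^-1; ``fit_window`` is an absolute ``(t_lo, t_hi)`` in ms, or
    ``None`` for the whole post-onset trace.
    """

    fixed_activation: tuple[float, float, float, float]
    k_on_bounds: tuple[float, float] | None = None
    iN_max_multiplier: float = 3.0
    fit_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.iN_max_multiplier <= 0:
            raise ValueError("iN_max_multiplier must be positive")
        if self.k_on_bounds is not None:
            lo, hi = self.k_on_bounds
            if lo < 0:
                raise ValueError("k_on lower bound must be non-negative")
            if hi <= lo:
                raise ValueError("k_on bound interval is empty")
        if len(self.fixed_activation) != 4 or any(v < 0 for v in self.fixed_activation):
            raise ValueError("fixed_activation must be four non-negative rates")


@dataclass
class FitResult:
    """Fitted (k_on, k_off, iN) with diagnostics.

    For cohort fits, ``k_on``/``k_off`` hold the across-trace means,
    ``k_on_sd``/``k_off_sd`` the standard deviations, and
    ``per_trace_results`` the individual fits (failed traces appear with
    ``converged=False`` and NaN parameters).
    """

    k_on: float
    k_off: float
    iN: float
    residual_sum_of_squares: float
    n_iterations: int
    converged: bool
    active_constraints: list[str] = field(default_factory=list)
    label: str = ""
    k_on_sd: float | None = None
    k_off_sd: float | None = None
    n_traces: int | None = None
    per_trace_results: list["FitResult"] | None = None

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "k_on": self.k_on,
            "k_off": self.k_off,
            "iN": self.iN,
            "rss": self.residual_sum_of_squares,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "active_constraints": list(self.active_constraints),
        }
        if self.n_traces is not None:
            d.update(k_on_sd=self.k_on_sd, k_off_sd=self.k_off_sd, n_traces=self.n_traces)
        return d


@dataclass
class ActivationEstimate:
    """Activation-pathway rates estimated from reference traces."""

    a1: float
    b1: float
    a2: float
    b2: float
    source_traces: list[str]
    residual_sum_of_squares: float
    converged: bool = True

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a1, self.b1, self.a2, self.b2)


# ---------------------------------------------------------------------------
# model evaluation


def _trace_filter_sos(trace: CurrentTrace):
    """Causal 4-pole Bessel low-pass matching the trace's recorded filter."""
    from scipy.signal import bessel

    fc = trace.filter_cutoff
    sr = trace.protocol.sample_rate
    if fc is None or fc >= 0.99 * sr / 2:
        return None
    return bessel(4, fc, btype="low", fs=sr, output="sos")


def _model_current(trace: CurrentTrace, rates: RateSet, iN: float, sos) -> np.ndarray:
    k = trace.protocol.onset_index
    t = trace.times
    cur = np.zeros_like(t)
    traj = propagate_occupancy(rates, [1.0, 0.0, 0.0, 0.0], t[k:] - t[k])
    cur[k:] = iN * traj.p_open
    if sos is not None:
        from scipy.signal import sosfilt

        cur = sosfilt(sos, cur)
    return cur


def _baseline_subtracted(trace: CurrentTrace) -> np.ndarray:
    k = trace.protocol.onset_index
    data = trace.current.astype(float)
    if k > 0:
        data = data - data[:k].mean()
    return data


def _window_mask(trace: CurrentTrace, constraints: FitConstraints) -> np.ndarray:
    t = trace.times
    if constraints.fit_window is None:
        lo = trace.protocol.pre_step_baseline
        hi = t[-1]
    else:
        lo, hi = constraints.fit_window
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise ValueError("fit_window must lie within the trace extent")
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)


def _initial_guess(trace: CurrentTrace, data: np.ndarray) -> tuple[float, float, float]:
    """Heuristic (k_on, k_off, iN) start: decay rate from a log-linear fit
    of the relaxation tail, split by the observed extent of inactivation."""
    k = trace.protocol.onset_index
    t = trace.times
    post = data[k:]
    if post.size < 4 or np.max(post) <= 0:
        raise ValueError("no current to fit")
    ipk = int(np.argmax(post))
    peak = post[ipk]
    tail = post[-max(3, post.size // 10):]
    ss = float(tail.mean())
    extent = float(np.clip(1.0 - ss / peak, 1e-3, 0.999))
    lam_s = 400.0  # fallback decay rate, s^-1
    y = post[ipk:] - ss
    tt = t[k + ipk:] - t[k + ipk]
    sel = y > 0.05 * (peak - ss)
    if sel.sum() >= 5:
        coef = np.polyfit(tt[sel], np.log(y[sel]), 1)
        lam = -coef[0] * 1000.0  # ms^-1 -> s^-1
        if np.isfinite(lam):
            lam_s = float(np.clip(lam, 1.0, 5000.0))
    return lam_s * extent, lam_s * (1.0 - extent), float(peak) * 1.05


def fit_inactivation(
    trace: CurrentTrace,
    constraints: FitConstraints,
    initial_guess: tuple[float, float, float] | None = None,
) -> FitResult:
    """Fit (k_on, k_off, iN) to one trace by bounded Levenberg–Marquardt.

    Activation rates come from ``constraints.fixed_activation``.  Bound
    constraints are enforced throughout the optimisation; an estimate
    pinned at a bound is listed in ``active_constraints``.
    """
    data = _baseline_subtracted(trace)
    mask = _window_mask(trace, constraints)
    sos = _trace_filter_sos(trace)
    if initial_guess is None:
        k_on0, k_off0, iN0 = _initial_guess(trace, data)
    else:
        k_on0, k_off0, iN0 = (float(v) for v in initial_guess)
        if np.max(data[trace.protocol.onset_index:], initial=0.0) <= 0:
            raise ValueError("no current to fit")

    iN_max = constraints.iN_max_multiplier * float(np.max(np.abs(data)))
    if iN_max <= 0:
        raise ValueError("no current to fit")
    if constraints.k_on_bounds is None:
        k_on_lo, k_on_hi = 1e-6, np.inf
    else:
        k_on_lo, k_on_hi = (max(constraints.k_on_bounds[0], 1e-6), constraints.k_on_bounds[1])

    def clipped(name, v, lo, hi):
        c = float(np.clip(v, lo * (1 + 1e-9) if np.isfinite(lo) else lo, hi * (1 - 1e-9) if np.isfinite(hi) else hi))
        if c != v:
            warnings.warn(f"initial {name}={v:g} outside bounds [{lo:g}, {hi:g}]; projected to {c:g}")
        return c

    params = Parameters()
    params.add("k_on", value=clipped("k_on", k_on0, k_on_lo, k_on_hi), min=k_on_lo, max=k_on_hi)
    params.add("k_off", value=clipped("k_off", k_off0, 1e-6, np.inf), min=1e-6)
    params.add("iN", value=clipped("iN", iN0, 1e-9, iN_max), min=1e-9, max=iN_max)

    a1, b1, a2, b2 = constraints.fixed_activation

    def residual(p):
        rates = RateSet(a1, b1, a2, b2, p["k_on"].value, p["k_off"].value)
        return (_model_current(trace, rates, p["iN"].value, sos) - data)[mask]

    rss0 = float(np.sum(residual(params) ** 2))
    out = minimize(
        residual, params, method="leastsq",
        xtol=_XTOL, ftol=_GTOL, gtol=_GTOL, max_nfev=_MAX_NFEV,
    )
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    converged = bool(out.success) and rss <= rss0 * (1 + 1e-12) + 1e-300

    k_on = float(out.params["k_on"].value)
    k_off = float(out.params["k_off"].value)
    iN = float(out.params["iN"].value)
    active: list[str] = []
    if constraints.k_on_bounds is not None:
        if k_on <= k_on_lo * (1 + _BOUND_TOL):
            active.append("k_on_lower")
        if np.isfinite(k_on_hi) and k_on >= k_on_hi * (1 - _BOUND_TOL):
            active.append("k_on_upper")
    if iN >= iN_max * (1 - _BOUND_TOL):
        active.append("iN_upper")

    return FitResult(
        k_on=k_on, k_off=k_off, iN=iN,
        residual_sum_of_squares=rss,
        n_iterations=int(out.nfev),
        converged=converged,
        active_constraints=active,
        label=trace.label,
    )


def fit_cohort(traces, constraints: FitConstraints) -> FitResult:
    """Fit each trace independently and summarise k_on/k_off as mean ± SD.

    The iN cap is evaluated per trace from that trace's own maximum.
    Traces whose fit raises or fails to converge stay in
    ``per_trace_results`` (flagged) but are excluded from the summary.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("fit_cohort requires at least one trace")
    per_trace: list[FitResult] = []
    for tr in traces:
        try:
            per_trace.append(fit_inactivation(tr, constraints))
        except Exception as exc:  # degenerate trace: keep the cohort going
            warnings.warn(f"trace {tr.label!r} failed to fit: {exc}")
            per_trace.append(
                FitResult(np.nan, np.nan, np.nan, np.nan, 0, False, ["fit_error"], tr.label)
            )
    good = [r for r in per_trace if r.converged]
    if not good:
        raise ValueError("no trace in the cohort could be fit")
    k_on = np.array([r.k_on for r in good])
    k_off = np.array([r.k_off for r in good])
    return FitResult(
        k_on=float(k_on.mean()),
        k_off=float(k_off.mean()),
        iN=float(np.mean([r.iN for r in good])),
        residual_sum_of_squares=float(np.sum([r.residual_sum_of_squares for r in good])),
        n_iterations=int(np.sum([r.n_iterations for r in good])),
        converged=len(good) == len(per_trace),
        label=traces[0].label,
        k_on_sd=float(k_on.std(ddof=1)) if len(good) > 1 else 0.0,
        k_off_sd=float(k_off.std(ddof=1)) if len(good) > 1 else 0.0,
        n_traces=len(good),
        per_trace_results=per_trace,
    )


def extent_of_inactivation(obj, fixed_activation=None) -> float:
    """Fraction of the peak current lost at steady state, in [0, 1].

    For a ``FitResult`` with no deactivation this is the closed form
    ``k_on / (k_on + k_off)``; with non-zero deactivation rates it is
    computed from the model's stationary and peak open probabilities.
    For a ``CurrentTrace`` it is ``1 - steady / peak`` measured from the
    data (steady = mean of the last 5% of post-onset samples).
    """
    if isinstance(obj, FitResult):
        if obj.k_on + obj.k_off <= 0:
            raise ValueError("rates must be positive")
        if fixed_activation is None or (fixed_activation[1] == 0 and fixed_activation[3] == 0):
            return obj.k_on / (obj.k_on + obj.k_off)
        a1, b1, a2, b2 = fixed_activation
        rates = RateSet(a1, b1, a2, b2, obj.k_on, obj.k_off)
        p_inf = steady_state(rates)[2]
        t = np.linspace(0, 200.0, 4001)
        p_peak = propagate_occupancy(rates, [1, 0, 0, 0], t).p_open.max()
        return float(1.0 - p_inf / p_peak)
    if isinstance(obj, CurrentTrace):
        data = _baseline_subtracted(obj)[obj.protocol.onset_index:]
        peak = float(np.max(data, initial=-np.inf))
        if peak <= 0:
            raise ValueError("trace has no positive peak")
        steady = float(data[-max(2, data.size // 20):].mean())
        return float(np.clip(1.0 - steady / peak, 0.0, 1.0))
    raise TypeError("expected a CurrentTrace or FitResult")


def sensitivity_analysis(
    trace: CurrentTrace,
    constraints: FitConstraints,
    perturbation: float = 0.2,
) -> pd.DataFrame:
    """Refit after scaling each fixed activation rate by (1 ± perturbation).

    Returns one row per (rate, scale factor) with the relative change in
    fitted k_on, k_off and in the extent of inactivation, so the impact
    of the frozen activation rates on the inactivation estimates can be
    judged.  A failed perturbed fit is flagged, not dropped.
    """
    base = fit_inactivation(trace, constraints)
    if not base.converged:
        raise ValueError("baseline fit did not converge")
    base_ext = extent_of_inactivation(base, constraints.fixed_activation)
    rows = []
    names = ("a1", "b1", "a2", "b2")
    for i, name in enumerate(names):
        for factor in (1.0 - perturbation, 1.0 + perturbation):
            perturbed = list(constraints.fixed_activation)
            perturbed[i] *= factor
            c = FitConstraints(
                fixed_activation=tuple(perturbed),
                k_on_bounds=constraints.k_on_bounds,
                iN_max_multiplier=constraints.iN_max_multiplier,
                fit_window=constraints.fit_window,
            )
            row = {"parameter": name, "factor": factor, "converged": False,
                   "rel_dk_on": np.nan, "rel_dk_off": np.nan, "rel_dextent": np.nan}
            try:
                res = fit_inactivation(trace, c)
                ext = extent_of_inactivation(res, c.fixed_activation)
                row.update(
                    converged=res.converged,
                    rel_dk_on=(res.k_on - base.k_on) / base.k_on,
                    rel_dk_off=(res.k_off - base.k_off) / base.k_off,
                    rel_dextent=(ext - base_ext) / base_ext if base_ext else np.nan,
                )
            except Exception as exc:
                logger.warning("perturbed fit (%s x %g) failed: %s", name, factor, exc)
            rows.append(row)
    return pd.DataFrame(rows)


def estimate_activation_rates(
    traces, initial_guess: RateSet, fix_deactivation: bool = False
) -> ActivationEstimate:
    """Estimate the activation rates (a1, b1, a2, b2) from reference traces.

    All six rates plus one iN per trace are free; the summed squared
    residual over the supplied traces is minimised by LM starting from
    ``initial_guess``.  The returned activation rates are what the
    inactivation fits subsequently hold fixed.  Deterministic given the
    guess and the data; non-convergence is flagged, never silent.

    A single macroscopic trace carries at most six independent waveform
    quantities (three eigenvalues, two amplitude ratios, one scale), so
    with all six rates and iN free the solution lies on a degenerate
    manifold; ``fix_deactivation=True`` pins b1 and b2 at the guess
    values (zero at a strong depolarisation), which makes the remaining
    rates identifiable up to the exact a1 <-> a2 exchange symmetry.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("at least one trace is required")
    proto0 = traces[0].protocol
    for tr in traces[1:]:
        if (tr.protocol.sample_rate != proto0.sample_rate
                or tr.protocol.duration != proto0.duration
                or tr.protocol.pre_step_baseline != proto0.pre_step_baseline):
            raise ValueError("all traces must share one protocol")
    datas = [_baseline_subtracted(tr) for tr in traces]
    peaks = [float(np.max(d[tr.protocol.onset_index:], initial=0.0)) for tr, d in zip(traces, datas)]
    if max(peaks) <= 0:
        raise ValueError("no current to fit")
    soses = [_trace_filter_sos(tr) for tr in traces]

    params = Parameters()
    for name in ("a1", "b1", "a2", "b2", "k_on", "k_off"):
        v = getattr(initial_guess, name)
        if fix_deactivation and name in ("b1", "b2"):
            params.add(name, value=v, vary=False)
        else:
            params.add(name, value=max(v, 1e-3), min=0.0 if v == 0 else 1e-6)
    for j, pk in enumerate(peaks):
        params.add(f"iN_{j}", value=max(pk, 1e-6) * 1.05, min=1e-9)

    def residual(p):
        rates = RateSet(p["a1"].value, p["b1"].value, p["a2"].value,
                        p["b2"].value, p["k_on"].value, p["k_off"].value)
        parts = [
            _model_current(tr, rates, p[f"iN_{j}"].value, sos) - d
            for j, (tr, d, sos) in enumerate(zip(traces, datas, soses))
        ]
        return np.concatenate(parts)

    out = minimize(residual, params, method="leastsq",
                   xtol=_XTOL, ftol=_GTOL, gtol=_GTOL, max_nfev=10 * _MAX_NFEV)
    return ActivationEstimate(
        a1=float(out.params["a1"].value),
        b1=float(out.params["b1"].value),
        a2=float(out.params["a2"].value),
        b2=float(out.params["b2"].value),
        source_traces=[tr.label for tr in traces],
        residual_sum_of_squares=float(np.sum(np.asarray(out.residual) ** 2)),
        converged=bool(out.success),
    )
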