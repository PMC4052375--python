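"""Synthetic inside-out patch recordings and a Gillespie reference simulator.

The generators emulate the statistical structure the analysis assumes:
currents sampled at 10 kHz through a 4-pole 2 kHz low-pass filter,
band-limited Gaussian instrumentation noise, patch-to-patch lognormal
scatter of channel count (iN) and of the gate rates, and grouped
free-energy datasets with the construct labels of the valine-count
series.  ``gillespie_reference`` is an exact event-driven simulation of
an ensemble of independent channels, used as a brute-force oracle for
the deterministic master-equation propagator — it shares no code with
it beyond the rate definitions.

All generators are reproducible from a single integer seed; child
streams are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import bessel, sosfilt

from .energetics import BindingModel, binding_model_keq, free_energy
from .kinetics import CurrentTrace, GatingProtocol, RateSet, simulate_current

__all__ = [
    "NoiseModel",
    "PatchCohortSpec",
    "CONSTRUCT_LABELS",
    "generate_trace",
    "generate_cohort",
    "cohort_manifest",
    "generate_dg_dataset",
    "gillespie_occupancy",
    "gillespie_reference",
]

#: Construct labels of the valine-count series, keyed by number of I470V
#: subunits (0V = wild-type concatemer ... 4 = all subunits mutated).
CONSTRUCT_LABELS: dict[int, tuple[str, ...]] = {
    0: ("WT",),
    1: ("1V", "2V", "3V", "4V"),
    2: ("1V4V", "2V4V"),
    3: ("1V2V3V", "2V3V4V"),
    4: ("1V2V3V4V",),
}


@dataclass(frozen=True)
class NoiseModel:
    """Recording noise and bandwidth emulation.

    ``gaussian_sd`` is the noise standard deviation, either as a
    fraction of the noiseless peak current (``sd_units='fraction_of_peak'``,
    default) or in pA (``sd_units='pA'``).  ``filter_cutoff`` is the
    low-pass corner in kHz (4-pole Bessel, as in patch-clamp amplifiers),
    applied to the model current and to the noise alike; noise is
    rescaled after filtering so its sample SD equals ``gaussian_sd``.
    """

    gaussian_sd: float = 0.02
    sd_units: str = "fraction_of_peak"
    filter_cutoff: float = 2.0  # kHz

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be non-negative")
        if self.filter_cutoff <= 0:
            raise ValueError("filter_cutoff must be positive")
        if self.sd_units not in ("fraction_of_peak", "pA"):
            raise ValueError("sd_units must be 'fraction_of_peak' or 'pA'")


@dataclass(frozen=True)
class PatchCohortSpec:
    """Generative description of a multi-patch recording cohort.

    Patch-level gate rates are drawn once per patch, lognormal with mean
    equal to the generative value and coefficient of variation
    ``rate_scatter`` (so cohort means are unbiased); ``iN`` is lognormal
    with the given median and CV.  Traces within a patch share the
    patch's rates and iN and differ only in noise.  Defaults mirror the
    reported cohorts: ~5-10 patches with ~10 traces each.
    """

    rates: RateSet
    n_patches: int = 7
    traces_per_patch: int = 10
    iN_median: float = 200.0  # pA
    iN_cv: float = 0.5
    rate_scatter: float = 0.15  # CV of patch-level k_on, k_off
    protocol: GatingProtocol = field(default_factory=GatingProtocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    label: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1 or self.traces_per_patch < 1:
            raise ValueError("n_patches and traces_per_patch must be >= 1")
        if self.iN_cv < 0 or self.rate_scatter < 0:
            raise ValueError("CVs must be non-negative")
        if self.iN_median <= 0:
            raise ValueError("iN_median must be positive")


def _filter_sos(cutoff_khz: float, sample_rate_khz: float):
    if cutoff_khz >= 0.99 * sample_rate_khz / 2:
        return None  # at/above Nyquist: identity
    return bessel(4, cutoff_khz, btype="low", fs=sample_rate_khz, output="sos")


def _filtered_noise(rng: np.random.Generator, n: int, sd: float, sos) -> np.ndarray:
    """Band-limited Gaussian noise with sample SD ``sd`` after filtering."""
    white = rng.standard_normal(n)
    if sos is None or sd == 0:
        return sd * white
    # noise gain of the filter from its impulse response
    m = max(n, 4096)
    h = sosfilt(sos, np.r_[1.0, np.zeros(m - 1)])
    gain = math.sqrt(float(np.sum(h * h)))
    return sd / gain * sosfilt(sos, white)


def generate_trace(
    rates: RateSet,
    iN: float,
    protocol: GatingProtocol,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> CurrentTrace:
    """One synthetic current trace: filtered model current plus noise.

    Deterministic given the seed.  ``iN_true`` and the filter cutoff are
    recorded on the trace so fits can be scored against ground truth and
    can match the filter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = simulate_current(rates, iN, protocol, label=label)
    sos = _filter_sos(noise.filter_cutoff, protocol.sample_rate)
    current = clean.current if sos is None else sosfilt(sos, clean.current)
    sd = noise.gaussian_sd
    if noise.sd_units == "fraction_of_peak":
        sd *= float(np.max(clean.current))
    current = current + _filtered_noise(rng, current.size, sd, sos)
    return CurrentTrace(
        times=clean.times,
        current=current,
        protocol=protocol,
        label=label,
        iN_true=iN,
        filter_cutoff=noise.filter_cutoff if sos is not None else None,
        meta={"k_on_true": rates.k_on, "k_off_true": rates.k_off},
    )


def _lognormal_mean(rng, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2)))


def _lognormal_median(rng, median: float, cv: float) -> float:
    if cv == 0:
        return median
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(math.log(median), math.sqrt(s2)))


def generate_cohort(spec: PatchCohortSpec) -> list[CurrentTrace]:
    """Synthetic patch cohort: patch-labelled traces, reproducible by seed."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_patches)
    traces: list[CurrentTrace] = []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        k_on_p = _lognormal_mean(rng, spec.rates.k_on, spec.rate_scatter)
        k_off_p = _lognormal_mean(rng, spec.rates.k_off, spec.rate_scatter)
        iN_p = _lognormal_median(rng, spec.iN_median, spec.iN_cv)
        patch_rates = spec.rates.replace(k_on=k_on_p, k_off=k_off_p)
        for t in range(spec.traces_per_patch):
            tr = generate_trace(
                patch_rates, iN_p, spec.protocol, spec.noise,
                seed=rng, label=spec.label,
            )
            tr.meta.update(patch=p, trace=t, cohort_seed=spec.seed)
            traces.append(tr)
    return traces


def cohort_manifest(traces) -> pd.DataFrame:
    """Tabulate generator provenance (patch, true rates, true iN) per trace."""
    rows = []
    for tr in traces:
        rows.append(
            {
                "label": tr.label,
                "patch": tr.meta.get("patch"),
                "trace": tr.meta.get("trace"),
                "seed": tr.meta.get("cohort_seed"),
                "k_on_true": tr.meta.get("k_on_true"),
                "k_off_true": tr.meta.get("k_off_true"),
                "iN_true": tr.iN_true,
            }
        )
    return pd.DataFrame(rows)


def generate_dg_dataset(
    model: BindingModel,
    n_per_group: int = 10,
    dg_noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped free-energy measurements for the valine-count series.

    For every valine count n = 0..4 and every construct label at that
    count, draws ``n_per_group`` values of the model dG(n) plus Gaussian
    noise (SD in RT units).  Columns: construct_label, n_valine, delta_g.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(model.n_sites + 1):
        dg = free_energy(binding_model_keq(model, n))
        for lab in CONSTRUCT_LABELS.get(n, (f"{n}V_construct",)):
            vals = dg + dg_noise_sd * rng.standard_normal(n_per_group)
            for v in vals:
                rows.append({"construct_label": lab, "n_valine": n, "delta_g": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gillespie oracle


def gillespie_occupancy(
    rates: RateSet,
    times_ms: np.ndarray,
    n_channels: int,
    seed: int = 0,
) -> np.ndarray:
    """Exact stochastic state counts of an ensemble of independent channels.

    Event-driven simulation of the aggregate counts of ``n_channels``
    4-state chains starting in C1 at t = 0; returns the integer count
    matrix (n_times, 4) sampled at ``times_ms``.  Independent of the
    deterministic propagator by construction.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    t_grid = np.asarray(times_ms, dtype=float) / 1000.0  # s
    edges = [
        (0, 1, rates.a1), (1, 0, rates.b1), (1, 2, rates.a2),
        (2, 1, rates.b2), (2, 3, rates.k_on), (3, 2, rates.k_off),
    ]
    edges = [(i, j, r) for i, j, r in edges if r > 0]
    counts = [n_channels, 0, 0, 0]
    out = np.empty((t_grid.size, 4), dtype=np.int64)
    rng = np.random.default_rng(seed)
    buf = rng.random(1 << 16)
    pos = 0

    def draw() -> float:
        nonlocal buf, pos
        if pos == buf.size:
            buf = rng.random(1 << 16)
            pos = 0
        pos += 1
        return buf[pos - 1]

    t = 0.0
    g = 0
    n_grid = t_grid.size
    while g < n_grid:
        props = [counts[i] * r for i, _, r in edges]
        total = sum(props)
        if total == 0.0:
            break
        t_next = t - math.log(1.0 - draw()) / total
        while g < n_grid and t_grid[g] < t_next:
            out[g] = counts
            g += 1
        if g == n_grid:
            break
        u = draw() * total
        acc = 0.0
        for (i, j, _), pr in zip(edges, props):
            acc += pr
            if u <= acc:
                counts[i] -= 1
                counts[j] += 1
                break
        t = t_next
    while g < n_grid:
        out[g] = counts
        g += 1
    return out


def gillespie_reference(
    rates: RateSet,
    n_channels: int,
    protocol: GatingProtocol,
    seed: int = 0,
    iN: float | None = None,
) -> CurrentTrace:
    """Stochastic ensemble current, ``(iN / n_channels) * N_open(t)``.

    With ``iN`` omitted every channel carries 1 pA, so the trace equals
    the open-channel count.  Converges to ``iN * P_O(t)`` as the channel
    count grows (law of large numbers).
    """
    if iN is None:
        iN = float(n_channels)
    t = protocol.times()
    k = protocol.onset_index
    occ = gillespie_occupancy(rates, t[k:] - t[k], n_channels, seed=seed)
    current = np.zeros_like(t)
    current[k:] = (iN / n_channels) * occ[:, 2]
    return CurrentTrace(
        times=t, current=current, protocol=protocol,
        label=f"gillespie_n{n_channels}", iN_true=iN,
        meta={"n_channels": n_channels, "seed": seed},
    )
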