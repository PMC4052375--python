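"""Four-state Markov scheme for N-type inactivation of Shaker K+ channels.

The gating scheme is a reversible linear chain

    C1 <-> C2 <-> O <-> I

with two closed states, the open state and the N-type inactivated state
(the inactivation "ball" bound in the open pore).  At a strong
depolarisation the activation pathway C1 -> C2 -> O is fast and
essentially irreversible, after which the macroscopic current relaxes as
the open/inactivated equilibrium O <-> I (rates ``k_on``/``k_off``) is
established.  Macroscopic current is ``I(t) = iN * P_O(t)`` where ``iN``
lumps channel count times unitary current.

Conventions used throughout the package:

* state order ``(C1, C2, O, I)``;
* occupancy is a row vector evolving as ``dp/dt = p @ Q``;
* rates are per second, times are in milliseconds, currents in pA;
* membrane potentials are metadata only — no rate depends on voltage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "STATES",
    "RateSet",
    "GatingProtocol",
    "OccupancyTrajectory",
    "CurrentTrace",
    "build_generator",
    "propagate_occupancy",
    "steady_state",
    "simulate_current",
]

#: State order used for every occupancy vector / generator matrix.
STATES = ("C1", "C2", "O", "I")

_RATE_FIELDS = ("a1", "b1", "a2", "b2", "k_on", "k_off")

# Index of the open state in STATES.
OPEN = 2


@dataclass(frozen=True)
class RateSet:
    """The six transition rates of the C1<->C2<->O<->I chain, in s^-1.

    ``a1``/``a2`` are the forward activation rates C1->C2 and C2->O,
    ``b1``/``b2`` the corresponding deactivation rates, and
    ``k_on``/``k_off`` the open->inactivated binding and unbinding rates
    of the inactivation gate.  At +60 mV deactivation is negligible, so
    the package default sets ``b1 = b2 = 0``.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"rate {name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"rate {name!r} must be non-negative, got {v!r}")
            object.__setattr__(self, name, v)

    def replace(self, **changes: float) -> "RateSet":
        """Return a copy with the given rates replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _RATE_FIELDS}

    @property
    def activation(self) -> tuple[float, float, float, float]:
        """The four rates of the activation pathway, ``(a1, b1, a2, b2)``."""
        return (self.a1, self.b1, self.a2, self.b2)


#: Default activation rates at +60 mV: sub-millisecond activation
#: (two steps of 3000 s^-1 give an activation time constant well under
#: 1 ms, clearly faster than even homotetramer inactivation at 430 s^-1,
#: so the open probability approaches 1 before the gate binds), no
#: deactivation.  These ship as configuration values; any fitting
#: workflow re-estimates them from homotetramer/concatemer currents.
DEFAULT_ACTIVATION = (3000.0, 0.0, 3000.0, 0.0)


def default_rates(k_on: float, k_off: float) -> RateSet:
    """RateSet with the default +60 mV activation rates and given gate rates."""
    a1, b1, a2, b2 = DEFAULT_ACTIVATION
    return RateSet(a1, b1, a2, b2, k_on, k_off)


@dataclass(frozen=True)
class GatingProtocol:
    """A single voltage-step protocol.

    Holding and step potentials are recorded for provenance only; the
    kinetic model has no voltage dependence.  The time grid is uniform,
    ``t_i = i / sample_rate`` over ``pre_step_baseline + duration`` ms,
    with the depolarising step at ``t = pre_step_baseline``.
    """

    holding_potential: float = -80.0  # mV, metadata
    step_potential: float = 60.0  # mV, metadata
    duration: float = 90.0  # ms of depolarisation
    sample_rate: float = 10.0  # kHz
    pre_step_baseline: float = 5.0  # ms at holding potential

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.pre_step_baseline < 0:
            raise ValueError("pre_step_baseline must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_step_baseline + self.duration) * self.sample_rate)) + 1

    @property
    def onset_index(self) -> int:
        """Index of the first sample at or after the step onset."""
        return int(round(self.pre_step_baseline * self.sample_rate))

    def times(self) -> np.ndarray:
        """Uniform time grid in ms."""
        return np.arange(self.n_samples) / self.sample_rate

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class OccupancyTrajectory:
    """State occupancy probabilities on a time grid (rows sum to 1)."""

    times: np.ndarray  # ms
    occupancy: np.ndarray  # shape (n_times, 4), state order STATES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (self.times.size, len(STATES)):
            raise ValueError("occupancy must have shape (n_times, 4)")

    @property
    def p_open(self) -> np.ndarray:
        return self.occupancy[:, OPEN]


@dataclass
class CurrentTrace:
    """A macroscopic current trace with its protocol and provenance.

    ``iN_true`` is only set on synthetic traces; ``filter_cutoff`` (kHz)
    records the low-pass filter the trace went through, so a fitter can
    apply the same filter to its model.  ``meta`` carries free-form
    generator provenance (patch id, generative rates, seeds).
    """

    times: np.ndarray  # ms
    current: np.ndarray  # pA
    protocol: GatingProtocol
    label: str = ""
    iN_true: float | None = None
    filter_cutoff: float | None = None  # kHz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.current.shape:
            raise ValueError("times and current must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def build_generator(rates: RateSet) -> np.ndarray:
    """Rate-generator matrix Q (s^-1) of the C1<->C2<->O<->I chain.

    Off-diagonal entry ``Q[i, j]`` is the i->j rate; rows sum to zero;
    only nearest-neighbour transitions along the chain are non-zero.
    """
    if not isinstance(rates, RateSet):
        rates = RateSet(*rates)
    Q = np.zeros((4, 4))
    Q[0, 1] = rates.a1
    Q[1, 0] = rates.b1
    Q[1, 2] = rates.a2
    Q[2, 1] = rates.b2
    Q[2, 3] = rates.k_on
    Q[3, 2] = rates.k_off
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _validate_initial(initial) -> np.ndarray:
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (4,):
        raise ValueError("initial occupancy must be a length-4 vector")
    if np.any(p0 < -1e-12):
        raise ValueError("initial occupancy must be non-negative")
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError(f"initial occupancy must sum to 1, got {p0.sum()!r}")
    return p0


# Eigenvector condition number above which the spectral solver is
# considered unreliable (near-defective generator) and per-step matrix
# exponentials are used instead.
_SPECTRAL_COND_MAX = 1e8


def _propagate_spectral(Q_ms: np.ndarray, p0: np.ndarray, t: np.ndarray) -> np.ndarray | None:
    w, V = np.linalg.eig(Q_ms)
    if not np.all(np.isfinite(V)) or np.linalg.cond(V) > _SPECTRAL_COND_MAX:
        return None
    # p(t) = p0 @ V @ diag(exp(w t)) @ V^-1
    c = p0 @ V
    traj = np.real((np.exp(np.outer(t, w)) * c) @ np.linalg.inv(V))
    # near-degenerate eigenvalues can slip past the condition check;
    # probability conservation is an exact invariant, so use it as the
    # accuracy certificate for the spectral route
    if np.max(np.abs(traj.sum(axis=1) - 1.0)) > 1e-12:
        return None
    return traj


def _propagate_expm(Q_ms: np.ndarray, p0: np.ndarray, t: np.ndarray) -> np.ndarray:
    traj = np.empty((t.size, 4))
    cache: dict[float, np.ndarray] = {}
    p = p0
    prev = 0.0
    for i, ti in enumerate(t):
        dt = ti - prev
        if dt > 0:
            key = round(dt, 12)
            T = cache.get(key)
            if T is None:
                T = expm(Q_ms * dt)
                cache[key] = T
            p = p @ T
        traj[i] = p
        prev = ti
    return traj


def propagate_occupancy(rates: RateSet, initial, times) -> OccupancyTrajectory:
    """Solve the master equation ``dp/dt = p Q`` on a time grid.

    ``times`` is in ms, sorted ascending and non-negative; propagation
    starts from ``initial`` at t = 0.  Uses the spectral decomposition
    of Q (exact for a diagonalisable generator) with a matrix-exponential
    stepping fallback when Q is near-defective.
    """
    p0 = _validate_initial(initial)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t[0] < 0 or (t.size > 1 and np.any(np.diff(t) < 0)):
        raise ValueError("times must be sorted ascending and non-negative")
    Q_ms = build_generator(rates) / 1000.0  # rates s^-1 -> ms^-1
    traj = _propagate_spectral(Q_ms, p0, t)
    if traj is None:
        traj = _propagate_expm(Q_ms, p0, t)
    # spectral round-off can leave ~1e-15 excursions outside [0, 1]
    np.clip(traj, 0.0, 1.0, out=traj)
    return OccupancyTrajectory(times=t, occupancy=traj)


def steady_state(rates: RateSet) -> np.ndarray:
    """Stationary occupancy vector p with ``p Q = 0`` and sum 1.

    Requires a unique stationary distribution (single recurrent class);
    a generator with several closed communicating classes — e.g. all
    rates zero — raises.
    """
    Q = build_generator(rates)
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError("no unique stationary distribution for this rate set")
    v = ns[:, 0]
    s = v.sum()
    if abs(s) < 1e-12:
        raise ValueError("no unique stationary distribution for this rate set")
    v = v / s
    if np.any(v < -1e-9):
        raise ValueError("stationary solve produced negative occupancy")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def simulate_current(
    rates: RateSet,
    iN: float,
    protocol: GatingProtocol,
    label: str = "",
) -> CurrentTrace:
    """Noise-free macroscopic current ``I = iN * P_O`` under a step protocol.

    All channels start in C1 at the step onset; samples before the onset
    are zero current (the channels are closed at the holding potential).
    """
    if iN <= 0:
        raise ValueError("iN must be positive")
    t = protocol.times()
    k = protocol.onset_index
    current = np.zeros_like(t)
    traj = propagate_occupancy(rates, [1.0, 0.0, 0.0, 0.0], t[k:] - t[k])
    current[k:] = iN * traj.p_open
    return CurrentTrace(times=t, current=current, protocol=protocol, label=label)
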