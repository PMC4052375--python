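"""Inactivation energetics: equilibrium constants, free energies, and the
four-site cooperative binding model of the intracellular cavity.

The open<->inactivated equilibrium constant is ``K_eq = k_on / k_off``
and its free energy, in RT units, ``dG = -ln(K_eq)`` (so stronger
inactivation, K_eq > 1, gives negative dG).  A single inactivation gate
can bind at any of the four subunit interfaces lining the cavity; the
channel-level constant is the sum of the per-site constants.  When
``n`` subunits carry the cavity I470V substitution (per-site constant
``K_V`` instead of ``K_I``), each valine boosts the apparent affinity of
the remaining isoleucine sites by a fraction ``epsilon``:

    K(n) = (4 - n) * K_I * (1 + epsilon)**n  +  n * K_V

The boost applies only to isoleucine sites, and only the *count* of
valine subunits matters, not their arrangement — consistent with the
observation that single-subunit substitutions at any position are
indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "EquilibriumResult",
    "BindingModel",
    "equilibrium_constant",
    "free_energy",
    "mean_dwell_time",
    "aggregate_on_rate",
    "binding_model_keq",
    "predict_free_energy_curve",
    "fit_cooperativity",
    "pool_by_count",
]

#: Sign convention for free energies: dG = DG_SIGN * ln(K_eq).
DG_SIGN = -1.0


def free_energy(k_eq: float, sign: float = DG_SIGN) -> float:
    """Free energy of an equilibrium in RT units, ``sign * ln(K_eq)``."""
    k_eq = np.asarray(k_eq, dtype=float)
    if np.any(k_eq <= 0):
        raise ValueError("K_eq must be positive")
    out = sign * np.log(k_eq)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium constant and its free energy in RT units."""

    K_eq: float
    delta_G: float


def equilibrium_constant(k_on: float, k_off: float) -> EquilibriumResult:
    """K_eq = k_on / k_off and dG = -ln(K_eq) for the O<->I equilibrium."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("k_on and k_off must be positive")
    k_eq = k_on / k_off
    return EquilibriumResult(K_eq=k_eq, delta_G=free_energy(k_eq))


def mean_dwell_time(k_off: float) -> float:
    """Mean residence time (ms) of the gate in the pore, ``1000 / k_off``."""
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    return 1000.0 / k_off


def aggregate_on_rate(per_gate_k_on: float, n_gates: int) -> float:
    """Total on-rate of ``n_gates`` independent identical inactivation gates.

    A homotetramer carries four gates, a concatemer one; with independent
    gates the macroscopic on-rate scales linearly with the gate count.
    """
    if n_gates < 1:
        raise ValueError("n_gates must be >= 1")
    return n_gates * per_gate_k_on


@dataclass(frozen=True)
class BindingModel:
    """Four-site cavity binding model for the single inactivation gate.

    ``K_I``/``K_V`` are per-site equilibrium constants for isoleucine and
    valine subunits; ``epsilon`` is the fractional affinity boost each
    valine confers on the remaining isoleucine sites.  ``boost`` selects
    the multiplicative ``(1+eps)**n`` (default) or additive ``1 + n*eps``
    form of that enhancement.
    """

    K_I: float
    K_V: float
    epsilon: float = 0.0
    n_sites: int = 4
    boost: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.K_I <= 0 or self.K_V <= 0:
            raise ValueError("per-site constants K_I and K_V must be positive")
        if self.epsilon <= -1:
            raise ValueError("epsilon must be > -1")
        if self.boost not in ("multiplicative", "additive"):
            raise ValueError("boost must be 'multiplicative' or 'additive'")


def _boost_factor(model: BindingModel, n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if model.boost == "multiplicative":
        return (1.0 + model.epsilon) ** n
    return 1.0 + n * model.epsilon


def binding_model_keq(model: BindingModel, n_valine) -> float | np.ndarray:
    """Channel-level K_eq with ``n_valine`` subunits mutated to valine.

    ``K(n) = (n_sites - n) * K_I * boost(n) + n * K_V``: the gate binds
    one of the sites, so per-site constants add; valines boost only the
    remaining isoleucine sites.
    """
    n = np.asarray(n_valine)
    if np.any(n < 0) or np.any(n > model.n_sites):
        raise ValueError(f"n_valine must be in [0, {model.n_sites}]")
    k = (model.n_sites - n) * model.K_I * _boost_factor(model, n) + n * model.K_V
    return float(k) if k.ndim == 0 else k


def predict_free_energy_curve(model: BindingModel) -> pd.DataFrame:
    """dG(n) in RT units for n = 0..n_sites, with the independent-site
    (epsilon = 0) curve alongside for comparison.

    Even with epsilon = 0 the curve is -ln of a linear function of n and
    hence not linear in n; the fitted epsilon quantifies the *additional*
    curvature relative to independent sites.
    """
    n = np.arange(model.n_sites + 1)
    keq = binding_model_keq(model, n)
    indep = BindingModel(
        K_I=model.K_I, K_V=model.K_V, epsilon=0.0, n_sites=model.n_sites, boost=model.boost
    )
    keq0 = binding_model_keq(indep, n)
    return pd.DataFrame(
        {
            "n_valine": n,
            "K_eq": keq,
            "delta_g": free_energy(keq),
            "delta_g_independent": free_energy(keq0),
        }
    )


def pool_by_count(data) -> dict[int, np.ndarray]:
    """Pool position-labelled dG measurements by valine count.

    Accepts a mapping ``{n: values}`` or a DataFrame with column
    ``n_valine`` and either ``delta_g`` or both ``k_on`` and ``k_off``
    (dG computed as -ln(k_on/k_off)).  Construct labels (e.g. ``1V4V``
    vs ``2V4V``) are ignored beyond their count: only the number of
    valine subunits enters the model.
    """
    if isinstance(data, pd.DataFrame):
        df = data
        if "delta_g" in df.columns:
            dg = np.asarray(df["delta_g"], dtype=float)
        elif {"k_on", "k_off"} <= set(df.columns):
            dg = free_energy(np.asarray(df["k_on"], dtype=float) / np.asarray(df["k_off"], dtype=float))
        else:
            raise ValueError("need a 'delta_g' column or 'k_on' and 'k_off' columns")
        counts = np.asarray(df["n_valine"], dtype=int)
        return {int(n): dg[counts == n] for n in np.unique(counts)}
    return {int(n): np.asarray(v, dtype=float) for n, v in dict(data).items()}


def fit_cooperativity(
    dg_by_n,
    n_sites: int = 4,
    boost: str = "multiplicative",
    space: str = "dg",
) -> BindingModel:
    """Fit the affinity-boost parameter epsilon from grouped dG data.

    The endpoint groups pin the per-site constants — ``K_I`` from the
    all-isoleucine group (n = 0) and ``K_V`` from the all-valine group
    (n = n_sites), each as the group-mean K_eq divided by ``n_sites`` —
    and epsilon is then estimated by least squares on the intermediate
    groups, in dG space by default (``space='keq'`` fits K_eq instead).
    """
    groups = pool_by_count(dg_by_n)
    if 0 not in groups or n_sites not in groups:
        raise ValueError(
            f"groups for n_valine = 0 and n_valine = {n_sites} are required to pin K_I and K_V"
        )
    intermediate = {n: v for n, v in groups.items() if 0 < n < n_sites and len(v) > 0}
    if not intermediate:
        raise ValueError("at least one intermediate valine-count group is required")
    if space not in ("dg", "keq"):
        raise ValueError("space must be 'dg' or 'keq'")

    k_i = float(np.mean(np.exp(DG_SIGN * np.asarray(groups[0])))) / n_sites
    k_v = float(np.mean(np.exp(DG_SIGN * np.asarray(groups[n_sites])))) / n_sites

    ns = np.concatenate([np.full(len(v), n) for n, v in sorted(intermediate.items())])
    obs_dg = np.concatenate([np.asarray(v, float) for _, v in sorted(intermediate.items())])

    def residuals(theta):
        model = BindingModel(K_I=k_i, K_V=k_v, epsilon=theta[0], n_sites=n_sites, boost=boost)
        pred_keq = binding_model_keq(model, ns)
        if space == "dg":
            return free_energy(pred_keq) - obs_dg
        return pred_keq - np.exp(DG_SIGN * obs_dg)

    sol = least_squares(residuals, x0=[0.05], bounds=([-0.99], [10.0]), xtol=1e-14, ftol=1e-14)
    return BindingModel(K_I=k_i, K_V=k_v, epsilon=float(sol.x[0]), n_sites=n_sites, boost=boost)
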