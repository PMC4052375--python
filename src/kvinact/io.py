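"""Plain-text serialization: trace CSVs with JSON sidecars, rate/protocol
JSON, cohort manifests, fit summaries and free-energy datasets.

Traces are written as two-column CSV (``time_ms,current_pA``) using
shortest round-trip float representation, so write -> read -> write is
byte-identical.  A sidecar ``<name>.json`` carries the protocol, label
and generator provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import BindingModel
from .kinetics import CurrentTrace, GatingProtocol, RateSet

__all__ = [
    "write_trace",
    "read_trace",
    "rates_from_dict",
    "protocol_from_dict",
    "write_binding_model",
    "read_dg_dataset",
    "write_cohort_summary",
]

TRACE_HEADER = "time_ms,current_pA"


def write_trace(trace: CurrentTrace, path, sidecar: bool = True) -> Path:
    """Write a trace CSV (and JSON sidecar) and return the CSV path."""
    path = Path(path)
    lines = [TRACE_HEADER]
    # shortest round-trip repr of Python floats keeps write->read->write
    # byte-identical
    lines.extend(f"{float(t)!r},{float(c)!r}" for t, c in zip(trace.times, trace.current))
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        meta = {
            "label": trace.label,
            "protocol": trace.protocol.as_dict(),
            "iN_true": trace.iN_true,
            "filter_cutoff": trace.filter_cutoff,
            "meta": _jsonable(trace.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_trace(path) -> CurrentTrace:
    """Read a trace CSV, picking up the JSON sidecar when present."""
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns ({TRACE_HEADER})")
    times, current = arr[:, 0], arr[:, 1]
    sidecar = path.with_suffix(".json")
    label, iN_true, cutoff, meta = "", None, None, {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        label = info.get("label", "")
        iN_true = info.get("iN_true")
        cutoff = info.get("filter_cutoff")
        meta = info.get("meta", {}) or {}
        protocol = protocol_from_dict(info["protocol"])
    else:
        # infer a minimal protocol from the grid: no baseline samples
        dt = float(np.median(np.diff(times)))
        protocol = GatingProtocol(
            duration=float(times[-1] - times[0]), sample_rate=1.0 / dt, pre_step_baseline=0.0
        )
    return CurrentTrace(
        times=times, current=current, protocol=protocol,
        label=label, iN_true=iN_true, filter_cutoff=cutoff, meta=meta,
    )


def rates_from_dict(d: dict) -> RateSet:
    return RateSet(**{k: float(d[k]) for k in ("a1", "b1", "a2", "b2", "k_on", "k_off")})


def protocol_from_dict(d: dict) -> GatingProtocol:
    return GatingProtocol(**{k: float(v) for k, v in d.items()})


def write_binding_model(model: BindingModel, path) -> Path:
    path = Path(path)
    payload = {
        "n_sites": model.n_sites,
        "K_I": model.K_I,
        "K_V": model.K_V,
        "epsilon": model.epsilon,
        "boost": model.boost,
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def read_dg_dataset(path) -> pd.DataFrame:
    """Read a free-energy dataset CSV.

    Accepts either ``construct_label,n_valine,k_on,k_off`` (dG computed
    downstream from the rates) or ``construct_label,n_valine,delta_g``.
    """
    df = pd.read_csv(path)
    required = {"construct_label", "n_valine"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if "delta_g" not in df.columns and not {"k_on", "k_off"} <= set(df.columns):
        raise ValueError(f"{path}: need 'delta_g' or 'k_on'+'k_off' columns")
    return df


def write_cohort_summary(per_trace_results, path) -> Path:
    """Per-trace fit table: label,k_on,k_off,iN,rss,converged."""
    path = Path(path)
    rows = [
        {
            "label": r.label,
            "k_on": r.k_on,
            "k_off": r.k_off,
            "iN": r.iN,
            "rss": r.residual_sum_of_squares,
            "converged": r.converged,
        }
        for r in per_trace_results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
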