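"""On-disk trace bundles: CSV samples with a JSON metadata sidecar.

One directory per recording: ``trace.csv`` holds time in the first column
and one or more channels after it; ``meta.json`` carries sampling rate,
channel kinds, units and any protocol/marker metadata; optional ground
truth goes to ``truth_events.csv`` / ``truth_params.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpecificationError, Trace

_UNITS = {"voltage_cc": "mV", "current_stim": "pA", "current_vc": "pA", "field": "mV"}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_trace_bundle(path: str | Path, traces: list[Trace] | Trace,
                      truth_events: pd.DataFrame | None = None,
                      truth_params: dict | None = None) -> Path:
    """Write one recording (one or more aligned channels) to a directory."""
    if isinstance(traces, Trace):
        traces = [traces]
    if not traces:
        raise SpecificationError("nothing to save")
    fs, t0, n = traces[0].fs, traces[0].t0, traces[0].n
    for tr in traces[1:]:
        if tr.fs != fs or tr.n != n:
            raise SpecificationError("bundle channels must share fs and length")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = {"time_s": t0 + np.arange(n) / fs}
    meta = {"fs_hz": fs, "t0_s": t0, "channels": []}
    for i, tr in enumerate(traces):
        name = f"ch{i}_{tr.kind}"
        cols[name] = tr.samples
        meta["channels"].append({"column": name, "kind": tr.kind,
                                 "units": _UNITS[tr.kind], "meta": _jsonable(tr.meta)})
    pd.DataFrame(cols).to_csv(path / "trace.csv", index=False)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth_events is not None:
        truth_events.to_csv(path / "truth_events.csv", index=False)
    if truth_params is not None:
        (path / "truth_params.json").write_text(json.dumps(_jsonable(truth_params), indent=1))
    return path


def load_trace_bundle(path: str | Path) -> tuple[list[Trace], pd.DataFrame | None, dict | None]:
    """Read a bundle back; returns (traces, truth_events, truth_params)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    df = pd.read_csv(path / "trace.csv")
    traces = []
    for ch in meta["channels"]:
        traces.append(Trace(df[ch["column"]].to_numpy(), fs=meta["fs_hz"],
                            kind=ch["kind"], t0=meta["t0_s"], meta=ch.get("meta", {})))
    events = None
    ev_path = path / "truth_events.csv"
    if ev_path.exists():
        events = pd.read_csv(ev_path)
    params = None
    pp = path / "truth_params.json"
    if pp.exists():
        params = json.loads(pp.read_text())
    return traces, events, params
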