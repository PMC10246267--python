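"""Plain-text trace format: one TSV per sweep plus a JSON sidecar.

Columns are ``time_ms``, ``v_mV``, ``i_uA`` (the recorded total current).
The format is deliberately diffable; floats are written with ``%.10g`` which
round-trips bit-identically through read/write cycles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .gating_model import SolutionPair, Sweep, TraceSet

FORMAT_VERSION = 1
_FMT = "%.10g"


def write_traceset(ts: TraceSet, out_dir: str | Path, name: str = "traceset") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sweep_entries = []
    for idx, sweep in enumerate(ts.sweeps):
        fname = f"sweep_{idx:03d}.tsv"
        data = np.column_stack([sweep.t_ms, sweep.v_mV, sweep.i_total])
        header = "time_ms\tv_mV\ti_uA"
        np.savetxt(out_dir / fname, data, fmt=_FMT, delimiter="\t",
                   header=header, comments="")
        sweep_entries.append({"file": fname, "meta": _jsonable(sweep.meta)})
    sidecar = {
        "format_version": FORMAT_VERSION,
        "name": name,
        "solution": ts.solution.to_dict(),
        "meta": _jsonable(ts.meta),
        "sweeps": sweep_entries,
    }
    sidecar_path = out_dir / f"{name}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return sidecar_path


def read_traceset(path: str | Path) -> TraceSet:
    """Load a trace set from its sidecar path (or a directory holding one)."""
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.glob("*.json"))
        if len(candidates) != 1:
            raise ValueError(
                f"expected exactly one sidecar JSON in {path}, found {len(candidates)}")
        path = candidates[0]
    sidecar = json.loads(path.read_text())
    if sidecar.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported trace format_version in {path}")
    sol = SolutionPair(**sidecar["solution"])
    sweeps = []
    for entry in sidecar["sweeps"]:
        data = np.loadtxt(path.parent / entry["file"], delimiter="\t", skiprows=1,
                          ndmin=2)
        t, v, i = data[:, 0], data[:, 1], data[:, 2]
        sweeps.append(Sweep(t_ms=t, v_mV=v, i_ionic=i,
                            i_gating=np.zeros_like(i), meta=entry.get("meta", {})))
    return TraceSet(sweeps=sweeps, solution=sol, meta=sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
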