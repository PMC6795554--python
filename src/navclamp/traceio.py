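"""Trace-set file I/O: one long-format CSV per protocol run plus a JSON
sidecar carrying the protocol, units and provenance (genotype, seed,
subtraction).  Round-trips exactly at the stored precision."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clamp import TraceSet, VoltageProtocol

__all__ = ["write_traceset", "read_traceset"]

_FLOAT_FMT = "%.6g"


def write_traceset(traces: TraceSet, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``<basepath>.csv`` (sweep, time_ms, v_mV, i) and
    ``<basepath>.json`` (protocol + metadata).  Returns the two paths."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    n_sweeps, T = traces.current.shape
    df = pd.DataFrame({
        "sweep": np.repeat(np.arange(n_sweeps), T),
        "time_ms": np.tile(traces.time, n_sweeps),
        "v_mV": traces.voltage.ravel(),
        "i": traces.current.ravel(),
    })
    csv_path = basepath.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "protocol": json.loads(traces.protocol.model_dump_json()),
        "levels": traces.levels.tolist(),
        "windows": traces.windows,
        "meta": traces.meta,
    }
    json_path = basepath.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path, json_path


def read_traceset(basepath: str | Path) -> TraceSet:
    basepath = Path(basepath)
    sidecar = json.loads(basepath.with_suffix(".json").read_text())
    prot = VoltageProtocol.model_validate(sidecar["protocol"])
    df = pd.read_csv(basepath.with_suffix(".csv"))
    n_sweeps = int(df["sweep"].max()) + 1
    T = len(df) // n_sweeps
    return TraceSet(
        protocol=prot,
        time=df["time_ms"].to_numpy()[:T],
        voltage=df["v_mV"].to_numpy().reshape(n_sweeps, T),
        current=df["i"].to_numpy().reshape(n_sweeps, T),
        levels=np.asarray(sidecar["levels"], dtype=float),
        windows=[tuple(w) for w in sidecar["windows"]],
        meta=sidecar["meta"],
    )
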