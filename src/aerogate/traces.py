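"""The (time, voltage, current) trace container and its flat-file format.

Traces are written as tab-separated text with ``#`` comment headers and the
columns ``time_s``, ``voltage_V``, ``current_A``; metadata travels in a JSON
sidecar with the same basename and suffix ``.meta.json``.  The convention for
signs follows the transport model: positive current is cation flux from the
cis to the trans side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd


class TraceError(ValueError):
    """Malformed current trace or trace file."""


@dataclass
class CurrentTrace:
    """Uniformly sampled recording of voltage and current versus time."""

    time_s: np.ndarray
    voltage_v: np.ndarray
    current_a: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    #: optional simulation ground truth (arrays), not serialized to the TSV
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        v = np.asarray(self.voltage_v, float)
        i = np.asarray(self.current_a, float)
        if not (t.size == v.size == i.size) or t.size < 2:
            raise TraceError("trace arrays must have equal length >= 2")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise TraceError(f"time axis not strictly increasing at index {bad}")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12)))
            raise TraceError(f"non-uniform time step at index {bad}")
        self.time_s, self.voltage_v, self.current_a = t, v, i

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + self.dt


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".tsv" \
        else path.with_name(path.stem + ".meta.json")


def write_trace(trace: CurrentTrace, path: str | Path,
                max_ground_truth_points: int = 20000) -> Path:
    """Write a trace as TSV plus a ``.meta.json`` sidecar; returns the TSV path.

    Ground-truth arrays (if present) are decimated to at most
    ``max_ground_truth_points`` samples before being stored in the sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# aerogate current trace\n")
        fh.write("# columns: time_s\tvoltage_V\tcurrent_A\n")
        fh.write("# sign convention: positive current = cation flux cis->trans\n")
        df = pd.DataFrame(
            {"time_s": trace.time_s, "voltage_V": trace.voltage_v,
             "current_A": trace.current_a}
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.9e")
    meta: dict[str, Any] = dict(trace.metadata)
    if trace.ground_truth:
        gt: dict[str, Any] = {}
        for key, val in trace.ground_truth.items():
            arr = np.asarray(val)
            if arr.ndim >= 1 and arr.size > max_ground_truth_points:
                step = int(np.ceil(arr.size / max_ground_truth_points))
                gt[key] = arr[::step].tolist()
                gt[f"{key}_decimation"] = step
            elif arr.ndim >= 1:
                gt[key] = arr.tolist()
            else:
                gt[key] = val
        meta["ground_truth"] = gt
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a TSV trace; a missing sidecar yields empty metadata and a warning."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["time_s", "voltage_V", "current_A"]
    if list(df.columns) != expected:
        raise TraceError(f"expected columns {expected}, found {list(df.columns)}")
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        warnings.warn(f"no metadata sidecar at {side}; loading with empty metadata",
                      RuntimeWarning, stacklevel=2)
        meta = {}
    gt = meta.pop("ground_truth", None)
    if gt is not None:
        gt = {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in gt.items()}
    return CurrentTrace(
        time_s=df["time_s"].to_numpy(),
        voltage_v=df["voltage_V"].to_numpy(),
        current_a=df["current_A"].to_numpy(),
        metadata=meta,
        ground_truth=gt,
    )
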