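"""Timestamped recordings (clamp currents, membrane voltage, spike trains).

Serialization convention: a CSV with columns ``time_ms,value`` (traces) or a
single ``spike_time_ms`` column (spike lists), plus a JSON sidecar
``<name>.meta.json`` carrying mode, holding potential and acquisition
metadata (direction, velocity, trial, seed, mechanism toggles ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recording"]

_MODES = ("voltage_clamp_current", "membrane_voltage", "spike_times")


@dataclass
class Recording:
    mode: str
    dt_ms: float | None = None
    t0_ms: float = 0.0
    values: np.ndarray | None = None       # pA for clamp current, mV for voltage
    spike_times_ms: np.ndarray | None = None
    hold_potential_mv: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown recording mode {self.mode!r}")
        if self.mode == "spike_times":
            st = np.asarray([] if self.spike_times_ms is None
                            else self.spike_times_ms, dtype=float)
            if st.size and not np.all(np.diff(st) > 0):
                raise ValueError("spike times must be strictly increasing")
            self.spike_times_ms = st
        else:
            if self.dt_ms is None or self.dt_ms <= 0:
                raise ValueError("trace recordings need a positive dt")
            self.values = np.asarray(self.values, dtype=float)
            if self.mode == "voltage_clamp_current" and self.hold_potential_mv is None:
                raise ValueError("clamp recordings must carry hold_potential")

    @property
    def time_ms(self) -> np.ndarray:
        if self.values is None:
            raise ValueError("spike-time recordings have no trace time axis")
        return self.t0_ms + self.dt_ms * np.arange(self.values.size)

    @property
    def n_spikes(self) -> int:
        if self.spike_times_ms is None:
            raise ValueError("not a spike recording")
        return int(self.spike_times_ms.size)

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if self.mode == "spike_times":
            pd.DataFrame({"spike_time_ms": self.spike_times_ms}).to_csv(
                path, index=False)
        else:
            pd.DataFrame({"time_ms": self.time_ms, "value": self.values}).to_csv(
                path, index=False)
        meta = {
            "mode": self.mode,
            "dt_ms": self.dt_ms,
            "t0_ms": self.t0_ms,
            "hold_potential_mv": self.hold_potential_mv,
            "metadata": _jsonable(self.metadata),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text())
        df = pd.read_csv(path)
        if meta["mode"] == "spike_times":
            return cls(mode="spike_times",
                       spike_times_ms=df["spike_time_ms"].to_numpy(),
                       metadata=meta.get("metadata", {}))
        return cls(mode=meta["mode"], dt_ms=meta["dt_ms"],
                   t0_ms=meta.get("t0_ms", 0.0),
                   values=df["value"].to_numpy(),
                   hold_potential_mv=meta.get("hold_potential_mv"),
                   metadata=meta.get("metadata", {}))


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
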