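"""CSV/JSON serialization and flat config files.

Traces and memories are written as plain CSV with a JSON sidecar
(``<file>.meta.json``) holding the run metadata (specs, seeds, provenance);
formatting is fixed so that identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bank import OscillatorBankSpec
from .core import OutputTrace, ReferenceMemory

__all__ = [
    "write_trace",
    "read_trace",
    "write_memory",
    "read_memory",
    "write_voltage_traces",
    "load_config",
    "write_json",
]

_FLOAT_FMT = "%.12g"


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_sanitize(payload), indent=2, sort_keys=True))


def write_trace(trace: OutputTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "out": trace.values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    write_json(trace.metadata, path.with_suffix(path.suffix + ".meta.json"))


def read_trace(path: str | Path) -> OutputTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return OutputTrace(df["time_s"].to_numpy(), df["out"].to_numpy(), meta)


def write_memory(memory: ReferenceMemory, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "oscillator_id": np.arange(len(memory.weights)),
            "f_hz": memory.frequencies,
            "weight": memory.weights,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_json(
        {
            "criterion": memory.criterion,
            "n_trials": memory.n_trials,
            "norm_constant": memory.norm_constant,
        },
        path.with_suffix(path.suffix + ".meta.json"),
    )


def read_memory(path: str | Path) -> ReferenceMemory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(
        path.with_suffix(path.suffix + ".meta.json").read_text()
    )
    return ReferenceMemory(
        weights=df["weight"].to_numpy(),
        frequencies=df["f_hz"].to_numpy(),
        criterion=meta["criterion"],
        n_trials=meta["n_trials"],
        norm_constant=meta["norm_constant"],
    )


def write_voltage_traces(
    times_s: np.ndarray, voltages: np.ndarray, path: str | Path
) -> None:
    """Long-format CSV (time_s, neuron_id, value) for a bank voltage matrix."""
    n_t, n = voltages.shape
    df = pd.DataFrame(
        {
            "time_s": np.repeat(times_s, n),
            "neuron_id": np.tile(np.arange(n), n_t),
            "value": voltages.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_config(path: str | Path) -> dict:
    """Flat key-value config file (YAML)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return data


def bank_spec_from_config(cfg: dict) -> OscillatorBankSpec:
    return OscillatorBankSpec(
        n_osc=int(cfg.get("n_osc", 1000)),
        f_min=float(cfg.get("f_min", 8.0)),
        f_max=float(cfg.get("f_max", 12.0)),
        amplitude=float(cfg.get("amplitude", 1.0)),
    )
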