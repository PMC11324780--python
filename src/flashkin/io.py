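"""Trace file I/O and run configuration.

Traces are stored as delimited text: ``#``-prefixed header lines carrying
JSON-encoded metadata, then one row per sample with columns
``time_us value valid``.  Floats are written with ``repr`` so that
``read_trace(write_trace(x)) == x`` bitwise for finite values; masked
samples are encoded explicitly in the third column.

Run configuration files are strict YAML: nested sections mirror the
parameter dataclasses and unknown keys are rejected with the offending
section named.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .correction import CorrectionConfig
from .kok import KokParams
from .polyphasic import PolyphasicSpec
from .simulate import DQParams, SimConfig, TQParams
from .train import IntervalSpec
from .trace import TimeTrace

__all__ = ["read_trace", "write_trace", "RunConfig", "load_config"]

_MAGIC = "# flashkin-trace v1"


def write_trace(trace: TimeTrace, path: str | Path) -> None:
    """Write a trace as delimited text with a metadata header."""
    path = Path(path)
    lines = [_MAGIC]
    for key in sorted(trace.metadata):
        lines.append(f"# {key}: {json.dumps(trace.metadata[key])}")
    lines.append("# columns: time_us value valid")
    for t, v, ok in zip(trace.times, trace.values, trace.valid):
        lines.append(f"{float(t)!r}\t{float(v)!r}\t{1 if ok else 0}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> TimeTrace:
    """Read a trace written by :func:`write_trace`.

    Malformed headers or rows raise ``ValueError`` naming the line number;
    non-monotone time grids are rejected by the trace invariant.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    valid: list[bool] = []
    metadata: dict[str, Any] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise ValueError(f"{path}:1: not a flashkin trace file (bad magic)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body and not body.startswith("columns:"):
                    key, _, raw = body.partition(":")
                    try:
                        metadata[key.strip()] = json.loads(raw.strip())
                    except json.JSONDecodeError:
                        metadata[key.strip()] = raw.strip()
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from exc
            valid.append(parts[2] != "0" if len(parts) == 3 else True)
    if not times:
        raise ValueError(f"{path}: no data rows")
    try:
        return TimeTrace(np.array(times), np.array(values), np.array(valid), metadata)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration


def _build(cls: type, data: dict, section: str):
    """Instantiate a (possibly nested) parameter dataclass from a dict,
    rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"config section '{section}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "tq":
            value = _build(TQParams, value, f"{section}.tq")
        elif key == "dq":
            if isinstance(value, dict):
                value = {k: tuple(v) if isinstance(v, list) else v for k, v in value.items()}
            value = _build(DQParams, value, f"{section}.dq")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclasses.dataclass
class RunConfig:
    """Aggregated configuration for CLI runs."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    kok: KokParams = dataclasses.field(default_factory=KokParams)
    intervals: IntervalSpec = dataclasses.field(default_factory=IntervalSpec)
    correction: CorrectionConfig = dataclasses.field(default_factory=CorrectionConfig)
    polyphasic: PolyphasicSpec = dataclasses.field(default_factory=PolyphasicSpec)
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"


_SECTIONS = {
    "sim": SimConfig,
    "kok": KokParams,
    "intervals": IntervalSpec,
    "correction": CorrectionConfig,
    "polyphasic": PolyphasicSpec,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a strict-YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed", "outdir", "log_level"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    for scalar in ("seed", "outdir", "log_level"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return RunConfig(**kwargs)
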