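"""Trace-table and config I/O.

Trace tables are comma-separated UTF-8 text with a header row
``time_s,channel,value`` and optional ``position_cm`` and ``kind`` columns;
one row per sample, one logical trace per channel.  Configs are YAML
documents; fitted objects and run summaries are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .kinetics import Trace

__all__ = [
    "load_trace_table",
    "save_trace_table",
    "load_config",
    "config_hash",
    "write_summary",
]

REQUIRED_COLUMNS = ("time_s", "channel", "value")


class SchemaError(DomainError):
    """A trace table is missing a required column."""


class ValidationError(DomainError):
    """A trace table violates an invariant; the message names the row."""


def load_trace_table(path: str | Path) -> list[Trace]:
    """Read a trace table into typed traces, one per channel.

    Times must be strictly increasing within each channel; the first
    offending row index (0-based, in file order) is named otherwise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table {path} missing column(s): {missing}")
    traces = []
    for channel, g in df.groupby("channel", sort=False):
        times = g["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            row = int(g.index[bad[0] + 1])
            raise ValidationError(
                f"non-monotone time_s in channel {channel!r} at row {row}"
            )
        position = None
        if "position_cm" in g.columns and g["position_cm"].notna().any():
            position = float(g["position_cm"].iloc[0])
        kind = ""
        if "kind" in g.columns and g["kind"].notna().any():
            kind = str(g["kind"].iloc[0])
        traces.append(
            Trace(times=times, values=g["value"].to_numpy(dtype=float),
                  position=position, kind=kind, channel=str(channel))
        )
    return traces


def save_trace_table(traces: Sequence[Trace], path: str | Path) -> None:
    """Write traces to a trace table; round-trips with
    :func:`load_trace_table`."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "channel": tr.channel or f"ch{len(frames)}",
                    "value": tr.values,
                    "position_cm": tr.position,
                    "kind": tr.kind,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise DomainError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable SHA-256 of a canonicalised config document."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_summary(payload: dict, path: str | Path, cfg: dict | None = None) -> None:
    """Write a machine-readable run summary embedding the config hash and
    package version, with deterministic key order."""
    from . import __version__

    doc = {
        "package_version": __version__,
        "config_hash": config_hash(cfg or {}),
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=float))
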