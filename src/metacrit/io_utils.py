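"""Serialization: trial tables and counts as CSV, scalar reports as JSON.

Tabular artifacts are plain CSV preceded by '#'-prefixed ``key=value``
metadata lines (model, parameters, seed), so every stochastic artifact is
reproducible from its own header. Numbers in JSON reports are rounded to 12
significant digits, which keeps round-trips lossless at test tolerances.
"""

from __future__ import annotations

import io
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .metad import ConfidenceCounts
from .outcome_oracle import OutcomeCurve

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_counts_csv",
    "read_counts_csv",
    "curve_to_frame",
    "write_curve_csv",
    "round_floats",
    "write_json_report",
]


def _format_meta_value(v):
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_meta_value(s: str):
    if s == "":
        return None
    try:
        i = int(s)
        return i
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write a trial table with its ``attrs`` metadata as header comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in trials.attrs.items():
            fh.write(f"# {key}={_format_meta_value(value)}\n")
        trials.to_csv(fh, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials_csv`.

    Metadata from '#'-prefixed header lines is restored into ``df.attrs``.
    """
    path = Path(path)
    meta = {}
    body = io.StringIO()
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = _parse_meta_value(value.strip())
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body)
    df.attrs.update(meta)
    return df


def write_counts_csv(counts: ConfidenceCounts, path) -> None:
    """Write confidence counts as an 8-row tidy CSV."""
    counts.to_frame().to_csv(path, index=False)


def read_counts_csv(path) -> ConfidenceCounts:
    return ConfidenceCounts.from_frame(pd.read_csv(path))


def curve_to_frame(curve: OutcomeCurve, engine: str = "exact") -> pd.DataFrame:
    """Tidy frame of an outcome curve: columns c2, value, response, context,
    engine."""
    return pd.DataFrame(
        {
            "c2": curve.grid,
            "value": curve.values,
            "response": curve.response,
            "context": curve.context,
            "engine": engine,
        }
    )


def write_curve_csv(curve: OutcomeCurve, path, engine: str = "exact") -> None:
    curve_to_frame(curve, engine).to_csv(path, index=False)


def round_floats(obj, sig: int = 12):
    """Recursively round floats to ``sig`` significant digits for JSON."""
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if not math.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_json_report(report: dict, path_or_stream) -> None:
    payload = json.dumps(round_floats(report), indent=2)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(payload + "\n")
    else:
        Path(path_or_stream).write_text(payload + "\n")
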