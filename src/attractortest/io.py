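"""Delimited-text reading and writing for regime time series.

The on-disk format is a plain CSV with a header row: a mandatory ``time``
column, one column per variable, and an optional ``regime`` column holding
the segment labels.  Missing values are empty fields.  Metadata travels in
``#``-prefixed comment lines above the header (``# key: value``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .series import RegimePair, RegimeSeries

__all__ = ["read_series", "write_series", "read_table"]

_RESERVED = {"time", "regime"}


def read_table(path, delimiter: str = ",") -> tuple[pd.DataFrame, dict]:
    """Read a series file into a DataFrame plus its ``#`` metadata mapping."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        stripped = line.lstrip("#").strip()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(
        _io.StringIO("\n".join(lines[body_start:])),
        sep=delimiter,
        float_precision="round_trip",
    )
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing mandatory 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return df, meta


def _frame_to_bundle(df: pd.DataFrame, label: str = ""):
    variables = [c for c in df.columns if c not in _RESERVED]
    if not variables:
        raise ValueError("no variable columns found")
    times = df["time"].to_numpy(dtype=float)
    bundle = {
        v: RegimeSeries(
            df[v].to_numpy(dtype=float), times,
            regime_label=label, variable_name=v,
        )
        for v in variables
    }
    if len(bundle) == 1:
        return next(iter(bundle.values()))
    return bundle


def read_series(path, delimiter: str = ","):
    """Read a series file.

    Returns a single :class:`RegimeSeries` (one variable), a dict of aligned
    series (several variables), or — when a ``regime`` column with exactly
    two labels is present — a :class:`RegimePair` of either shape.  Empty
    fields become NaN (missing).
    """
    df, _ = read_table(path, delimiter=delimiter)
    if "regime" in df.columns:
        labels = list(dict.fromkeys(df["regime"]))
        if len(labels) != 2:
            raise ValueError(
                f"{path}: expected exactly 2 regime labels, found {len(labels)}"
            )
        parts = [
            _frame_to_bundle(df[df["regime"] == lab], label=str(lab))
            for lab in labels
        ]
        return RegimePair(parts[0], parts[1])
    return _frame_to_bundle(df)


def write_series(
    path,
    data: Union[RegimeSeries, Mapping[str, RegimeSeries], RegimePair],
    delimiter: str = ",",
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write series to delimited text, preserving full float precision."""
    path = Path(path)

    def bundle_frame(bundle, label=None) -> pd.DataFrame:
        if isinstance(bundle, RegimeSeries):
            bundle = {bundle.variable_name or "x": bundle}
        first = next(iter(bundle.values()))
        frame = {"time": first.times}
        for name, s in bundle.items():
            if len(s) != len(first) or not np.array_equal(s.times, first.times):
                raise ValueError("all variables must share one time axis")
            frame[name or "x"] = s.values
        df = pd.DataFrame(frame)
        if label is not None:
            df["regime"] = label
        return df

    if isinstance(data, RegimePair):
        df = pd.concat(
            [
                bundle_frame(data.regime_a, label=data.labels[0] or "A"),
                bundle_frame(data.regime_b, label=data.labels[1] or "B"),
            ],
            ignore_index=True,
        )
    else:
        df = bundle_frame(data)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(
            fh, sep=delimiter, index=False, lineterminator="\n",
            float_format="%.17g",
        )
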