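"""Readers and writers for the time-series containers the pipeline touches.

Supports the OpenSim storage dialect (``.sto`` / ``.mot``), plain CSV
envelope tables (first column time, one column per channel) and JSON
result reports.  All readers verify declared against actual dimensions and
never silently truncate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "LabeledTimeSeries",
    "FormatError",
    "read_sto",
    "write_sto",
    "read_csv_envelopes",
    "write_csv_envelopes",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


@dataclass
class LabeledTimeSeries:
    """A sampled multichannel signal with named channels.

    Attributes
    ----------
    time:
        Strictly increasing sample times in seconds, shape ``(n,)``.
    values:
        Sample matrix, shape ``(n, n_channels)``.
    labels:
        Unique channel names, length ``n_channels``.
    in_degrees:
        Unit flag carried over from OpenSim storage headers (kinematic
        files); ``None`` when the source format does not declare it.
    """

    time: np.ndarray
    values: np.ndarray
    labels: list[str]
    in_degrees: bool | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if len(self.time) != self.values.shape[0]:
            raise ValueError(
                f"time has {len(self.time)} samples but values has "
                f"{self.values.shape[0]} rows"
            )
        if len(self.labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def rate(self) -> float:
        """Sampling rate in Hz estimated from the median time step."""
        if len(self.time) < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.time)))

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.labels.index(name)]


# ---------------------------------------------------------------------------
# OpenSim storage (.sto / .mot)
# ---------------------------------------------------------------------------

def read_sto(path: str | Path) -> LabeledTimeSeries:
    """Read an OpenSim storage file.

    The header must end with an ``endheader`` line; ``nRows``/``nColumns``
    declarations, when present, are checked against the data block.  Data
    rows may be tab- or whitespace-delimited.  The first data column must
    be named ``time``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            body_start = i + 1
            break
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
    if body_start is None:
        raise FormatError(f"{path}: no 'endheader' line found")
    if body_start >= len(lines):
        raise FormatError(f"{path}: no column-name row after endheader")

    columns = lines[body_start].split()
    if not columns or columns[0].lower() != "time":
        raise FormatError(f"{path}: first column must be 'time', got {columns[:1]}")

    rows = []
    for lineno, line in enumerate(lines[body_start + 1:], body_start + 2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != len(columns):
            raise FormatError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None

    data = np.array(rows, dtype=float).reshape(len(rows), len(columns))
    if "nRows" in header and int(header["nRows"]) != len(rows):
        raise FormatError(
            f"{path}: header declares nRows={header['nRows']} but found {len(rows)}"
        )
    if "nColumns" in header and int(header["nColumns"]) != len(columns):
        raise FormatError(
            f"{path}: header declares nColumns={header['nColumns']} "
            f"but found {len(columns)}"
        )

    in_degrees = None
    if "inDegrees" in header:
        in_degrees = header["inDegrees"].lower() in ("yes", "true", "1")
    return LabeledTimeSeries(
        time=data[:, 0], values=data[:, 1:], labels=columns[1:],
        in_degrees=in_degrees, meta={"header": header},
    )


def write_sto(ts: LabeledTimeSeries, path: str | Path, name: str = "musyn") -> None:
    """Write a :class:`LabeledTimeSeries` as tab-delimited OpenSim storage."""
    path = Path(path)
    n, m = ts.values.shape
    in_degrees = "yes" if ts.in_degrees else "no"
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={n}\nnColumns={m + 1}\n")
        fh.write(f"inDegrees={in_degrees}\nendheader\n")
        fh.write("time\t" + "\t".join(ts.labels) + "\n")
        for i in range(n):
            row = "\t".join(f"{v:.12g}" for v in ts.values[i])
            fh.write(f"{ts.time[i]:.12g}\t{row}\n")


# ---------------------------------------------------------------------------
# CSV envelopes
# ---------------------------------------------------------------------------

def read_csv_envelopes(path: str | Path) -> LabeledTimeSeries:
    """Read an envelope table: header row, first column time (s), one
    column per muscle.  Non-numeric or missing cells are rejected with the
    offending coordinates."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one channel")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric or missing cell at data row {bad[0]}, "
            f"column '{df.columns[bad[1]]}'"
        )
    return LabeledTimeSeries(
        time=numeric.iloc[:, 0].to_numpy(),
        values=numeric.iloc[:, 1:].to_numpy(),
        labels=[str(c) for c in df.columns[1:]],
    )


def write_csv_envelopes(ts: LabeledTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.labels)
    df.insert(0, "time", ts.time)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonable(obj: Any, keypath: str = "") -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, f"{keypath}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, f"{keypath}[{i}]") for i, v in enumerate(obj)]
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict(), keypath)
    raise TypeError(f"unserializable field '{keypath or '<root>'}' of type {type(obj).__name__}")


def write_report(results: dict[str, Any], path: str | Path) -> None:
    """Serialize a results dictionary (decompositions, R² curves, selected
    orders, match reports, config, seeds) to self-describing JSON.

    Numbers round-trip bit-exactly: floats are written with repr precision.
    """
    payload = _jsonable(results)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
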