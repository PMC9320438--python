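"""Reading tracker-exported gaze CSV files and writing event/metric files.

The expected CSV layout follows Gazepoint-style exports: a header row with a
time column and per-eye pupil-center columns (``TIME``, ``LPCX``, ``RPCX``,
optionally ``LPCY``, ``RPCY`` and validity flags ``LPCV``/``RPCV``).  Vendor
header variations bind through ``column_map``.  Missing or non-numeric
coordinate cells mark the sample invalid for that eye — rows are never
dropped here, so the preprocessing module owns all deletions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GazeTrace
from .detection import FPEvent

__all__ = [
    "GazeFormatError",
    "GazeDataError",
    "read_gaze_csv",
    "write_events",
    "read_events",
]

_CANONICAL_REQUIRED = ("TIME", "LPCX", "RPCX")
_CANONICAL_OPTIONAL = ("LPCY", "RPCY", "LPCV", "RPCV")

_EVENT_FIELDS = ("t_peak", "t_high", "t_low", "x_high", "x_low", "amplitude", "duration", "eye")


class GazeFormatError(ValueError):
    """The file does not have the expected columns/structure."""


class GazeDataError(ValueError):
    """The file parses but its contents violate a data invariant."""


def _resolve(columns, name: str, column_map: dict | None) -> str | None:
    if column_map and name in column_map:
        target = column_map[name]
        return target if target in columns else None
    lower = {c.lower(): c for c in columns}
    return lower.get(name.lower())


def read_gaze_csv(
    path,
    column_map: dict | None = None,
    fs: float | None = None,
    time_unit: str = "s",
) -> GazeTrace:
    """Read a tracker CSV export into a :class:`GazeTrace`.

    Parameters
    ----------
    path : path-like
        CSV file with a header row (comma-separated, UTF-8).
    column_map : dict, optional
        Maps canonical names (TIME, LPCX, RPCX, LPCY, RPCY, LPCV, RPCV) to
        the actual headers in the file.
    fs : float, optional
        Sampling rate; inferred from the median timestamp spacing if omitted.
    time_unit : {"s", "ms"}
        Unit of the time column.  Times are normalised to seconds from the
        first sample.

    Raises
    ------
    GazeFormatError
        A required column is missing (the message names it).
    GazeDataError
        Timestamps are non-monotonic (the message gives the first offending
        row) or otherwise unusable.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)

    resolved = {}
    for name in _CANONICAL_REQUIRED:
        col = _resolve(cols, name, column_map)
        if col is None:
            raise GazeFormatError(f"missing required column {name!r} in {path.name}")
        resolved[name] = col
    for name in _CANONICAL_OPTIONAL:
        col = _resolve(cols, name, column_map)
        if col is not None:
            resolved[name] = col

    t = pd.to_numeric(df[resolved["TIME"]], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        bad = int(np.nonzero(~np.isfinite(t))[0][0])
        raise GazeDataError(f"non-numeric timestamp at row {bad}")
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise GazeDataError(f"timestamps not increasing at row {int(bad[0]) + 1}")
    if time_unit == "ms":
        t = t / 1000.0
    elif time_unit != "s":
        raise ValueError("time_unit must be 's' or 'ms'")
    t = t - t[0] if t.size else t

    def numeric(name: str) -> np.ndarray | None:
        if name not in resolved:
            return None
        return pd.to_numeric(df[resolved[name]], errors="coerce").to_numpy(dtype=float)

    lpcx = numeric("LPCX")
    rpcx = numeric("RPCX")
    valid_left = np.isfinite(lpcx)
    valid_right = np.isfinite(rpcx)
    lpcv, rpcv = numeric("LPCV"), numeric("RPCV")
    if lpcv is not None:
        valid_left &= np.nan_to_num(lpcv) != 0
    if rpcv is not None:
        valid_right &= np.nan_to_num(rpcv) != 0

    if fs is None:
        if t.size > 1:
            fs = 1.0 / float(np.median(np.diff(t)))
        else:
            fs = 150.0

    return GazeTrace(
        t=t,
        lpcx=lpcx,
        rpcx=rpcx,
        lpcy=numeric("LPCY"),
        rpcy=numeric("RPCY"),
        valid_left=valid_left,
        valid_right=valid_right,
        fs=fs,
        source=str(path),
    )


def write_events(events: list[FPEvent], path, format: str = "json", meta: dict | None = None) -> None:
    """Write detected fast-phase events as CSV or JSON.

    Events must be sorted by onset time.  Round-tripping through
    :func:`read_events` preserves every field to at least 6 decimal places.
    """
    path = Path(path)
    times = [e.t_peak for e in events]
    if times != sorted(times):
        raise ValueError("events must be sorted by t_peak")
    if format == "csv":
        df = pd.DataFrame([e.to_dict() for e in events], columns=list(_EVENT_FIELDS))
        df.to_csv(path, index=False)
    elif format == "json":
        payload = {"events": [e.to_dict() for e in events], "meta": meta or {}}
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError("format must be 'csv' or 'json'")


def read_events(path) -> list[FPEvent]:
    """Read events written by :func:`write_events` (format by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if df.empty:
            return []
        rows = df.to_dict("records")
    else:
        rows = json.loads(path.read_text())["events"]
    events = []
    for r in rows:
        events.append(
            FPEvent(
                t_high=float(r["t_high"]),
                t_low=float(r["t_low"]),
                x_high=float(r["x_high"]),
                x_low=float(r["x_low"]),
                t_peak=float(r["t_peak"]),
                amplitude=float(r.get("amplitude", abs(float(r["x_high"]) - float(r["x_low"])))),
                duration=float(r.get("duration", abs(float(r["t_low"]) - float(r["t_high"])))),
                eye=str(r.get("eye", "left")),
            )
        )
    return events
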