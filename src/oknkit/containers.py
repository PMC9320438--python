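"""Core containers for binocular gaze recordings.

A :class:`GazeTrace` holds the horizontal pupil-center coordinate of both
eyes sampled at a fixed rate (150 Hz for the Gazepoint GP3HD class of
trackers).  Coordinates are kept in the tracker's native linear unit
("tracker units"); conversion to visual degrees goes through the
calibration model in :mod:`oknkit.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GazeSample", "GazeTrace"]


@dataclass(frozen=True)
class GazeSample:
    """One binocular sample: time plus per-eye pupil-center coordinates."""

    t: float
    lpcx: float
    rpcx: float
    lpcy: float = np.nan
    rpcy: float = np.nan
    valid_left: bool = True
    valid_right: bool = True


@dataclass
class GazeTrace:
    """Timestamped binocular horizontal gaze series at a fixed sampling rate.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    lpcx, rpcx : array of float
        Left/right pupil-center X coordinate in tracker units.
    lpcy, rpcy : array of float, optional
        Vertical coordinates; kept only for round-tripping files.
    valid_left, valid_right : bool arrays, optional
        Per-eye validity flags (False during blinks / pupil loss).
    fs : float
        Nominal sampling rate in Hz.
    source : str
        Free-text provenance.
    """

    t: np.ndarray
    lpcx: np.ndarray
    rpcx: np.ndarray
    lpcy: np.ndarray | None = None
    rpcy: np.ndarray | None = None
    valid_left: np.ndarray | None = None
    valid_right: np.ndarray | None = None
    fs: float = 150.0
    source: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lpcx = np.asarray(self.lpcx, dtype=float)
        self.rpcx = np.asarray(self.rpcx, dtype=float)
        n = self.t.size
        for name in ("lpcx", "rpcx"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != t length {n}")
        for name in ("lpcy", "rpcy"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)
        for name in ("valid_left", "valid_right"):
            v = getattr(self, name)
            v = np.ones(n, dtype=bool) if v is None else np.asarray(v, dtype=bool)
            if v.size != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, v)
        if n and not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite timestamps")
        if n > 1:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise ValueError(f"timestamps not strictly increasing at row {bad[0] + 1}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0] + 1.0 / self.fs) if len(self) else 0.0

    def eye_x(self, eye: str) -> np.ndarray:
        if eye == "left":
            return self.lpcx
        if eye == "right":
            return self.rpcx
        raise ValueError(f"unknown eye {eye!r}")

    def eye_valid(self, eye: str) -> np.ndarray:
        if eye == "left":
            return self.valid_left
        if eye == "right":
            return self.valid_right
        raise ValueError(f"unknown eye {eye!r}")

    @property
    def samples(self) -> list[GazeSample]:
        """Row-wise view of the trace (convenience, O(n) to build)."""
        nan = float("nan")
        return [
            GazeSample(
                t=float(self.t[i]),
                lpcx=float(self.lpcx[i]),
                rpcx=float(self.rpcx[i]),
                lpcy=float(self.lpcy[i]) if self.lpcy is not None else nan,
                rpcy=float(self.rpcy[i]) if self.rpcy is not None else nan,
                valid_left=bool(self.valid_left[i]),
                valid_right=bool(self.valid_right[i]),
            )
            for i in range(len(self))
        ]

    def take(self, index) -> "GazeTrace":
        """New trace containing the selected samples (mask or index array)."""
        idx = np.asarray(index)
        return GazeTrace(
            t=self.t[idx],
            lpcx=self.lpcx[idx],
            rpcx=self.rpcx[idx],
            lpcy=self.lpcy[idx] if self.lpcy is not None else None,
            rpcy=self.rpcy[idx] if self.rpcy is not None else None,
            valid_left=self.valid_left[idx],
            valid_right=self.valid_right[idx],
            fs=self.fs,
            source=self.source,
        )

    def copy(self) -> "GazeTrace":
        return self.take(np.arange(len(self)))
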