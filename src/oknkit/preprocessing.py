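"""Abnormal-data-point filtering and gap segmentation.

Noise in video-oculography comes from blinks, head movement and the subject
looking away from the screen.  Such samples land far from the central
fixation point, so filtering is done by deletion: a binocular sample is
removed when either eye leaves the calibrated screen range
``[center - h, center + h]`` (h = ``CalibrationModel.outlier_half_range``)
or is flagged invalid by the tracker.  Both eyes are deleted together so the
two series stay on a single time base.

Deletion leaves temporal holes; downstream slope analysis must not connect
extrema across a blink, so the filtered trace is split into contiguous
segments at gaps and short leftover fragments are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GazeTrace
from .geometry import CalibrationModel

__all__ = [
    "FilterReport",
    "TraceSegment",
    "filter_abnormal_points",
    "segment_at_gaps",
    "interpolate_invalid",
]


@dataclass
class FilterReport:
    """Accounting of which samples the abnormal-point filter removed and why."""

    n_input: int
    n_removed: int
    removed_indices: list[int]
    reasons: dict[int, str]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "removed_indices": list(self.removed_indices),
            "reasons": {str(k): v for k, v in self.reasons.items()},
        }


@dataclass(frozen=True)
class TraceSegment:
    """Contiguous run of retained samples: half-open index range into ``parent``."""

    parent: GazeTrace
    start_idx: int
    end_idx: int
    eye: str | None = None

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("empty segment")

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def duration_s(self) -> float:
        return float(self.parent.t[self.end_idx - 1] - self.parent.t[self.start_idx])

    def times(self) -> np.ndarray:
        return self.parent.t[self.start_idx : self.end_idx]

    def values(self, eye: str) -> np.ndarray:
        return self.parent.eye_x(eye)[self.start_idx : self.end_idx]


def filter_abnormal_points(
    trace: GazeTrace, calib: CalibrationModel
) -> tuple[GazeTrace, FilterReport]:
    """Delete samples outside the per-eye retention bounds or flagged invalid.

    A sample is removed iff ``LPCX > CL + h``, ``LPCX < CL - h``,
    ``RPCX > CR + h``, ``RPCX < CR - h`` (strict inequalities; values exactly
    on the bound are retained) or either validity flag is False.  The whole
    binocular sample is removed when any rule fires.  Idempotent.
    """
    h = calib.outlier_half_range
    if h <= 0:
        raise ValueError("calibration outlier_half_range must be positive")
    n = len(trace)
    if n == 0:
        return trace.copy(), FilterReport(0, 0, [], {})

    invalid = (
        ~trace.valid_left
        | ~trace.valid_right
        | ~np.isfinite(trace.lpcx)
        | ~np.isfinite(trace.rpcx)
    )
    with np.errstate(invalid="ignore"):
        left_high = trace.lpcx > calib.cl + h
        left_low = trace.lpcx < calib.cl - h
        right_high = trace.rpcx > calib.cr + h
        right_low = trace.rpcx < calib.cr - h

    remove = invalid | left_high | left_low | right_high | right_low
    reasons: dict[int, str] = {}
    # invalid first (out-of-range coordinates on an invalid sample are
    # tracker placeholders, not gaze), then the rules in stated order
    for idx in np.nonzero(remove)[0]:
        if invalid[idx]:
            reasons[int(idx)] = "invalid"
        elif left_high[idx]:
            reasons[int(idx)] = "left_high"
        elif left_low[idx]:
            reasons[int(idx)] = "left_low"
        elif right_high[idx]:
            reasons[int(idx)] = "right_high"
        else:
            reasons[int(idx)] = "right_low"

    removed_indices = [int(i) for i in np.nonzero(remove)[0]]
    report = FilterReport(
        n_input=n,
        n_removed=len(removed_indices),
        removed_indices=removed_indices,
        reasons=reasons,
    )
    return trace.take(~remove), report


def interpolate_invalid(trace: GazeTrace, eye: str) -> np.ndarray:
    """Eye series with invalid samples linearly interpolated from valid ones.

    The slope-threshold pipeline never interpolates (it deletes and
    segments), but the spectral and FIR baselines need a contiguous series:
    feeding them the tracker's zero placeholders would swamp the filters
    with dropout step transients.  Leading/trailing invalid runs take the
    nearest valid value.
    """
    xs = np.array(trace.eye_x(eye), dtype=float)
    valid = trace.eye_valid(eye) & np.isfinite(xs)
    if valid.all():
        return xs
    if not valid.any():
        raise ValueError(f"no valid samples for {eye} eye")
    idx = np.arange(xs.size)
    xs[~valid] = np.interp(idx[~valid], idx[valid], xs[valid])
    return xs


def segment_at_gaps(
    trace: GazeTrace,
    max_gap_samples: int = 5,
    min_segment_s: float = 0.5,
) -> list[TraceSegment]:
    """Split a (filtered) trace into contiguous segments at temporal gaps.

    A new segment starts wherever consecutive timestamps are more than
    ``max_gap_samples / fs`` apart.  Segments shorter than ``min_segment_s``
    are dropped: extrema and slopes bridging a blink are meaningless, and a
    fragment shorter than a couple of OKN cycles cannot anchor the adaptive
    slope threshold.
    """
    if max_gap_samples < 1:
        raise ValueError("max_gap_samples must be >= 1")
    n = len(trace)
    if n == 0:
        return []
    gap = max_gap_samples / trace.fs
    # small relative tolerance so regular spacing is never split by float fuzz
    breaks = np.nonzero(np.diff(trace.t) > gap * (1 + 1e-9))[0] + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    segments = []
    for s, e in zip(starts, ends):
        seg = TraceSegment(parent=trace, start_idx=int(s), end_idx=int(e))
        if seg.duration_s >= min_segment_s:
            segments.append(seg)
    return segments
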