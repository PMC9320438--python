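"""Fast-phase detection for optokinetic nystagmus waveforms.

OKN alternates a slow phase (SP: the eye pursues the moving field) with a
fast phase (FP: a rapid resetting saccade in the opposite direction).  The
detector works directly on the horizontal pupil-center series:

1. amplitude-gated extrema search — local maxima/minima whose displacement
   from the previously accepted extremum exceeds ``min_gap`` (default 0.001
   tracker units), which suppresses micro-fluctuations;
2. segment formation — consecutive extrema are joined two by two into line
   segments whose slope is displacement over time;
3. slope classification against the stimulus direction — for a leftward
   stimulus SP segments have positive slope and FP segments negative slope
   steeper than a threshold M (mirrored for a rightward stimulus);
4. endpoint refinement — each FP endpoint is snapped to the true local
   extremum of the raw series within a small window.

The pipeline entry point :func:`detect_fp` composes these with the
abnormal-point filter and gap segmentation of :mod:`oknkit.preprocessing`.
:class:`FastPhaseDetector` wraps the same pipeline in an estimator API.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .containers import GazeTrace
from .geometry import CalibrationModel
from .preprocessing import filter_abnormal_points, segment_at_gaps

logger = logging.getLogger(__name__)

__all__ = [
    "ExtremumPoint",
    "PhaseSegment",
    "FPEvent",
    "StimulusSpec",
    "DetectionParams",
    "find_extrema",
    "build_segments",
    "classify_segments",
    "amplitude_consistency_filter",
    "refine_fp",
    "detect_fp",
    "FastPhaseDetector",
]

DEFAULT_MIN_GAP = 0.001  # tracker units; minimum displacement between extrema


@dataclass(frozen=True)
class ExtremumPoint:
    """A retained local extremum of the gaze series."""

    idx: int
    t: float
    x: float
    kind: str  # "max" | "min"


@dataclass(frozen=True)
class PhaseSegment:
    """Line segment between consecutive extrema, labelled SP/FP by slope."""

    start: ExtremumPoint
    end: ExtremumPoint
    slope: float  # tracker units per second
    label: str = "unclassified"  # "SP" | "FP" | "unclassified"

    @property
    def duration_s(self) -> float:
        return self.end.t - self.start.t


@dataclass(frozen=True)
class FPEvent:
    """One detected fast phase: its bracketing extrema and onset time."""

    t_high: float
    t_low: float
    x_high: float
    x_low: float
    t_peak: float  # onset-side extremum time
    amplitude: float
    duration: float
    eye: str = "left"

    def to_dict(self) -> dict:
        return {
            "t_peak": self.t_peak,
            "t_high": self.t_high,
            "t_low": self.t_low,
            "x_high": self.x_high,
            "x_low": self.x_low,
            "amplitude": self.amplitude,
            "duration": self.duration,
            "eye": self.eye,
        }


@dataclass(frozen=True)
class StimulusSpec:
    """Moving-grating stimulus: direction and angular speed."""

    direction: str  # "left" | "right"
    speed_deg_s: float = 20.0
    stripe_width_deg: float = 3.1

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        if self.speed_deg_s <= 0:
            raise ValueError("stimulus speed must be positive")

    @property
    def sp_sign(self) -> int:
        """Sign of the slow-phase slope: + for leftward stimulus, - for rightward."""
        return 1 if self.direction == "left" else -1


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the detection pipeline (see docs/methods.md)."""

    min_gap: float = DEFAULT_MIN_GAP
    slope_threshold: float | str = "adaptive"
    refine_window: int = 3
    max_gap_samples: int = 5
    min_segment_s: float = 0.5
    eye: str = "left"  # "left" | "right" | "both"
    fp_amplitude_factor: float = 0.5  # 0 disables the consistency gate


def _raw_candidates(xs: np.ndarray) -> list[tuple[int, str]]:
    """Interior turning points by neighbour comparison.

    Plateaus take their first index; trace endpoints are never candidates.
    """
    cands: list[tuple[int, str]] = []
    direction = 0
    run_end = 0  # first index of the current plateau / last value change
    for i in range(1, len(xs)):
        if xs[i] == xs[i - 1]:
            continue
        newdir = 1 if xs[i] > xs[i - 1] else -1
        if direction == 1 and newdir == -1:
            cands.append((run_end, "max"))
        elif direction == -1 and newdir == 1:
            cands.append((run_end, "min"))
        direction = newdir
        run_end = i
    return cands


def find_extrema(
    xs: np.ndarray,
    ts: np.ndarray,
    min_gap: float = DEFAULT_MIN_GAP,
) -> list[ExtremumPoint]:
    """Alternating local extrema with an amplitude gate.

    An opposite-kind candidate is accepted only if its displacement from the
    last accepted extremum is strictly greater than ``min_gap``; a same-kind
    candidate replaces the last accepted extremum when it is more extreme.
    The output therefore strictly alternates max/min and consecutive extrema
    differ by more than ``min_gap``.
    """
    xs = np.asarray(xs, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if xs.size != ts.size:
        raise ValueError("xs and ts must have equal length")
    if min_gap < 0:
        raise ValueError("min_gap must be non-negative")
    if xs.size < 3:
        return []

    accepted: list[ExtremumPoint] = []
    for idx, kind in _raw_candidates(xs):
        pt = ExtremumPoint(idx=idx, t=float(ts[idx]), x=float(xs[idx]), kind=kind)
        if not accepted:
            accepted.append(pt)
            continue
        last = accepted[-1]
        if kind == last.kind:
            if (kind == "max" and pt.x > last.x) or (kind == "min" and pt.x < last.x):
                accepted[-1] = pt
        elif abs(pt.x - last.x) > min_gap:
            accepted.append(pt)
    return accepted


def build_segments(extrema: list[ExtremumPoint]) -> list[PhaseSegment]:
    """Join consecutive extrema two by two into slope-carrying line segments."""
    if len(extrema) < 2:
        return []
    segments = []
    for a, b in zip(extrema, extrema[1:]):
        if b.kind == a.kind:
            raise ValueError("extrema must alternate max/min")
        if b.t <= a.t:
            raise ValueError("extrema must be in increasing time order")
        slope = (b.x - a.x) / (b.t - a.t)
        segments.append(PhaseSegment(start=a, end=b, slope=slope))
    return segments


def adaptive_slope_threshold(segments: list[PhaseSegment], stimulus: StimulusSpec) -> float:
    """Default FP slope threshold M: twice the median |slope| of SP-sign segments.

    FP slopes are several-fold steeper than SP slopes by construction (the
    reset covers the whole slow-phase excursion in a few tens of
    milliseconds), so a threshold anchored on the slow-phase population
    separates the two robustly without committing to a unit scale.
    """
    sp_mags = [abs(s.slope) for s in segments if s.slope * stimulus.sp_sign > 0]
    if not sp_mags:
        return 0.0
    return 2.0 * float(np.median(sp_mags))


def classify_segments(
    segments: list[PhaseSegment],
    stimulus: StimulusSpec,
    m_threshold: float | str = "adaptive",
) -> list[PhaseSegment]:
    """Label segments SP/FP by slope sign versus the stimulus direction.

    For a leftward stimulus the slow phase follows the stripes (positive
    slope) and the fast phase resets with a negative slope of magnitude at
    least ``m_threshold``; for a rightward stimulus the signs mirror.
    Segments meeting neither rule stay unclassified.
    """
    if m_threshold == "adaptive":
        m = adaptive_slope_threshold(segments, stimulus)
    else:
        m = float(m_threshold)
        if m < 0:
            raise ValueError("m_threshold must be non-negative")
    sign = stimulus.sp_sign
    out = []
    for seg in segments:
        if seg.slope * sign > 0:
            label = "SP"
        elif seg.slope * sign < 0 and abs(seg.slope) >= m:
            label = "FP"
        else:
            label = "unclassified"
        out.append(replace(seg, label=label))
    return out


def amplitude_consistency_filter(
    segments: list[PhaseSegment], factor: float = 0.5
) -> list[PhaseSegment]:
    """Demote FP candidates far smaller than the slow-phase excursion.

    In OKN each fast phase resets the excursion the preceding slow phase
    accumulated, so within a trace FP amplitudes match the SP segment
    amplitudes.  A candidate whose amplitude falls below ``factor`` times
    the median SP amplitude is a micro-fluctuation that slipped past the
    extrema gate, not a reset; it is relabelled unclassified.  No-op when
    ``factor`` is 0, when there are no SP segments to anchor the gate, or on
    clean sawtooth data (where FP and SP amplitudes coincide).
    """
    if factor <= 0:
        return segments
    sp_amps = [abs(s.end.x - s.start.x) for s in segments if s.label == "SP"]
    if not sp_amps:
        return segments
    gate = factor * float(np.median(sp_amps))
    return [
        replace(s, label="unclassified")
        if s.label == "FP" and abs(s.end.x - s.start.x) < gate
        else s
        for s in segments
    ]


def refine_fp(
    segment: PhaseSegment,
    xs: np.ndarray,
    ts: np.ndarray,
    window: int = 3,
    eye: str = "left",
) -> FPEvent:
    """Fine-tune an FP segment against the raw samples.

    Each endpoint snaps to the raw local extremum within ``+-window``
    samples (recovering any amplitude lost to gating; windows are clamped so
    the endpoints cannot cross).  The onset time ``t_peak`` is then taken at
    the corner where the reset slope actually begins — found by walking back
    from the terminal extremum along the monotone reset run — rather than at
    the snapped onset extremum: on jittery recordings the highest sample can
    sit several samples before the reset, while the corner is stable.
    """
    if segment.label != "FP":
        raise ValueError("refine_fp expects an FP-labelled segment")
    if window < 0:
        raise ValueError("window must be non-negative")
    xs = np.asarray(xs, dtype=float)
    ts = np.asarray(ts, dtype=float)
    n = xs.size

    def snap(idx: int, kind: str, lo_lim: int, hi_lim: int) -> int:
        lo = max(lo_lim, idx - window)
        hi = min(hi_lim, idx + window)
        sl = xs[lo : hi + 1]
        off = int(np.argmax(sl)) if kind == "max" else int(np.argmin(sl))
        return lo + off

    i0, i1 = segment.start.idx, segment.end.idx
    j0 = snap(i0, segment.start.kind, 0, i1 - 1)
    j1 = snap(i1, segment.end.kind, j0 + 1, n - 1)

    # Reset-onset corner by step (velocity) thresholding: locate the
    # steepest single-sample step of the reset, then walk back while steps
    # stay at least a third as steep; the onset sample is where that steep
    # run starts.  Slow-phase and jitter steps are several-fold shallower
    # than reset steps, so the run boundary is stable under jitter.
    sign = -1.0 if segment.start.kind == "max" else 1.0
    steps = sign * np.diff(xs[j0 : j1 + 1])
    if steps.size:
        k = int(np.argmax(steps))
        thresh = steps[k] / 3.0
        while k > 0 and steps[k - 1] >= thresh:
            k -= 1
        t_onset = float(ts[j0 + k])
    else:
        t_onset = float(ts[j0])

    p0 = (float(ts[j0]), float(xs[j0]), segment.start.kind)
    p1 = (float(ts[j1]), float(xs[j1]), segment.end.kind)
    (t_high, x_high) = (p0[0], p0[1]) if p0[2] == "max" else (p1[0], p1[1])
    (t_low, x_low) = (p0[0], p0[1]) if p0[2] == "min" else (p1[0], p1[1])
    return FPEvent(
        t_high=t_high,
        t_low=t_low,
        x_high=x_high,
        x_low=x_low,
        t_peak=t_onset,
        amplitude=abs(x_high - x_low),
        duration=p1[0] - p0[0],
        eye=eye,
    )


def detect_fp(
    trace: GazeTrace,
    calib: CalibrationModel,
    stimulus: StimulusSpec,
    params: DetectionParams | None = None,
) -> tuple[list[FPEvent], list[PhaseSegment]]:
    """Full FP detection pipeline on one trace.

    Composition: abnormal-point filtering -> gap segmentation -> per-segment
    extrema search -> segment formation -> slope classification -> FP
    endpoint refinement.  Returns the FP events (sorted by onset time) and
    every labelled phase segment.  Deterministic for fixed inputs.
    """
    params = params or DetectionParams()
    if len(trace) == 0:
        raise ValueError("empty trace")
    filtered, _report = filter_abnormal_points(trace, calib)
    segments = segment_at_gaps(filtered, params.max_gap_samples, params.min_segment_s)
    if not segments:
        logger.warning("no segment survived preprocessing; returning empty result")
        return [], []

    eyes = ("left", "right") if params.eye == "both" else (params.eye,)
    events: list[FPEvent] = []
    all_phase_segments: list[PhaseSegment] = []
    for eye in eyes:
        for seg in segments:
            xs = seg.values(eye)
            ts = seg.times()
            extrema = find_extrema(xs, ts, params.min_gap)
            phase = build_segments(extrema)
            phase = classify_segments(phase, stimulus, params.slope_threshold)
            phase = amplitude_consistency_filter(phase, params.fp_amplitude_factor)
            all_phase_segments.extend(phase)
            for p in phase:
                if p.label == "FP":
                    events.append(refine_fp(p, xs, ts, params.refine_window, eye=eye))
    events.sort(key=lambda e: e.t_peak)
    return events, all_phase_segments


class FastPhaseDetector(BaseEstimator):
    """Estimator-style wrapper around the FP detection pipeline.

    Parameters mirror :class:`DetectionParams` plus the calibration and
    stimulus context.  ``fit(trace)`` runs detection and exposes the results
    as fitted attributes.

    Attributes
    ----------
    events_ : list of FPEvent
        Detected fast phases, sorted by onset time.
    segments_ : list of PhaseSegment
        All labelled phase segments (SP, FP, unclassified).
    times_ : ndarray
        Onset times of the detected fast phases.
    n_events_ : int
    """

    def __init__(
        self,
        calibration: CalibrationModel | None = None,
        stimulus: StimulusSpec | None = None,
        min_gap: float = DEFAULT_MIN_GAP,
        slope_threshold: float | str = "adaptive",
        refine_window: int = 3,
        max_gap_samples: int = 5,
        min_segment_s: float = 0.5,
        eye: str = "left",
        fp_amplitude_factor: float = 0.5,
    ):
        self.calibration = calibration
        self.stimulus = stimulus
        self.min_gap = min_gap
        self.slope_threshold = slope_threshold
        self.refine_window = refine_window
        self.max_gap_samples = max_gap_samples
        self.min_segment_s = min_segment_s
        self.eye = eye
        self.fp_amplitude_factor = fp_amplitude_factor

    def _params(self) -> DetectionParams:
        return DetectionParams(
            min_gap=self.min_gap,
            slope_threshold=self.slope_threshold,
            refine_window=self.refine_window,
            max_gap_samples=self.max_gap_samples,
            min_segment_s=self.min_segment_s,
            eye=self.eye,
            fp_amplitude_factor=self.fp_amplitude_factor,
        )

    def fit(self, trace: GazeTrace, y=None) -> "FastPhaseDetector":
        if self.calibration is None or self.stimulus is None:
            raise ValueError("calibration and stimulus must be set before fit")
        events, segments = detect_fp(trace, self.calibration, self.stimulus, self._params())
        self.events_ = events
        self.segments_ = segments
        self.times_ = np.array([e.t_peak for e in events])
        self.n_events_ = len(events)
        return self

    def fit_detect(self, trace: GazeTrace) -> list[FPEvent]:
        return self.fit(trace).events_
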