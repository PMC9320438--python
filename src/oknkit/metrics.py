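"""OKN summary parameters and detector evaluation.

Clinical OKN analysis summarises a trace by the mean slow-phase velocity
(MSPV, in deg/s) and the gain, the ratio of MSPV to the stimulus speed
(gain near 1 indicates full optokinetic following).  Detector output is
scored against reference fast-phase times (physician marks or simulator
ground truth) by one-to-one matching within a time tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import FPEvent, PhaseSegment, StimulusSpec

__all__ = [
    "OKNMetrics",
    "DetectionEvaluation",
    "mspv",
    "gain",
    "evaluate_detection",
    "compute_metrics",
]


@dataclass(frozen=True)
class OKNMetrics:
    """Per-trace OKN summary: MSPV, gain, fast-phase count and rate."""

    mspv_deg_s: float
    gain: float
    fp_count: int
    fp_rate_hz: float
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "mspv_deg_s": self.mspv_deg_s,
            "gain": self.gain,
            "fp_count": self.fp_count,
            "fp_rate_hz": self.fp_rate_hz,
            "duration_s": self.duration_s,
        }


@dataclass(frozen=True)
class DetectionEvaluation:
    """Match-based scoring of detected vs reference fast-phase times."""

    n_truth: int
    n_detected: int
    n_matched: int
    recognition_rate: float
    tolerance_s: float
    false_positive_rate: float = 0.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recognition_rate
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_detected": self.n_detected,
            "n_matched": self.n_matched,
            "recognition_rate": self.recognition_rate,
            "tolerance_s": self.tolerance_s,
            "false_positive_rate": self.false_positive_rate,
            "precision": self.precision,
            "f1": self.f1,
        }


def mspv(sp_segments: list[PhaseSegment], deg_per_unit: float) -> float:
    """Mean slow-phase velocity in deg/s.

    Mean of |slope| over segments labelled SP, converted from tracker units
    to degrees.  Segments with other labels are ignored; an empty SP list
    yields 0.
    """
    if deg_per_unit <= 0:
        raise ValueError("deg_per_unit must be positive")
    mags = [abs(s.slope) for s in sp_segments if s.label == "SP"]
    if not mags:
        return 0.0
    return float(np.mean(mags)) * deg_per_unit


def gain(mspv_deg_s: float, stimulus_speed: float) -> float:
    """Optokinetic gain: induced slow-phase velocity over stimulus velocity."""
    if stimulus_speed <= 0:
        raise ValueError("stimulus speed must be positive")
    return mspv_deg_s / stimulus_speed


def evaluate_detection(
    detected,
    truth,
    tolerance_s: float = 0.033,
) -> DetectionEvaluation:
    """Greedy one-to-one matching of detected to reference times.

    Reference times are visited in increasing order; each matches the nearest
    unmatched detection within ``tolerance_s`` (ties go to the earlier
    detection).  ``recognition_rate`` is matched/n_truth — the fraction of
    true fast phases found; ``false_positive_rate`` is the fraction of
    detections left unmatched.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be non-negative")
    det = np.sort(np.asarray(list(detected), dtype=float))
    tru = np.sort(np.asarray(list(truth), dtype=float))
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in tru:
        best = -1
        best_dt = np.inf
        for j in range(det.size):
            if used[j]:
                continue
            dt = abs(det[j] - t)
            if dt <= tolerance_s and dt < best_dt:
                best, best_dt = j, dt
        if best >= 0:
            used[best] = True
            matched += 1
    n_truth, n_det = int(tru.size), int(det.size)
    return DetectionEvaluation(
        n_truth=n_truth,
        n_detected=n_det,
        n_matched=matched,
        recognition_rate=matched / n_truth if n_truth else 0.0,
        tolerance_s=tolerance_s,
        false_positive_rate=(n_det - matched) / n_det if n_det else 0.0,
    )


def compute_metrics(
    events: list[FPEvent],
    segments: list[PhaseSegment],
    stimulus: StimulusSpec,
    deg_per_unit: float,
    duration_s: float,
) -> OKNMetrics:
    """Assemble the per-trace OKN summary from detector output."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    m = mspv(segments, deg_per_unit)
    return OKNMetrics(
        mspv_deg_s=m,
        gain=gain(m, stimulus.speed_deg_s),
        fp_count=len(events),
        fp_rate_hz=len(events) / duration_s,
        duration_s=duration_s,
    )
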