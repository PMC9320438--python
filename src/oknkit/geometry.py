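"""Viewing geometry and central-fixation calibration.

The stimulus geometry converts physical extents on the monitor into visual
angles.  The calibration model anchors the outlier filter: during the
calibration sweep the subject fixates points 20 degrees left and right of the
screen center, which spans ``calib_disp`` tracker units between the two
pupil positions.  The full screen is about 30 degrees to each side, i.e.
``calib_disp * 30/20`` units, so a gaze sample farther than half that span
from the central fixation point (CL for the left eye, CR for the right) has
left the screen and is treated as an outlier.

The tracker reports pupil displacement on a scale it labels millimetres; the
magnitudes are far too small for physical millimetres, so this package treats
them as opaque "tracker units" and honours the printed constants verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViewingGeometry",
    "CalibrationModel",
    "visual_angle_deg",
    "derive_calibration",
    "outlier_bounds",
    "truncate_3dp",
    "estimate_central_fixation",
]


@dataclass(frozen=True)
class ViewingGeometry:
    """Physical layout of the display: viewing distance and screen size (cm)."""

    distance_cm: float
    screen_w_cm: float
    screen_h_cm: float

    def __post_init__(self) -> None:
        if min(self.distance_cm, self.screen_w_cm, self.screen_h_cm) <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def h_angle_deg(self) -> float:
        return visual_angle_deg(self.screen_w_cm, self.distance_cm)

    @property
    def v_angle_deg(self) -> float:
        return visual_angle_deg(self.screen_h_cm, self.distance_cm)


def visual_angle_deg(extent_cm: float, distance_cm: float) -> float:
    """Visual angle subtended by ``extent_cm`` viewed from ``distance_cm``.

    Uses the exact symmetric formula ``2 * atan(extent / (2 * distance))``.
    """
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    if extent_cm < 0:
        raise ValueError("extent must be non-negative")
    return math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))


def truncate_3dp(x: float) -> float:
    """Truncate toward zero to 3 decimal places (reproduces printed constants)."""
    return math.trunc(x * 1000.0) / 1000.0


@dataclass(frozen=True)
class CalibrationModel:
    """Per-eye central fixation values and derived outlier/scale constants.

    Attributes
    ----------
    cl, cr : float
        Central fixation coordinate of the left / right eye (tracker units).
    calib_disp : float
        Tracker units spanned by the +-`calib_half_angle_deg` calibration
        sweep (0.031 units for a +-20 degree sweep on the reference setup).
    calib_half_angle_deg, screen_half_angle_deg : float
        Half-angles of the calibration sweep and of the full screen.
    """

    cl: float
    cr: float
    calib_disp: float = 0.031
    calib_half_angle_deg: float = 20.0
    screen_half_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.calib_disp <= 0:
            raise ValueError("calib_disp must be positive")
        if self.calib_half_angle_deg <= 0 or self.screen_half_angle_deg <= 0:
            raise ValueError("calibration angles must be positive")

    @property
    def screen_disp(self) -> float:
        """Tracker units spanned by the full screen (0.0465 on the reference setup)."""
        return self.calib_disp * self.screen_half_angle_deg / self.calib_half_angle_deg

    @property
    def outlier_half_range(self) -> float:
        """Half-range h of the abnormal-point filter: retain iff |x - center| <= h."""
        return self.screen_disp / 2.0

    @property
    def deg_per_unit(self) -> float:
        """Degrees of visual angle per tracker unit."""
        return 2.0 * self.calib_half_angle_deg / self.calib_disp

    def printed_constants(self) -> tuple[float, float]:
        """(full range, half range) truncated to 3 d.p. as conventionally printed."""
        return truncate_3dp(self.screen_disp), truncate_3dp(self.outlier_half_range)

    def center(self, eye: str) -> float:
        if eye == "left":
            return self.cl
        if eye == "right":
            return self.cr
        raise ValueError(f"unknown eye {eye!r}")

    def to_dict(self) -> dict:
        return {
            "cl": self.cl,
            "cr": self.cr,
            "calib_disp": self.calib_disp,
            "calib_half_angle_deg": self.calib_half_angle_deg,
            "screen_half_angle_deg": self.screen_half_angle_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**{k: float(v) for k, v in d.items()})


def derive_calibration(
    cl: float,
    cr: float,
    calib_disp: float = 0.031,
    calib_half_angle_deg: float = 20.0,
    screen_half_angle_deg: float = 30.0,
) -> CalibrationModel:
    """Build a :class:`CalibrationModel` from the calibration sweep span."""
    return CalibrationModel(
        cl=cl,
        cr=cr,
        calib_disp=calib_disp,
        calib_half_angle_deg=calib_half_angle_deg,
        screen_half_angle_deg=screen_half_angle_deg,
    )


def outlier_bounds(center: float, half_range: float) -> tuple[float, float]:
    """Symmetric retention interval around a central fixation value."""
    if half_range < 0:
        raise ValueError("half_range must be non-negative")
    return (center - half_range, center + half_range)


def estimate_central_fixation(trace, window_s: float | None = None) -> tuple[float, float]:
    """Estimate (CL, CR) as the mean of valid samples over a fixation window.

    ``window_s`` limits the estimate to the first ``window_s`` seconds of the
    trace; by default the whole trace is used.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("empty trace")
    mask = np.ones(n, dtype=bool)
    if window_s is not None:
        mask &= trace.t - trace.t[0] <= window_s
    lmask = mask & trace.valid_left & np.isfinite(trace.lpcx)
    rmask = mask & trace.valid_right & np.isfinite(trace.rpcx)
    if not lmask.any() or not rmask.any():
        raise ValueError("no valid samples in fixation window")
    return float(trace.lpcx[lmask].mean()), float(trace.rpcx[rmask].mean())
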