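"""Synthetic binocular OKN traces with exact fast-phase ground truth.

The generator emulates what the low-cost tracker records during a moving
grating session: a sawtooth horizontal gaze trace — slow-phase ramps at the
pursuit velocity interleaved with rapid fast-phase resets at 2–4 per second
— sampled at 150 Hz for both eyes, plus the disturbances that motivate the
abnormal-point filter: blink dropouts (invalid samples), gaze-away
excursions beyond the calibrated screen range, slow sinusoidal drift, and
per-sample jitter.

Layout: a trace of duration D with fast-phase rate r contains
``n_fp = floor(D * r)`` resets separated by ``n_fp + 1`` slow-phase ramps,
so every reset has samples on both sides and every generated fast phase is
in principle detectable.  Each reset exactly cancels the preceding ramp's
excursion, keeping the trace stationary and inside the outlier bounds in
the absence of injected noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .containers import GazeTrace
from .geometry import CalibrationModel, derive_calibration

__all__ = [
    "NoiseSpec",
    "PRESET_NOISE",
    "SyntheticOKNSpec",
    "GroundTruth",
    "generate_okn",
    "inject_noise",
    "write_fixture",
    "read_truth",
    "default_calibration",
]

# Margin (s) by which contaminated windows recorded in the ground truth are
# expanded: a fast phase this close to a dropout loses the neighbouring
# samples its bracketing extrema need.
CONTAMINATION_MARGIN_S = 0.05
# Noise windows are placed at least this far apart and from the trace edges
# so that clean spans always exceed the preprocessing minimum-segment length.
NOISE_MIN_SEPARATION_S = 1.0
NOISE_EDGE_MARGIN_S = 0.6


@dataclass(frozen=True)
class NoiseSpec:
    """Noise mixture parameters; all zero means a clean trace."""

    jitter_sd: float = 0.0  # tracker units, per-sample Gaussian
    blink_rate_hz: float = 0.0  # blinks per second
    blink_len_s: float = 0.15
    drift_amp: float = 0.0  # tracker units, slow sinusoid
    drift_freq_hz: float = 0.1
    gaze_away_count: int = 0
    gaze_away_len_s: float = 0.5
    gaze_away_amp: float = 0.05  # tracker units, beyond the outlier bounds

    def is_zero(self) -> bool:
        return (
            self.jitter_sd == 0
            and self.blink_rate_hz == 0
            and self.drift_amp == 0
            and self.gaze_away_count == 0
        )


# Preset used for the noisy-condition experiments: ~5% of samples lost to
# blinks, three gaze-away excursions, mild drift and sample jitter.
PRESET_NOISE = NoiseSpec(
    jitter_sd=3e-4,
    blink_rate_hz=1.0 / 3.0,
    blink_len_s=0.15,
    drift_amp=0.002,
    drift_freq_hz=0.1,
    gaze_away_count=3,
    gaze_away_len_s=0.5,
    gaze_away_amp=0.05,
)


def default_calibration(cl: float = 0.35, cr: float = 0.40) -> CalibrationModel:
    """Reference calibration: 0.031-unit sweep over +-20 deg, +-30 deg screen."""
    return derive_calibration(cl, cr)


@dataclass(frozen=True)
class SyntheticOKNSpec:
    """Full parameterisation of one simulated OKN recording."""

    duration_s: float = 20.0
    fs: float = 150.0
    direction: str = "left"
    sp_velocity_deg_s: float = 20.0
    fp_rate_hz: float = 3.0
    fp_duration_s: float = 0.03
    deg_per_unit: float = 2.0 * 20.0 / 0.031
    cl: float = 0.35
    cr: float = 0.40
    cycle_jitter_frac: float = 0.1  # +-10% variation of slow-phase lengths
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        if self.fp_rate_hz <= 0:
            raise ValueError("fp_rate_hz must be positive")
        if 1.0 / self.fp_rate_hz <= self.fp_duration_s:
            raise ValueError("fast-phase reset longer than the OKN cycle")
        if self.fs <= 2.0 * self.fp_rate_hz:
            raise ValueError("sampling rate too low for the fast-phase rate")
        if self.sp_velocity_deg_s <= 0 or self.deg_per_unit <= 0:
            raise ValueError("velocities and scale must be positive")
        if not 0.0 <= self.cycle_jitter_frac < 1.0:
            raise ValueError("cycle_jitter_frac must be in [0, 1)")


@dataclass
class GroundTruth:
    """Exact event times and noise windows of a synthetic trace."""

    fp_times: list[float]  # onset (start of reset) in seconds
    fp_amplitudes: list[float]  # tracker units
    sp_slope: float  # tracker units per second (signed)
    fp_duration_s: float
    removed_noise_windows: list[tuple[float, float]] = field(default_factory=list)

    def clean_fp_times(self) -> list[float]:
        """Fast phases whose interval avoids every contaminated window."""
        out = []
        for t in self.fp_times:
            lo, hi = t, t + self.fp_duration_s
            if all(hi < w0 or lo > w1 for w0, w1 in self.removed_noise_windows):
                out.append(t)
        return out

    def to_dict(self) -> dict:
        return {
            "fp_times": list(self.fp_times),
            "fp_amplitudes": list(self.fp_amplitudes),
            "sp_slope": self.sp_slope,
            "fp_duration_s": self.fp_duration_s,
            "removed_noise_windows": [list(w) for w in self.removed_noise_windows],
        }


def _sawtooth(spec: SyntheticOKNSpec, rng: np.random.Generator):
    """Breakpoints of the piecewise-linear sawtooth plus fast-phase onsets."""
    n_fp = math.floor(spec.duration_s * spec.fp_rate_hz)
    sp_total = spec.duration_s - n_fp * spec.fp_duration_s
    base = sp_total / (n_fp + 1)
    if spec.cycle_jitter_frac > 0:
        mult = rng.uniform(1 - spec.cycle_jitter_frac, 1 + spec.cycle_jitter_frac, n_fp + 1)
    else:
        mult = np.ones(n_fp + 1)
    sp_lens = base * mult * (sp_total / (base * mult).sum())

    s = spec.sp_velocity_deg_s / spec.deg_per_unit
    if spec.direction == "right":
        s = -s

    bt, bx = [0.0], [0.0]
    onsets, amps = [], []
    t = x = 0.0
    for i, sp in enumerate(sp_lens):
        t += sp
        x += s * sp
        bt.append(t)
        bx.append(x)
        if i < n_fp:
            onsets.append(t)
            amps.append(abs(s) * sp)
            t += spec.fp_duration_s
            x -= s * sp  # reset exactly cancels the preceding ramp
            bt.append(t)
            bx.append(x)
    return np.array(bt), np.array(bx), onsets, amps, s


def generate_okn(spec: SyntheticOKNSpec) -> tuple[GazeTrace, GroundTruth]:
    """Simulate one binocular OKN recording with known ground truth.

    Deterministic for a fixed spec (including seed).  Noise, if any, is
    applied via :func:`inject_noise` with the same random stream.
    """
    rng = np.random.default_rng(spec.seed)
    bt, bx, onsets, amps, s = _sawtooth(spec, rng)

    n = round(spec.duration_s * spec.fs)
    tk = np.arange(n) / spec.fs
    rel = np.interp(tk, bt, bx)
    rel -= (rel.max() + rel.min()) / 2.0  # center the excursion on the fixation point

    trace = GazeTrace(
        t=tk,
        lpcx=spec.cl + rel,
        rpcx=spec.cr + rel,
        lpcy=np.full(n, 0.5),
        rpcy=np.full(n, 0.5),
        fs=spec.fs,
        source=f"synthetic(seed={spec.seed})",
    )
    truth = GroundTruth(
        fp_times=[float(t) for t in onsets],
        fp_amplitudes=[float(a) for a in amps],
        sp_slope=float(s),
        fp_duration_s=spec.fp_duration_s,
    )
    if not spec.noise.is_zero():
        trace, truth = inject_noise(trace, truth, spec.noise, rng)
    return trace, truth


def _place_windows(
    rng: np.random.Generator,
    duration: float,
    lengths: list[float],
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Place disjoint noise windows with minimum separation; seeded rejection."""
    placed = list(existing)
    new = []
    for length in lengths:
        lo = NOISE_EDGE_MARGIN_S
        hi = duration - NOISE_EDGE_MARGIN_S - length
        if hi <= lo:
            raise ValueError("trace too short to place noise windows")
        for _ in range(10000):
            start = rng.uniform(lo, hi)
            ok = all(
                start > e + NOISE_MIN_SEPARATION_S or start + length < b - NOISE_MIN_SEPARATION_S
                for b, e in placed
            )
            if ok:
                w = (start, start + length)
                placed.append(w)
                new.append(w)
                break
        else:
            raise ValueError("could not place noise windows with required separation")
    return new


def inject_noise(
    trace: GazeTrace,
    truth: GroundTruth,
    noise: NoiseSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[GazeTrace, GroundTruth]:
    """Contaminate a clean trace; the ground truth gains the noise windows.

    Drift and gaze-away excursions move both eyes together (they model head
    movement and looking away); jitter is drawn independently per eye;
    blinks invalidate both eyes and zero the coordinates, as the tracker
    reports when it loses the pupil.
    """
    if noise.is_zero():
        return trace, truth
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = trace.copy()
    n = len(out)
    duration = out.t[-1] - out.t[0] + 1.0 / out.fs

    if noise.drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        drift = noise.drift_amp * np.sin(2 * np.pi * noise.drift_freq_hz * out.t + phase)
        out.lpcx = out.lpcx + drift
        out.rpcx = out.rpcx + drift

    if noise.jitter_sd > 0:
        out.lpcx = out.lpcx + rng.normal(0, noise.jitter_sd, n)
        out.rpcx = out.rpcx + rng.normal(0, noise.jitter_sd, n)

    windows: list[tuple[float, float]] = []

    n_gaze = int(noise.gaze_away_count)
    if n_gaze > 0:
        gw = _place_windows(rng, duration, [noise.gaze_away_len_s] * n_gaze, windows)
        for start, end in gw:
            mask = (out.t >= start) & (out.t < end)
            offset = float(rng.choice([-1.0, 1.0])) * noise.gaze_away_amp
            out.lpcx[mask] += offset
            out.rpcx[mask] += offset
        windows.extend(gw)

    if noise.blink_rate_hz > 0:
        n_blinks = round(noise.blink_rate_hz * duration)
        bw = _place_windows(rng, duration, [noise.blink_len_s] * n_blinks, windows)
        for start, end in bw:
            mask = (out.t >= start) & (out.t < end)
            out.valid_left[mask] = False
            out.valid_right[mask] = False
            out.lpcx[mask] = 0.0
            out.rpcx[mask] = 0.0
        windows.extend(bw)

    expanded = sorted(
        (s - CONTAMINATION_MARGIN_S, e + CONTAMINATION_MARGIN_S) for s, e in windows
    )
    new_truth = replace(
        truth,
        removed_noise_windows=truth.removed_noise_windows + [tuple(w) for w in expanded],
    )
    return out, new_truth


def write_fixture(trace: GazeTrace, truth: GroundTruth, dir_path) -> tuple[Path, Path]:
    """Write the gaze CSV + ground-truth JSON pair for a synthetic recording."""
    import pandas as pd

    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    csv_path = dir_path / "gaze.csv"
    truth_path = dir_path / "truth.json"
    df = pd.DataFrame(
        {
            "TIME": trace.t,
            "LPCX": trace.lpcx,
            "LPCY": trace.lpcy if trace.lpcy is not None else np.nan,
            "RPCX": trace.rpcx,
            "RPCY": trace.rpcy if trace.rpcy is not None else np.nan,
            "LPCV": trace.valid_left.astype(int),
            "RPCV": trace.valid_right.astype(int),
        }
    )
    df.to_csv(csv_path, index=False)
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1))
    return csv_path, truth_path


def read_truth(path) -> GroundTruth:
    """Load a ground-truth JSON written by :func:`write_fixture`."""
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        fp_times=[float(t) for t in d["fp_times"]],
        fp_amplitudes=[float(a) for a in d["fp_amplitudes"]],
        sp_slope=float(d["sp_slope"]),
        fp_duration_s=float(d["fp_duration_s"]),
        removed_noise_windows=[tuple(w) for w in d.get("removed_noise_windows", [])],
    )
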