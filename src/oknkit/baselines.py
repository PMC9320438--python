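"""Comparison methods: naive peak finding, Welch spectra, Fourier series,
and FIR-filter-plus-threshold peak detection.

These are the conventional alternatives to the slope-threshold detector:

* naive peak finding — every strict interior local maximum, no amplitude or
  slope gating; heavily over-detects on noisy traces;
* Welch periodogram — averaged windowed periodogram locating the OKN
  frequency band (fast phases at 2–4 per second put the dominant spectral
  response at 2–4 Hz);
* Fourier series — truncated trigonometric representation of a periodic
  segment, the classical description of the OKN rhythm;
* FIR high-/band-pass filtering — zero-phase filtering isolates the
  fast-phase transients, peaks of the filtered magnitude above an adjustable
  threshold are mapped back to the adjacent raw extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .containers import GazeTrace
from .detection import FPEvent
from .preprocessing import interpolate_invalid

__all__ = [
    "WelchConfig",
    "Spectrum",
    "FourierSeriesModel",
    "naive_peak_finding",
    "welch_psd",
    "dominant_frequency",
    "fourier_series_eval",
    "fit_fourier_series",
    "fir_filter",
    "filtered_peak_detect",
    "default_peak_threshold",
    "NaivePeakDetector",
    "FilteredPeakDetector",
]


@dataclass(frozen=True)
class WelchConfig:
    """Averaged-periodogram settings: segment length M, overlap, window d2."""

    seg_len_m: int = 300  # 2 s at 150 Hz -> 0.5 Hz resolution
    overlap_frac: float = 0.5
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.seg_len_m < 8:
            raise ValueError("seg_len_m must be >= 8")
        if not 0.0 <= self.overlap_frac <= 0.9:
            raise ValueError("overlap_frac must be in [0, 0.9]")


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density on an increasing frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs_hz.size != self.power.size:
            raise ValueError("freqs and power must have equal length")


@dataclass(frozen=True)
class FourierSeriesModel:
    """Truncated Fourier series S(k) = x0/2 + sum_i xi cos(2 pi i T k) + bi sin(...).

    ``fundamental`` is T = 1/period (per unit of k); ``cos_coeffs`` and
    ``sin_coeffs`` hold xi and bi for i = 1..N.
    """

    x0: float
    cos_coeffs: np.ndarray
    sin_coeffs: np.ndarray
    fundamental: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cos_coeffs", np.asarray(self.cos_coeffs, dtype=float))
        object.__setattr__(self, "sin_coeffs", np.asarray(self.sin_coeffs, dtype=float))
        if self.cos_coeffs.size != self.sin_coeffs.size:
            raise ValueError("cos and sin coefficient lists must have equal length")

    @property
    def order(self) -> int:
        return int(self.cos_coeffs.size)


def naive_peak_finding(xs) -> list[int]:
    """Indices of all strict interior local maxima — no gating of any kind."""
    xs = np.asarray(xs, dtype=float)
    if xs.size < 3:
        return []
    interior = xs[1:-1]
    mask = (interior > xs[:-2]) & (interior > xs[2:])
    return [int(i) + 1 for i in np.nonzero(mask)[0]]


def _local_minima(xs: np.ndarray) -> np.ndarray:
    interior = xs[1:-1]
    mask = (interior < xs[:-2]) & (interior < xs[2:])
    return np.nonzero(mask)[0] + 1


def welch_psd(xs, fs: float, config: WelchConfig | None = None) -> Spectrum:
    """Welch averaged periodogram of the gaze series.

    The series is split into L overlapping segments of M samples, each
    windowed by d2(n) and periodogram-averaged with 1/(M U L) normalisation
    (U = mean window power), yielding a one-sided PSD whose integral
    approximates the signal variance.
    """
    xs = np.asarray(xs, dtype=float)
    config = config or WelchConfig()
    if xs.size < config.seg_len_m:
        raise ValueError(
            f"series length {xs.size} shorter than one Welch segment ({config.seg_len_m})"
        )
    freqs, power = signal.welch(
        xs,
        fs=fs,
        window=config.window,
        nperseg=config.seg_len_m,
        noverlap=int(config.overlap_frac * config.seg_len_m),
        detrend="constant",
        scaling="density",
    )
    return Spectrum(freqs_hz=freqs, power=power)


def dominant_frequency(spec: Spectrum, band: tuple[float, float] | None = None) -> float:
    """Frequency of maximum spectral power, optionally within a band.

    Ties resolve to the lowest frequency.
    """
    if spec.freqs_hz.size == 0:
        raise ValueError("empty spectrum")
    mask = np.ones(spec.freqs_hz.size, dtype=bool)
    if band is not None:
        lo, hi = band
        mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
        if not mask.any():
            raise ValueError(f"band {band} contains no spectral bins")
    f = spec.freqs_hz[mask]
    p = spec.power[mask]
    return float(f[int(np.argmax(p))])


def fourier_series_eval(model: FourierSeriesModel, k) -> np.ndarray | float:
    """Evaluate S(k) = x0/2 + sum_i (xi cos(2 pi i T k) + bi sin(2 pi i T k))."""
    k = np.asarray(k, dtype=float)
    i = np.arange(1, model.order + 1)
    phase = 2.0 * np.pi * model.fundamental * np.outer(k, i)
    s = (
        model.x0 / 2.0
        + np.cos(phase) @ model.cos_coeffs
        + np.sin(phase) @ model.sin_coeffs
    )
    return float(s[0]) if s.size == 1 and np.ndim(k) == 0 else s.reshape(k.shape)


def fit_fourier_series(xs) -> FourierSeriesModel:
    """Fit a full-order Fourier series to one period of ``xs`` via the DFT.

    The sample index is the series argument (fundamental T = 1/n), so
    evaluation at k = 0..n-1 reconstructs the series exactly, including the
    Nyquist term for even n.
    """
    xs = np.asarray(xs, dtype=float)
    n = xs.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    X = np.fft.rfft(xs)
    x0 = 2.0 * X[0].real / n
    n_half = n // 2
    cos_c = 2.0 * X[1:].real / n
    sin_c = -2.0 * X[1:].imag / n
    if n % 2 == 0:
        cos_c[-1] = X[n_half].real / n  # Nyquist term appears once, not twice
        sin_c[-1] = 0.0
    return FourierSeriesModel(x0=x0, cos_coeffs=cos_c, sin_coeffs=sin_c, fundamental=1.0 / n)


def fir_filter(xs, fs: float, mode: str, cutoffs, n_taps: int = 101) -> np.ndarray:
    """Zero-phase linear-phase FIR filtering (forward-backward application).

    ``mode`` is "highpass" (one cutoff) or "bandpass" (low, high); cutoffs in
    Hz below the Nyquist frequency; ``n_taps`` must be odd so the high-pass
    design is valid.  Neither mode passes DC, so the series mean is removed
    before filtering: at these cutoff/tap ratios the designed stopband alone
    leaves a few percent of a large DC offset in the output.
    """
    xs = np.asarray(xs, dtype=float)
    xs = xs - (xs.mean() if xs.size else 0.0)
    cut = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if n_taps % 2 == 0 or n_taps < 3:
        raise ValueError("n_taps must be odd and >= 3")
    if np.any(cut <= 0) or np.any(cut >= fs / 2):
        raise ValueError("cutoffs must lie strictly inside (0, fs/2)")
    if mode == "highpass":
        if cut.size != 1:
            raise ValueError("highpass takes a single cutoff")
        taps = signal.firwin(n_taps, cut[0], pass_zero=False, fs=fs)
    elif mode == "bandpass":
        if cut.size != 2 or cut[0] >= cut[1]:
            raise ValueError("bandpass takes (low, high) with low < high")
        taps = signal.firwin(n_taps, cut, pass_zero=False, fs=fs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return signal.filtfilt(taps, [1.0], xs)


def default_peak_threshold(filtered) -> float:
    """Adjustable threshold default: 95th percentile of |filtered|.

    Scale-free, and robust to the band-pass case where the filter passes the
    OKN fundamental itself and the output is near-sinusoidal (a
    median-multiple rule would then exceed the global maximum and detect
    nothing).
    """
    return float(np.percentile(np.abs(np.asarray(filtered, dtype=float)), 95.0))


def filtered_peak_detect(
    filtered,
    raw,
    ts,
    threshold: float | None = None,
    eye: str = "left",
    extremum_order: int | None = None,
) -> list[FPEvent]:
    """Fast-phase events from filtered-magnitude peaks mapped to raw extrema.

    Peaks of |filtered| above ``threshold`` mark candidate fast phases; each
    is paired with the nearest raw local maximum and nearest raw local
    minimum, and duplicate (max, min) pairs are merged.  The onset time is
    the earlier of the two extrema.

    ``extremum_order`` is the neighbourhood (in samples, each side) a raw
    extremum must dominate.  The "adjacent maximum/minimum" sought are the
    high and low points of a fast phase, which dominate the raw series on
    the saccade timescale; the default is 40 ms of samples (6 at 150 Hz),
    which keeps the mapping from latching onto per-sample jitter wiggles
    while leaving it local to the filtered peak.  Order 1 reduces to naive
    strict extrema.
    """
    filtered = np.asarray(filtered, dtype=float)
    raw = np.asarray(raw, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if not (filtered.size == raw.size == ts.size):
        raise ValueError("filtered, raw and ts must have equal length")
    if extremum_order is None:
        fs = 1.0 / float(np.median(np.diff(ts))) if ts.size > 1 else 150.0
        extremum_order = max(1, round(0.04 * fs))
    if extremum_order < 1:
        raise ValueError("extremum_order must be >= 1")
    if threshold is None:
        threshold = default_peak_threshold(filtered)

    mag = np.abs(filtered)
    peaks, _ = signal.find_peaks(mag, height=threshold)
    if peaks.size == 0:
        return []

    if extremum_order == 1:
        maxima = np.asarray(naive_peak_finding(raw))
        minima = _local_minima(raw)
    else:
        maxima = signal.argrelextrema(raw, np.greater, order=extremum_order)[0]
        minima = signal.argrelextrema(raw, np.less, order=extremum_order)[0]
    if maxima.size == 0 or minima.size == 0:
        return []

    def nearest(cands: np.ndarray, p: int) -> int:
        j = int(np.searchsorted(cands, p))
        best = None
        for k in (j - 1, j):
            if 0 <= k < cands.size:
                if best is None or abs(cands[k] - p) < abs(cands[best] - p):
                    best = k
        return int(cands[best])

    events: dict[tuple[int, int], FPEvent] = {}
    for p in peaks:
        hi = nearest(maxima, int(p))
        lo = nearest(minima, int(p))
        key = (hi, lo)
        if key in events:
            continue
        events[key] = FPEvent(
            t_high=float(ts[hi]),
            t_low=float(ts[lo]),
            x_high=float(raw[hi]),
            x_low=float(raw[lo]),
            t_peak=float(min(ts[hi], ts[lo])),
            amplitude=abs(float(raw[hi] - raw[lo])),
            duration=abs(float(ts[hi] - ts[lo])),
            eye=eye,
        )
    return sorted(events.values(), key=lambda e: e.t_peak)


class NaivePeakDetector(BaseEstimator):
    """Baseline: every strict local maximum is reported as a fast phase."""

    def __init__(self, eye: str = "left"):
        self.eye = eye

    def fit(self, trace: GazeTrace, y=None) -> "NaivePeakDetector":
        xs = interpolate_invalid(trace, self.eye)
        idx = naive_peak_finding(xs)
        self.peak_indices_ = idx
        self.times_ = trace.t[idx] if idx else np.array([])
        self.n_events_ = len(idx)
        return self


class FilteredPeakDetector(BaseEstimator):
    """Baseline: zero-phase FIR filtering plus thresholded peak detection.

    ``mode`` selects high-pass (default cutoff 1.5 Hz, isolating fast-phase
    transients) or band-pass (default 2–4 Hz, the OKN band).  ``threshold``
    of None uses :func:`default_peak_threshold` on the filtered magnitude.
    """

    def __init__(
        self,
        mode: str = "highpass",
        cutoffs=None,
        n_taps: int = 101,
        threshold: float | None = None,
        eye: str = "left",
    ):
        self.mode = mode
        self.cutoffs = cutoffs
        self.n_taps = n_taps
        self.threshold = threshold
        self.eye = eye

    def _cutoffs(self):
        if self.cutoffs is not None:
            return self.cutoffs
        return 1.5 if self.mode == "highpass" else (2.0, 4.0)

    def fit(self, trace: GazeTrace, y=None) -> "FilteredPeakDetector":
        xs = interpolate_invalid(trace, self.eye)
        filtered = fir_filter(xs, trace.fs, self.mode, self._cutoffs(), self.n_taps)
        self.filtered_ = filtered
        self.threshold_ = (
            default_peak_threshold(filtered) if self.threshold is None else self.threshold
        )
        self.events_ = filtered_peak_detect(filtered, xs, trace.t, self.threshold_, self.eye)
        self.times_ = np.array([e.t_peak for e in self.events_])
        self.n_events_ = len(self.events_)
        return self
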