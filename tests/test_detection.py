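import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oknkit.containers import GazeTrace
from oknkit.detection import (
    DetectionParams,
    ExtremumPoint,
    FastPhaseDetector,
    PhaseSegment,
    StimulusSpec,
    amplitude_consistency_filter,
    build_segments,
    classify_segments,
    detect_fp,
    find_extrema,
    refine_fp,
)
from oknkit.synthetic import SyntheticOKNSpec, generate_okn

from _reference import reference_extrema


def ts_for(xs, fs=150.0):
    return np.arange(len(xs)) / fs


def assert_matches_reference(xs, min_gap=0.001):
    ts = ts_for(xs)
    got = [(e.idx, e.kind) for e in find_extrema(xs, ts, min_gap)]
    want = [(i, k) for i, _, _, k in reference_extrema(xs, ts, min_gap)]
    assert got == want


class TestFindExtrema:
    def test_monotone_has_no_extrema(self):
        xs = np.linspace(0, 1, 50)
        assert find_extrema(xs, ts_for(xs)) == []

    def test_triangle_single_max(self):
        xs = np.array([0.0, 0.01, 0.02, 0.01, 0.0])
        out = find_extrema(xs, ts_for(xs))
        assert [(e.idx, e.kind) for e in out] == [(2, "max")]

    def test_small_wiggles_suppressed_on_sawtooth(self):
        # sawtooth apices 0.005 apart in value, wiggle amplitude 0.0005
        fs = 150.0
        t = np.arange(450) / fs
        saw = 0.005 * np.mod(t * 3, 1.0)  # rising ramps, sharp resets, 3 cycles/s
        wiggle = 0.0005 * np.sin(2 * np.pi * 20 * t)
        out = find_extrema(saw + wiggle, t, min_gap=0.001)
        # one max and one min per sawtooth cycle survive; the 20 Hz wiggle does not
        kinds = [e.kind for e in out]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        gaps = [abs(b.x - a.x) for a, b in zip(out, out[1:])]
        assert min(gaps) > 0.001
        assert 8 <= sum(k == "max" for k in kinds) <= 10  # 9 cycles in 3 s

    def test_plateau_takes_first_index(self):
        xs = np.array([0.0, 0.01, 0.01, 0.01, 0.0])
        out = find_extrema(xs, ts_for(xs))
        assert [(e.idx, e.kind) for e in out] == [(1, "max")]

    def test_endpoints_never_candidates(self):
        xs = np.array([0.02, 0.0, 0.02])
        out = find_extrema(xs, ts_for(xs))
        assert [(e.idx, e.kind) for e in out] == [(1, "min")]

    def test_too_short_series(self):
        assert find_extrema(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == []

    def test_equivalence_with_bruteforce_oracle_on_random_series(self, rng):
        """Gated extrema equal a naive neighbour-scan + sequential gating oracle."""
        for trial in range(1000):
            n = int(rng.integers(3, 200))
            kind = trial % 3
            if kind == 0:
                xs = rng.normal(0, 0.003, n)
            elif kind == 1:  # quantised to force plateaus and ties
                xs = np.round(rng.normal(0, 0.003, n), 3)
            else:  # sawtooth-ish with noise
                t = np.arange(n) / 150.0
                xs = 0.005 * np.mod(t * 3, 1.0) + rng.normal(0, 0.0005, n)
            assert_matches_reference(xs)

    @given(
        st.lists(
            st.floats(min_value=-0.01, max_value=0.01, allow_nan=False),
            min_size=3,
            max_size=60,
        ),
        st.sampled_from([0.0, 0.0005, 0.001, 0.005]),
    )
    def test_alternation_and_gap_invariants(self, values, min_gap):
        xs = np.asarray(values)
        out = find_extrema(xs, ts_for(xs), min_gap)
        kinds = [e.kind for e in out]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        for a, b in zip(out, out[1:]):
            assert abs(b.x - a.x) > min_gap


class TestBuildSegments:
    def test_two_extrema_slope(self):
        a = ExtremumPoint(0, 0.0, 0.0, "min")
        b = ExtremumPoint(75, 0.5, 0.00155, "max")
        (seg,) = build_segments([a, b])
        assert seg.slope == pytest.approx(0.0031)

    def test_empty_and_singleton(self):
        assert build_segments([]) == []
        assert build_segments([ExtremumPoint(0, 0.0, 0.0, "min")]) == []

    def test_five_alternating_extrema_alternating_slopes(self):
        pts = [
            ExtremumPoint(i, i * 0.1, x, k)
            for i, (x, k) in enumerate(
                [(0.0, "min"), (0.01, "max"), (0.002, "min"), (0.012, "max"), (0.004, "min")]
            )
        ]
        segs = build_segments(pts)
        assert len(segs) == 4
        signs = [np.sign(s.slope) for s in segs]
        assert signs == [1, -1, 1, -1]

    def test_non_alternating_rejected(self):
        pts = [ExtremumPoint(0, 0.0, 0.0, "max"), ExtremumPoint(1, 0.1, 1.0, "max")]
        with pytest.raises(ValueError):
            build_segments(pts)


def _seg(slope, t0=0.0, dt=0.1, label="unclassified"):
    kinds = ("min", "max") if slope > 0 else ("max", "min")
    a = ExtremumPoint(0, t0, 0.0, kinds[0])
    b = ExtremumPoint(1, t0 + dt, slope * dt, kinds[1])
    return PhaseSegment(start=a, end=b, slope=slope, label=label)


class TestClassifySegments:
    @pytest.mark.parametrize(
        "direction,slope,expected",
        [
            ("left", +0.005, "SP"),
            ("left", -0.05, "FP"),
            ("right", +0.05, "FP"),
            ("right", -0.005, "SP"),
            ("left", 0.0, "unclassified"),
        ],
    )
    def test_sign_convention(self, direction, slope, expected):
        stim = StimulusSpec(direction=direction, speed_deg_s=20)
        (out,) = classify_segments([_seg(slope)], stim, m_threshold=0.01)
        assert out.label == expected

    def test_shallow_opposite_slope_unclassified(self):
        stim = StimulusSpec(direction="left", speed_deg_s=20)
        (out,) = classify_segments([_seg(-0.005)], stim, m_threshold=0.01)
        assert out.label == "unclassified"

    def test_adaptive_threshold_separates_sawtooth(self):
        stim = StimulusSpec(direction="left", speed_deg_s=20)
        segs = [_seg(+0.0155), _seg(-0.155), _seg(+0.0155), _seg(-0.155), _seg(+0.0155)]
        out = classify_segments(segs, stim, "adaptive")
        assert [s.label for s in out] == ["SP", "FP", "SP", "FP", "SP"]


class TestAmplitudeConsistencyFilter:
    def _fp(self, amp, t0=0.0):
        a = ExtremumPoint(0, t0, amp, "max")
        b = ExtremumPoint(1, t0 + 0.03, 0.0, "min")
        return PhaseSegment(start=a, end=b, slope=-amp / 0.03, label="FP")

    def _sp(self, amp, t0=0.0):
        a = ExtremumPoint(0, t0, 0.0, "min")
        b = ExtremumPoint(1, t0 + 0.3, amp, "max")
        return PhaseSegment(start=a, end=b, slope=amp / 0.3, label="SP")

    def test_micro_candidates_demoted(self):
        segs = [self._sp(0.005), self._fp(0.005), self._sp(0.005), self._fp(0.0012)]
        out = amplitude_consistency_filter(segs, factor=0.5)
        assert [s.label for s in out] == ["SP", "FP", "SP", "unclassified"]

    def test_uniform_sawtooth_untouched(self):
        segs = [self._sp(0.005), self._fp(0.005), self._sp(0.005), self._fp(0.005)]
        out = amplitude_consistency_filter(segs, factor=0.5)
        assert [s.label for s in out] == [s.label for s in segs]

    def test_disabled_or_unanchored_is_noop(self):
        segs = [self._fp(0.0001)]
        assert amplitude_consistency_filter(segs, factor=0.0) == segs
        assert amplitude_consistency_filter(segs, factor=0.5) == segs  # no SP anchor


class TestRefineFP:
    def test_exact_endpoints_unchanged(self):
        xs = np.array([0.0, 0.004, 0.005, 0.001, 0.0, 0.002])
        ts = ts_for(xs)
        seg = PhaseSegment(
            start=ExtremumPoint(2, ts[2], xs[2], "max"),
            end=ExtremumPoint(4, ts[4], xs[4], "min"),
            slope=(xs[4] - xs[2]) / (ts[4] - ts[2]),
            label="FP",
        )
        ev = refine_fp(seg, xs, ts, window=3)
        assert ev.t_high == ts[2] and ev.t_low == ts[4]
        assert ev.amplitude == pytest.approx(0.005)

    def test_endpoint_moves_to_higher_raw_sample(self):
        xs = np.zeros(20)
        xs[10] = 0.0050
        xs[11] = 0.0052  # true raw max one sample later
        xs[15] = -0.005
        ts = ts_for(xs)
        seg = PhaseSegment(
            start=ExtremumPoint(10, ts[10], xs[10], "max"),
            end=ExtremumPoint(15, ts[15], xs[15], "min"),
            slope=-1.0,
            label="FP",
        )
        ev = refine_fp(seg, xs, ts, window=3)
        assert ev.t_high == ts[11]
        assert ev.amplitude >= 0.0102 - 1e-12  # never below the original amplitude

    def test_window_zero_keeps_endpoints(self):
        xs = np.array([0.0, 0.004, 0.005, 0.001, 0.0, 0.002])
        ts = ts_for(xs)
        seg = PhaseSegment(
            start=ExtremumPoint(2, ts[2], xs[2], "max"),
            end=ExtremumPoint(4, ts[4], xs[4], "min"),
            slope=-1.0,
            label="FP",
        )
        ev = refine_fp(seg, xs, ts, window=0)
        assert (ev.t_high, ev.t_low) == (ts[2], ts[4])

    def test_requires_fp_label(self):
        seg = _seg(0.01, label="SP")
        with pytest.raises(ValueError):
            refine_fp(seg, np.zeros(5), ts_for(np.zeros(5)))


class TestDetectFP:
    def test_clean_synthetic_recovers_all_events(self, calib, stimulus_left, clean_fixture):
        spec, trace, truth = clean_fixture
        events, segments = detect_fp(trace, calib, stimulus_left)
        assert len(events) == len(truth.fp_times) == 60
        # every event within 2 samples of its ground-truth onset
        dt = 2 / spec.fs
        for ev, t_true in zip(events, truth.fp_times):
            assert abs(ev.t_peak - t_true) <= dt + 1e-12
        # FP slopes oppose SP slopes throughout
        sp = {np.sign(s.slope) for s in segments if s.label == "SP"}
        fp = {np.sign(s.slope) for s in segments if s.label == "FP"}
        assert sp == {1.0} and fp == {-1.0}

    def test_constant_trace_no_events(self, calib, stimulus_left):
        n = 600
        trace = GazeTrace(
            t=np.arange(n) / 150.0, lpcx=np.full(n, 0.35), rpcx=np.full(n, 0.40), fs=150.0
        )
        events, segments = detect_fp(trace, calib, stimulus_left)
        assert events == []

    def test_gaze_away_spans_removed_recall_kept(self, calib):
        from dataclasses import replace
        from oknkit.synthetic import NoiseSpec
        from oknkit.metrics import evaluate_detection

        spec = SyntheticOKNSpec(seed=7, noise=NoiseSpec(gaze_away_count=3))
        trace, truth = generate_okn(spec)
        stim = StimulusSpec("left", 20)
        events, _ = detect_fp(trace, calib, stim)
        ev = evaluate_detection([e.t_peak for e in events], truth.clean_fp_times(), 0.033)
        assert ev.recognition_rate == 1.0

    @pytest.mark.parametrize("speed", [10, 20, 30, 40])
    @pytest.mark.parametrize("direction", ["left", "right"])
    def test_full_recognition_across_speeds_and_directions(self, calib, speed, direction):
        spec = SyntheticOKNSpec(
            seed=5, duration_s=10.0, sp_velocity_deg_s=speed, direction=direction
        )
        trace, truth = generate_okn(spec)
        events, _ = detect_fp(trace, calib, StimulusSpec(direction, speed))
        assert len(events) == len(truth.fp_times)
        for ev_t, t_true in zip([e.t_peak for e in events], truth.fp_times):
            assert abs(ev_t - t_true) <= 0.033

    def test_mirror_symmetry(self, calib):
        """Mirroring the trace about the fixation centers and flipping the
        stimulus direction yields identical fast-phase times."""
        from oknkit.synthetic import PRESET_NOISE

        spec = SyntheticOKNSpec(seed=9, noise=PRESET_NOISE)
        trace, _ = generate_okn(spec)
        mirrored = trace.copy()
        mirrored.lpcx = 2 * 0.35 - mirrored.lpcx
        mirrored.rpcx = 2 * 0.40 - mirrored.rpcx
        ev_l, _ = detect_fp(trace, calib, StimulusSpec("left", 20))
        ev_r, _ = detect_fp(mirrored, calib, StimulusSpec("right", 20))
        assert [e.t_peak for e in ev_l] == [e.t_peak for e in ev_r]

    def test_right_eye_channel(self, calib, stimulus_left, clean_fixture):
        _, trace, truth = clean_fixture
        events, _ = detect_fp(
            trace, calib, stimulus_left, DetectionParams(eye="right")
        )
        assert len(events) == len(truth.fp_times)
        assert all(e.eye == "right" for e in events)


class TestFastPhaseDetectorEstimator:
    def test_fit_exposes_results(self, calib, stimulus_left, clean_fixture):
        _, trace, truth = clean_fixture
        det = FastPhaseDetector(calibration=calib, stimulus=stimulus_left).fit(trace)
        assert det.n_events_ == len(truth.fp_times)
        assert det.times_.shape == (det.n_events_,)

    def test_get_set_params_round_trip(self, calib, stimulus_left):
        det = FastPhaseDetector(calibration=calib, stimulus=stimulus_left)
        params = det.get_params()
        assert params["min_gap"] == 0.001
        det.set_params(min_gap=0.002, eye="right")
        assert det.min_gap == 0.002 and det.eye == "right"

    def test_fit_without_context_raises(self, clean_fixture):
        _, trace, _ = clean_fixture
        with pytest.raises(ValueError):
            FastPhaseDetector().fit(trace)
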