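"""Normalization and response-criteria unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vnokit._util import DataError
from vnokit.protocol import Application, StimulusProtocol
from vnokit.traces import (
    BaselineStats,
    KnobTrace,
    NormalizedTrace,
    ResponseCall,
    analyze_trace,
    baseline_stats,
    call_responder,
    detect_response,
    normalize_trace,
)


def _trace(values, knob="k0"):
    return KnobTrace("s0", knob, np.asarray(values, dtype=float))


class TestNormalize:
    def test_constant_trace_becomes_all_ones(self, protocol):
        norm = normalize_trace(_trace(np.full(600, 500.0)), protocol)
        assert np.allclose(norm.ratio, 1.0)
        assert norm.f0 == pytest.approx(500.0)

    def test_scale_invariance(self, protocol, rng):
        raw = rng.uniform(100, 200, size=600)
        a = normalize_trace(_trace(raw), protocol)
        b = normalize_trace(_trace(3.0 * raw), protocol)
        np.testing.assert_allclose(a.ratio, b.ratio, rtol=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance_property(self, scale):
        proto = StimulusProtocol(baseline_window=(0, 10), applications=[])
        raw = np.linspace(50, 150, 30)
        a = normalize_trace(_trace(raw), proto)
        b = normalize_trace(_trace(scale * raw), proto)
        np.testing.assert_allclose(a.ratio, b.ratio, rtol=1e-9)

    def test_baseline_mean_is_one(self, protocol, rng):
        raw = rng.uniform(100, 200, size=600)
        norm = normalize_trace(_trace(raw), protocol)
        b0, b1 = protocol.baseline_window
        assert norm.ratio[b0:b1].mean() == pytest.approx(1.0)

    def test_planted_transient_peak_from_generator_params(self, protocol):
        # noiseless 20% transient: normalized peak must equal 1.20 exactly
        # at the kernel peak (unit-peak kernel times 0.2 amplitude)
        from vnokit.synth import transient_kernel

        raw = np.full(600, 400.0)
        onset = protocol.applications[0].onset_frame
        t = (np.arange(600) - onset) * protocol.frame_interval_s - 3.0
        raw = raw * (1 + 0.2 * transient_kernel(t, 3.0, 15.0))
        norm = normalize_trace(_trace(raw), protocol)
        assert norm.ratio.max() == pytest.approx(1.2, abs=1e-3)

    def test_zero_baseline_is_data_error(self, protocol):
        with pytest.raises(DataError, match="k0"):
            normalize_trace(_trace(np.zeros(600)), protocol)

    def test_short_trace_is_data_error(self, protocol):
        with pytest.raises(DataError):
            normalize_trace(_trace(np.ones(10)), protocol)


class TestBaselineStats:
    def test_all_ones(self, protocol):
        norm = normalize_trace(_trace(np.full(600, 7.0)), protocol)
        stats = baseline_stats(norm, protocol)
        assert stats.mean_b == pytest.approx(1.0)
        assert stats.sd_b == pytest.approx(0.0)

    def test_alternating_hand_value(self):
        # 0.99/1.01 alternating over 50 frames: every deviation is 0.01, so
        # the sample SD is 0.01 * sqrt(n/(n-1)) = 0.010102
        proto = StimulusProtocol(baseline_window=(0, 50), applications=[])
        vals = np.tile([0.99, 1.01], 25)
        stats = baseline_stats(NormalizedTrace("s", "k", vals, 1.0), proto)
        assert stats.mean_b == pytest.approx(1.0)
        assert stats.sd_b == pytest.approx(np.sqrt(50 / 49) * 0.01, rel=1e-9)
        assert stats.sd_b == pytest.approx(0.0101, abs=5e-5)

    def test_gaussian_noise_sd_within_sampling_bounds(self, protocol, rng):
        # SE of a sample SD (n=50) is sigma/sqrt(2(n-1)) = sigma/sqrt(98)
        raw = 1.0 + rng.normal(0, 0.02, size=600)
        stats = baseline_stats(NormalizedTrace("s", "k", raw, 1.0), protocol)
        assert abs(stats.sd_b - 0.02) < 3 * 0.02 / np.sqrt(98)

    def test_window_too_short(self):
        proto = StimulusProtocol(baseline_window=(0, 1), applications=[])
        with pytest.raises(ValueError):
            baseline_stats(NormalizedTrace("s", "k", np.ones(5), 1.0), proto)


def _norm(values):
    return NormalizedTrace("s0", "k0", np.asarray(values, dtype=float), 1.0)


class TestDetectResponse:
    def test_flat_noise_below_threshold_not_responded(self, short_protocol):
        vals = np.ones(150)
        vals[70] = 1.015  # single frame, below 1.02 threshold anyway
        call = detect_response(
            _norm(vals), BaselineStats(1.0, 0.01),
            short_protocol.applications[0], short_protocol,
        )
        assert not call.responded
        assert call.first_crossing_frame is None

    def test_step_response_latency(self, short_protocol):
        # sustained step to 1.05 starting 3 frames after onset, sd_b = 0.01
        onset = short_protocol.applications[0].onset_frame
        vals = np.ones(150)
        vals[onset + 3 :] = 1.05
        call = detect_response(
            _norm(vals), BaselineStats(1.0, 0.01),
            short_protocol.applications[0], short_protocol,
        )
        assert call.responded
        assert call.first_crossing_frame == onset + 3
        assert call.latency_s == pytest.approx(4.5)
        assert call.peak_amplitude >= 1.02

    def test_excursion_after_latency_window_rejected(self):
        # a deviation starting 70 s after onset violates the 1-min criterion
        proto = StimulusProtocol(applications=[Application("A", 60), Application("A", 210)])
        onset = 60
        late = onset + int(70 / 1.5) + 1  # first frame later than 70 s
        vals = np.ones(300)
        vals[late : late + 10] = 1.10
        call = detect_response(_norm(vals), BaselineStats(1.0, 0.01),
                               proto.applications[0], proto)
        assert not call.responded

    def test_crossing_at_exactly_60s_counts(self, short_protocol):
        onset = short_protocol.applications[0].onset_frame
        f60 = onset + 40  # 40 frames x 1.5 s = 60 s exactly
        vals = np.ones(180)
        vals[f60 : f60 + 5] = 1.05
        call = detect_response(_norm(vals), BaselineStats(1.0, 0.01),
                               short_protocol.applications[0], short_protocol)
        assert call.responded
        assert call.latency_s == pytest.approx(60.0)

    def test_window_exceeding_trace_is_data_error(self, short_protocol):
        with pytest.raises(DataError):
            detect_response(_norm(np.ones(80)), BaselineStats(1.0, 0.01),
                            short_protocol.applications[1], short_protocol)

    def test_single_frame_rule_recovered_with_min_frames_one(self, short_protocol):
        onset = short_protocol.applications[0].onset_frame
        vals = np.ones(150)
        vals[onset + 5] = 1.05  # one isolated frame
        args = (_norm(vals), BaselineStats(1.0, 0.01),
                short_protocol.applications[0], short_protocol)
        assert not detect_response(*args).responded
        assert detect_response(*args, min_frames_above=1).responded


def _call(responded, stim="A", idx=0):
    return ResponseCall("k0", stim, idx, responded)


class TestCallResponder:
    @pytest.mark.parametrize(
        "pattern,expected",
        [((True, True), True), ((True, False), False), ((False, True), False),
         ((False, False), False), ((True, True, False), False),
         ((True, True, True), True)],
    )
    def test_all_applications_rule(self, short_protocol, pattern, expected):
        calls = [_call(r, idx=i) for i, r in enumerate(pattern)]
        assert call_responder(calls, short_protocol) is expected

    def test_too_few_applications_is_data_error(self, short_protocol):
        with pytest.raises(DataError):
            call_responder([_call(True)], short_protocol)

    def test_mixed_stimuli_rejected(self, short_protocol):
        with pytest.raises(ValueError):
            call_responder([_call(True, "A"), _call(True, "B")], short_protocol)


def _oracle_detect(ratio, b0, b1, onset, lat_frames, mult, k):
    """Exhaustive frame-by-frame check of the full response rule.

    A response starts at the first frame f within the latency window whose
    next k frames (confirmation may extend past the window but not past the
    trace) all exceed the baseline threshold.
    """
    base = ratio[b0:b1]
    thr = base.mean() + mult * base.std(ddof=1)
    for f in range(onset, onset + lat_frames + 1):
        if f + k <= len(ratio) and all(ratio[g] > thr for g in range(f, f + k)):
            return f
    return None


class TestOracleEquivalence:
    """detect_response must agree exactly with brute-force scanning."""

    @given(
        data=st.lists(
            st.floats(min_value=0.5, max_value=1.5, allow_nan=False), min_size=20,
            max_size=20,
        ),
        k=st.integers(min_value=1, max_value=3),
    )
    def test_toy_traces(self, data, k):
        ratio = np.asarray(data)
        ratio[:5] = np.abs(ratio[:5]) + 0.5  # keep baseline positive
        proto = StimulusProtocol(
            baseline_window=(0, 5), latency_window_s=6.0, min_interstimulus_s=0,
            applications=[Application("A", 6), Application("A", 14)],
            frame_interval_s=1.5,
        )
        norm = NormalizedTrace("s", "k", ratio, 1.0)
        stats = baseline_stats(norm, proto)
        for app in proto.applications:
            call = detect_response(norm, stats, app, proto, min_frames_above=k)
            expect = _oracle_detect(ratio, 0, 5, app.onset_frame,
                                    proto.latency_window_frames, 2.0, k)
            assert call.responded == (expect is not None)
            assert call.first_crossing_frame == expect


class TestMonotonicity:
    def test_threshold_multiplier_never_increases_responders(self, short_protocol, rng):
        n = 300
        responders = {}
        traces = [
            KnobTrace("s0", f"k{i}", 100 * (1 + rng.normal(0, 0.02, 150)
                                            + (0.08 if i < 50 else 0.0)
                                            * (np.arange(150) > 60)))
            for i in range(n)
        ]
        for mult in (1.0, 2.0, 3.0):
            resp = {
                t.knob_id
                for t in traces
                if analyze_trace(t, short_protocol, threshold_multiplier=mult)
                .responder["A"]
            }
            responders[mult] = resp
        assert responders[3.0] <= responders[2.0] <= responders[1.0]

    def test_repeatable_responders_subset_of_single_application(
        self, short_protocol, rng
    ):
        both, single = 0, 0
        for i in range(400):
            raw = 100 * (1 + rng.normal(0, 0.02, 150))
            res = analyze_trace(KnobTrace("s", f"k{i}", raw), short_protocol,
                                min_frames_above=1)
            first = res.calls[0].responded
            single += first
            repeat = res.responder["A"]
            both += repeat
            assert not (repeat and not first)
        assert both < single  # strict on pure noise at this sample size
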