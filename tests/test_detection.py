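"""Detector behaviour against planted ground truth and hand-built cases."""

import numpy as np
import pytest

from zfeeg import Recording, TimelineMarks, bandpass
from zfeeg.detect import (
    DetectorParams,
    classify_event,
    compute_baseline_stats,
    detect_discharges,
    detect_events,
    flag_se,
    segment_events,
)
from zfeeg.synthetic import BASELINE_P2P_UV, _UNIT_P2P_FACTOR, generate_baseline, generate_ictal_segment
from zfeeg.types import ConfigurationError, InvalidArgumentError, SeizureEvent

FS = 250.0
MARKS = TimelineMarks(injection_time=120.0, session_end=600.0)


def _baseline_recording(seed=0, marks=MARKS, fs=FS):
    return Recording(
        samples=generate_baseline(marks.session_end, fs, 4, seed),
        fs=fs,
        montage={1: "rt", 2: "lt", 3: "pl", 4: "pr"},
        marks=marks,
    )


def _plant(rec, channel, onset, segment):
    i0 = int(onset * rec.fs)
    rec.samples[channel - 1, i0 : i0 + len(segment)] += segment
    return rec


class TestBaselineStats:
    def test_scale_matches_generator_noise(self):
        # generator noise std is p2p / unit factor; MAD of Gaussian-like
        # noise is ~0.674 sigma -> check within 20%
        stats = compute_baseline_stats(_baseline_recording())
        expected = 0.6745 * BASELINE_P2P_UV / _UNIT_P2P_FACTOR
        assert np.all(np.abs(stats.mad / expected - 1.0) < 0.2)

    def test_constant_zero_recording_is_degenerate(self):
        rec = _baseline_recording()
        rec.samples[:] = 0.0
        with pytest.raises(InvalidArgumentError):
            compute_baseline_stats(rec)

    def test_causal_window_only(self):
        rec_a = _baseline_recording(seed=5)
        rec_b = _baseline_recording(seed=5)
        rec_b.samples[:, int(MARKS.injection_time * FS) + 10 :] += 500.0
        a = compute_baseline_stats(rec_a)
        b = compute_baseline_stats(rec_b)
        np.testing.assert_array_equal(a.mad, b.mad)

    def test_short_control_window_rejected(self):
        marks = TimelineMarks(injection_time=30.0, session_end=300.0)
        with pytest.raises(ConfigurationError):
            compute_baseline_stats(_baseline_recording(marks=marks))


class TestDetectDischarges:
    def test_planted_spike_wave_train_found(self):
        rec = _baseline_recording(seed=1)
        seg = generate_ictal_segment("spike_wave", 30, FS, 2.5, 80.0, seed=2)
        _plant(rec, 2, 300.0, seg)
        rec = bandpass(rec)
        stats = compute_baseline_stats(rec)
        cands = detect_discharges(rec, stats)
        overlaps = [
            (max(0.0, min(e, 330.0) - max(s, 300.0)))
            / (max(e, 330.0) - min(s, 300.0))
            for s, e in cands[1]
        ]
        assert overlaps and max(overlaps) >= 0.8
        assert all(not ch for i, ch in enumerate(cands) if i != 1)

    def test_slow_1hz_spike_train_ignored(self):
        # 1 Hz biphasic spikes are below the >2.5/s repetition-rate rule
        rec = _baseline_recording(seed=2)
        n = int(30 * FS)
        t = np.arange(n) / FS
        spikes = np.zeros(n)
        width = int(0.04 * FS)
        lobe = np.sin(np.pi * np.arange(width) / width)
        for k in range(30):
            i = int(k * FS)
            spikes[i : i + width] += 60.0 * lobe
            spikes[i + width : i + 2 * width] -= 50.0 * lobe
        _plant(rec, 1, 300.0, spikes)
        rec = bandpass(rec)
        cands = detect_discharges(rec, compute_baseline_stats(rec))
        assert all(not ch for ch in cands)

    def test_pure_baseline_no_candidates(self):
        rec = bandpass(_baseline_recording(seed=3))
        cands = detect_discharges(rec, compute_baseline_stats(rec))
        assert all(not ch for ch in cands)

    def test_sign_flip_invariance(self):
        rec = _baseline_recording(seed=4)
        seg = generate_ictal_segment("theta", 20, FS, 6.0, 100.0, seed=5)
        _plant(rec, 3, 250.0, seg)
        rec = bandpass(rec)
        flipped = Recording(
            samples=-rec.samples, fs=rec.fs, montage=rec.montage, marks=rec.marks
        )
        a = detect_discharges(rec, compute_baseline_stats(rec))
        b = detect_discharges(flipped, compute_baseline_stats(flipped))
        assert a == b

    def test_candidates_start_after_stabilization(self):
        rec = _baseline_recording(seed=6)
        seg = generate_ictal_segment("theta", 60, FS, 6.0, 120.0, seed=7)
        # plant straddling the stabilization boundary (ends at 210 s)
        _plant(rec, 1, 180.0, seg)
        rec = bandpass(rec)
        cands = detect_discharges(rec, compute_baseline_stats(rec))
        for ch in cands:
            for s, _ in ch:
                assert s >= MARKS.stabilization_end

    def test_nonpositive_k_rejected(self):
        rec = bandpass(_baseline_recording())
        with pytest.raises(InvalidArgumentError):
            detect_discharges(
                rec, compute_baseline_stats(rec), DetectorParams(k=0.0)
            )


class TestSegmentEvents:
    def test_merge_arithmetic(self):
        # two 4-s candidates 1 s apart merge into one 9-s event
        cands = [[(100.0, 104.0), (105.0, 109.0)], [], [], []]
        events = segment_events(cands, merge_gap=2.0)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(9.0)

    def test_short_candidate_discarded(self):
        events = segment_events([[(100.0, 104.0)], [], [], []], merge_gap=2.0)
        assert events == []

    def test_multichannel_unification(self):
        cands = [
            [(100.0, 130.0)],
            [(99.0, 128.0)],
            [(100.5, 131.0)],
            [(101.0, 130.0)],
        ]
        events = segment_events(cands, merge_gap=2.0)
        assert len(events) == 1
        assert set(events[0].per_channel_onset) == {1, 2, 3, 4}
        assert events[0].per_channel_onset[2] == pytest.approx(99.0)

    def test_negative_merge_gap_rejected(self):
        with pytest.raises(InvalidArgumentError):
            segment_events([[]], merge_gap=-1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "cls,freq,expected",
        [("theta", 6.0, "theta"), ("spike_wave", 2.5, "spike_wave")],
    )
    def test_planted_class_recovered(self, cls, freq, expected):
        rec = _baseline_recording(seed=8)
        seg = generate_ictal_segment(cls, 30, FS, freq, 100.0, seed=9)
        _plant(rec, 2, 300.0, seg)
        rec = bandpass(rec)
        ev = SeizureEvent(onset=300.0, offset=330.0, per_channel_onset={2: 300.0})
        classify_event(ev, rec)
        assert ev.event_class == expected
        assert ev.dominant_freq == pytest.approx(freq, abs=0.5)

    def test_out_of_band_oscillation_is_other(self):
        rec = _baseline_recording(seed=10)
        t = np.arange(int(30 * FS)) / FS
        _plant(rec, 1, 300.0, 50.0 * np.sin(2 * np.pi * 10.0 * t))
        rec = bandpass(rec)
        ev = SeizureEvent(onset=300.0, offset=330.0, per_channel_onset={1: 300.0})
        classify_event(ev, rec)
        assert ev.event_class == "other"
        assert ev.dominant_freq == pytest.approx(10.0, abs=0.5)


class TestSEFlag:
    @pytest.mark.parametrize(
        "duration,expected", [(301.0, True), (300.0, False), (299.0, False)]
    )
    def test_strict_five_minute_rule(self, duration, expected):
        ev = SeizureEvent(onset=700.0, offset=700.0 + duration)
        flag_se([ev])
        assert ev.is_SE is expected


class TestEndToEnd:
    def test_planted_events_recovered(self, detected):
        from zfeeg.experiments import match_events

        _, truth, events = detected
        matches = match_events(events, truth)
        assert len(matches) == len(truth) == len(events)

    def test_baseline_only_recording_yields_no_events(self, baseline_recording):
        events = detect_events(bandpass(baseline_recording))
        assert events == []
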