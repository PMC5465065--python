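"""Generator contracts: amplitudes, spectral content, placement, determinism."""

import numpy as np
import pytest
from scipy.signal import periodogram

from zfeeg import AnimalProfile, TimelineMarks
from zfeeg.synthetic import (
    generate_baseline,
    generate_cohort,
    generate_ictal_segment,
    generate_recording,
    paper_cohort,
    truncated_poisson_lambda,
)
from zfeeg.types import InvalidArgumentError

FS = 250.0
MARKS = TimelineMarks(injection_time=120.0, session_end=900.0)


def _median_p2p(x, fs, win_s=2.0, step_s=1.0):
    win, step = int(win_s * fs), int(step_s * fs)
    return np.median(
        [
            np.ptp(x[c, i : i + win])
            for c in range(x.shape[0])
            for i in range(0, x.shape[1] - win + 1, step)
        ]
    )


class TestBaseline:
    def test_quiet_amplitude(self):
        x = generate_baseline(60, 500.0, 4, seed=1)
        assert _median_p2p(x, 500.0) <= 20.0

    @pytest.mark.parametrize("bad", [{"duration": 0}, {"duration": -5}, {"fs": 0}])
    def test_rejects_empty_input(self, bad):
        kw = dict(duration=60, fs=500.0)
        kw.update(bad)
        with pytest.raises(InvalidArgumentError):
            generate_baseline(kw["duration"], kw["fs"], 4, seed=0)

    def test_band_limited_below_40hz(self):
        # periodogram oracle: essentially no power above 45 Hz
        x = generate_baseline(120, 500.0, 1, seed=3)[0]
        f, p = periodogram(x, fs=500.0)
        assert p[f > 45.0].sum() / p.sum() < 0.01

    def test_reproducible(self):
        a = generate_baseline(10, 250.0, 2, seed=5)
        b = generate_baseline(10, 250.0, 2, seed=5)
        np.testing.assert_array_equal(a, b)


class TestIctalSegments:
    @pytest.mark.parametrize(
        "cls,freq",
        [("spike_wave", 2.5), ("spike_wave", 2.0), ("spike_wave", 3.0),
         ("theta", 6.0), ("theta", 5.0), ("theta", 7.0)],
    )
    def test_spectral_peak_at_dominant_freq(self, cls, freq):
        seg = generate_ictal_segment(cls, 30, 500.0, freq, 80.0, seed=3)
        f, p = periodogram(seg, fs=500.0)
        sel = (f >= 1.0) & (f <= 40.0)
        assert abs(f[sel][np.argmax(p[sel])] - freq) <= 0.5

    def test_peak_to_peak_amplitude(self):
        seg = generate_ictal_segment("theta", 10, 500.0, 6.0, 100.0, seed=0)
        assert np.ptp(seg) == pytest.approx(100.0, rel=1e-6)

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_ictal_segment("theta", 10, 500.0, 2.0, 100.0)
        with pytest.raises(InvalidArgumentError):
            generate_ictal_segment("spike_wave", 10, 500.0, 6.0, 100.0)

    def test_subthreshold_amplitude_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_ictal_segment("theta", 10, 500.0, 6.0, 15.0)


class TestRecordingGeneration:
    def test_nonresponder_is_baseline_only(self):
        profile = AnimalProfile(sex="male", responder=False)
        rec, truth = generate_recording(profile, MARKS, FS, seed=1)
        assert truth == []
        assert _median_p2p(rec.samples, FS) <= 20.0

    def test_fixed_count(self):
        profile = AnimalProfile(
            sex="female", count_fixed=3, duration_mean_s=20.0,
            latency_mean_s=100.0,
        )
        _, truth = generate_recording(profile, MARKS, FS, seed=2)
        assert len(truth) == 3

    def test_events_respect_stabilization_and_duration_floor(self):
        # exhaustive check over many generated sessions (truth-only mode)
        profile = AnimalProfile(
            sex="male", count_mean=3.0, duration_mean_s=25.0,
            latency_mean_s=100.0,
        )
        for seed in range(100):
            _, truth = generate_recording(
                profile, MARKS, FS, seed=seed, render=False
            )
            for gt in truth:
                assert gt.onset >= MARKS.stabilization_end
                assert gt.duration >= 5.0
                assert gt.offset <= MARKS.session_end

    def test_events_never_overlap(self):
        profile = AnimalProfile(
            sex="male", count_mean=6.0, duration_mean_s=40.0,
            latency_mean_s=100.0,
        )
        for seed in range(30):
            _, truth = generate_recording(
                profile, MARKS, FS, seed=seed, render=False
            )
            ivals = sorted((gt.onset, gt.offset) for gt in truth)
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                assert s1 >= e0

    def test_planted_count_converges_to_profile_mean(self):
        # >= 50 independent sessions per sex; sample mean within 2 SE
        cfg = paper_cohort(fs=FS, seizing_only=True)
        for profile in (cfg.male_profile, cfg.female_profile):
            counts = [
                len(
                    generate_recording(profile, seed=seed, fs=FS, render=False)[1]
                )
                for seed in range(60)
            ]
            se = np.std(counts, ddof=1) / np.sqrt(len(counts))
            assert abs(np.mean(counts) - profile.count_mean) <= 2 * se + 1e-9


class TestCohort:
    def test_truncated_poisson_calibration(self):
        # analytic identity: lambda / (1 - e^-lambda) equals the target
        for m in (3.38, 6.50, 2.0):
            lam = truncated_poisson_lambda(m)
            assert lam / -np.expm1(-lam) == pytest.approx(m, abs=1e-9)

    def test_paper_preset_composition(self):
        cohort = generate_cohort(paper_cohort(fs=FS), seed=3)
        assert len(cohort) == 17
        zero = sum(1 for _, truth in cohort if not truth)
        assert zero == 3
        sexes = [rec.sex for rec, _ in cohort]
        assert sexes.count("male") == 8 and sexes.count("female") == 9

    def test_cohort_deterministic(self):
        cfg = paper_cohort(fs=FS, seizing_only=True)
        a = generate_cohort(cfg, seed=11)
        b = generate_cohort(cfg, seed=11)
        for (ra, ta), (rb, tb) in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)
            assert ta == tb

    def test_empty_cohort(self):
        cfg = paper_cohort(fs=FS)
        from dataclasses import replace

        empty = replace(
            cfg, n_male=0, n_female=0,
            n_nonresponder_male=0, n_nonresponder_female=0,
        )
        assert generate_cohort(empty, seed=0) == []

    def test_negative_counts_rejected(self):
        from dataclasses import replace

        with pytest.raises(InvalidArgumentError):
            replace(paper_cohort(), n_male=-1)
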