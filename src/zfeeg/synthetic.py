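"""Synthetic adult-zebrafish EEG with planted, fully labelled seizures.

The generator emulates the statistical structure of skin-surface recordings
from a PTZ (pentylenetetrazole) seizure model in adult zebrafish:

* baseline activity: band-limited (< 40 Hz) pink noise kept under 20 μV
  peak-to-peak in 2-s windows;
* two ictal signal classes: high-amplitude 5–7 Hz theta runs and 2–3 Hz
  spike-and-slow-wave ("absence-like") complexes;
* a session timeline of 10 min control recording, convulsant injection,
  90 s stabilization (excluded from analysis) and a 60-min total session;
* per-animal event counts, durations and first-event latencies with
  sex-specific means, onset-channel probabilities over the 4-channel
  montage, and occasional status-epilepticus-like events (> 300 s).

Every planted event is returned as a :class:`GroundTruthEvent`, so the
detection, localization and statistics stages can be scored against exact
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .types import (
    AnimalProfile,
    GenerationError,
    GroundTruthEvent,
    InvalidArgumentError,
    Recording,
    TimelineMarks,
)

#: Default montage: channels 1/2 over the right/left telencephalon,
#: channels 3/4 over the posterior (midbrain) regions.
DEFAULT_MONTAGE = {
    1: "right telencephalon",
    2: "left telencephalon",
    3: "posterior-left",
    4: "posterior-right",
}

#: EDF-style channel labels matching DEFAULT_MONTAGE.
CHANNEL_LABELS = ("RT_TEL", "LT_TEL", "L_MID", "R_MID")

# Median 2-s-window peak-to-peak amplitude of unit-variance pink noise
# low-passed at 40 Hz (measured over long realizations; stable to ~1%
# for fs in [200, 1000]).  Baseline is scaled so its median 2-s p-p sits
# at BASELINE_P2P_UV, safely below the 20 μV ceiling of quiet skin EEG.
_UNIT_P2P_FACTOR = 5.04
BASELINE_P2P_UV = 15.0

_NOISE_LOWPASS_HZ = 40.0
_MIN_EVENT_DURATION_S = 5.0
_EVENT_GAP_S = 5.0
_EDGE_TAPER_S = 0.5

THETA_BAND = (5.0, 7.0)
SPIKE_WAVE_BAND = (2.0, 3.0)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def truncated_poisson_lambda(target_mean: float) -> float:
    """Rate λ such that a zero-truncated Poisson has the target mean.

    The zero-truncated mean is λ / (1 - e^{-λ}); solving for λ removes the
    upward bias that plain Poisson truncation would introduce (noticeable
    for small means, e.g. a target of 3.38 would drift to 3.50).
    """
    if target_mean <= 1.0:
        raise InvalidArgumentError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / -np.expm1(-lam) - target_mean
    return brentq(f, 1e-9, target_mean + 1.0)


def _sample_truncated_poisson(rng: np.random.Generator, target_mean: float) -> int:
    lam = truncated_poisson_lambda(target_mean)
    for _ in range(10_000):
        k = rng.poisson(lam)
        if k >= 1:
            return int(k)
    raise GenerationError("zero-truncated Poisson rejection failed")


def generate_baseline(
    duration: float,
    fs: float = 500.0,
    n_channels: int = 4,
    seed: int | np.random.Generator = 0,
    p2p_uv: float = BASELINE_P2P_UV,
) -> np.ndarray:
    """Generate baseline (non-ictal) activity, shape (n_channels, n).

    Pink (1/f) noise, low-passed at 40 Hz and scaled so the median 2-s
    sliding-window peak-to-peak amplitude is ``p2p_uv`` (default 15 μV,
    matching quiet skin-surface EEG which stays under 20 μV).
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    if fs < 200:
        raise InvalidArgumentError("fs must be at least 200 Hz")
    rng = _rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.ones_like(f)
    # 1/sqrt(f) amplitude weighting -> 1/f power; flat below 0.5 Hz to
    # avoid a divergent DC component.
    nz = f >= 0.5
    weight[nz] = np.sqrt(0.5 / f[nz])
    pink = np.fft.irfft(spec * weight, n=n, axis=1)
    sos = signal.butter(4, _NOISE_LOWPASS_HZ, btype="low", fs=fs, output="sos")
    pink = signal.sosfiltfilt(sos, pink, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return pink * (p2p_uv / _UNIT_P2P_FACTOR)


def _taper(n: int, fs: float, edge_s: float = _EDGE_TAPER_S) -> np.ndarray:
    """Raised-cosine on/off ramps so planted events have clean edges."""
    ramp = min(int(edge_s * fs), n // 2)
    w = np.ones(n)
    if ramp > 0:
        h = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = h
        w[-ramp:] = h[::-1]
    return w


def generate_ictal_segment(
    event_class: str,
    duration: float,
    fs: float,
    dominant_freq: float,
    amplitude_pp: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate one single-channel ictal segment.

    ``theta``: an amplitude-modulated sinusoid at ``dominant_freq``
    (5–7 Hz), envelope wandering between 60% and 100% of the peak.
    ``spike_wave``: a repeating complex of a 40-ms biphasic spike followed
    by a slow half-sine wave filling the rest of the cycle (2–3 Hz).

    The output peak-to-peak amplitude is ``amplitude_pp`` μV and the
    largest spectral peak lies within ±0.5 Hz of ``dominant_freq``.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    if amplitude_pp <= 20.0:
        raise InvalidArgumentError("ictal amplitude_pp must exceed 20 μV")
    band = {"theta": THETA_BAND, "spike_wave": SPIKE_WAVE_BAND}.get(event_class)
    if band is None:
        raise InvalidArgumentError(f"unknown event class {event_class!r}")
    if not band[0] <= dominant_freq <= band[1]:
        raise InvalidArgumentError(
            f"dominant_freq {dominant_freq} Hz outside the {event_class} "
            f"band {band}"
        )
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if event_class == "theta":
        phase = rng.uniform(0, 2 * np.pi)
        mod_phase = rng.uniform(0, 2 * np.pi)
        mod_freq = rng.uniform(0.1, 0.3)
        envelope = 0.8 + 0.2 * np.sin(2 * np.pi * mod_freq * t + mod_phase)
        x = envelope * np.sin(2 * np.pi * dominant_freq * t + phase)
    else:
        cycle_n = max(int(round(fs / dominant_freq)), 8)
        spike_n = max(int(round(0.040 * fs)), 4)
        spike_n = min(spike_n, cycle_n // 2)
        kernel = np.zeros(cycle_n)
        half = spike_n // 2
        # biphasic spike: sharp positive lobe then a negative lobe
        kernel[:half] = np.sin(np.pi * np.arange(half) / half)
        kernel[half:spike_n] = -0.8 * np.sin(
            np.pi * np.arange(spike_n - half) / (spike_n - half)
        )
        # slow wave: positive half-sine filling the remainder of the cycle
        wave_n = cycle_n - spike_n
        kernel[spike_n:] = 0.85 * np.sin(np.pi * np.arange(wave_n) / wave_n)
        n_cycles = int(np.ceil(n / cycle_n))
        gains = rng.uniform(0.9, 1.1, size=n_cycles)
        x = (kernel[None, :] * gains[:, None]).ravel()[:n]
        x = x - x.mean()
    x *= _taper(n, fs)
    span = x.max() - x.min()
    if span > 0:
        x *= amplitude_pp / span
    return x


def _draw_durations(
    rng: np.random.Generator,
    profile: AnimalProfile,
    n_events: int,
    se_event: bool,
) -> tuple[np.ndarray, int | None]:
    """Per-event durations; at most one SE event (> 300 s) per animal.

    The profile's ``duration_mean_s`` is the overall per-event mean
    *including* SE events, so the non-SE log-normal component is
    re-centred: m_non_se = (c·m − p_SE·m_SE) / (c − p_SE), with c the mean
    event count. This keeps the cohort-level mean duration at the stated
    value while still producing SE-like events at the stated per-animal
    probability.
    """
    mean_se = float(np.mean(profile.se_duration_range_s))
    m = profile.duration_mean_s
    if profile.se_prob > 0:
        c = profile.count_mean
        m = (c * m - profile.se_prob * mean_se) / (c - profile.se_prob)
        if m < _MIN_EVENT_DURATION_S:
            raise InvalidArgumentError(
                "SE mixture leaves non-SE mean duration below the 5-s floor"
            )
    mu, sigma = _lognormal_params(m, profile.duration_cv)
    durations = np.empty(n_events)
    for i in range(n_events):
        for _ in range(1000):
            d = rng.lognormal(mu, sigma)
            if d >= _MIN_EVENT_DURATION_S + 0.5:
                break
        durations[i] = d
    se_index = None
    if se_event and n_events > 0:
        se_index = int(rng.integers(n_events))
        durations[se_index] = rng.uniform(*profile.se_duration_range_s)
    return durations, se_index


def _place_events(
    rng: np.random.Generator,
    durations: np.ndarray,
    first_onset: float,
    window_end: float,
) -> np.ndarray:
    """Onsets for events after the first, uniformly spread with ≥5-s gaps."""
    n = len(durations)
    onsets = np.empty(n)
    onsets[0] = first_onset
    if n == 1:
        return onsets
    rest = durations[1:]
    start = first_onset + durations[0] + _EVENT_GAP_S
    free = (window_end - start) - rest.sum() - _EVENT_GAP_S * (n - 2)
    if free < 0:
        raise GenerationError("events do not fit in the post-injection window")
    slack = np.sort(rng.uniform(0, free, size=n - 1))
    slack = np.diff(np.concatenate([[0.0], slack]))
    cursor = start
    for i in range(n - 1):
        cursor += slack[i]
        onsets[i + 1] = cursor
        cursor += rest[i] + _EVENT_GAP_S
    return onsets


def generate_recording(
    profile: AnimalProfile,
    marks: TimelineMarks | None = None,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
    delay_range: tuple[float, float] = (0.1, 2.0),
    amplitude_pp_range: tuple[float, float] = (60.0, 200.0),
    max_retries: int = 100,
    render: bool = True,
) -> tuple[Recording, list[GroundTruthEvent]]:
    """Generate one full-session recording with planted ground truth.

    Events are drawn from the profile's distributions, start at or after
    the end of the stabilization window, never overlap (a ≥5-s gap is kept
    between consecutive events on every channel) and each is superimposed
    on the running baseline on its involved channels. Focal events live on
    the onset channel only; generalized events spread to all four channels
    with per-channel onset delays drawn from ``delay_range``.

    ``render=False`` skips signal synthesis (the samples come back as
    zeros) and returns only the ground truth — useful for statistical
    checks of the planted distributions at scale.
    """
    marks = marks or TimelineMarks()
    rng = _rng(seed)
    n_total = int(round(marks.session_end * fs))
    if render:
        samples = generate_baseline(marks.session_end, fs, 4, rng)
    else:
        samples = np.zeros((4, n_total))
    truth: list[GroundTruthEvent] = []

    if profile.responder:
        mu_l, sig_l = _lognormal_params(profile.latency_mean_s, profile.latency_cv)
        min_latency = marks.stabilization_end - marks.injection_time
        avail_end = marks.session_end - 1.0
        placed = False
        for _ in range(max_retries):
            if profile.count_fixed is not None:
                n_events = int(profile.count_fixed)
                if n_events == 0:
                    onsets = np.empty(0)
                    durations = np.empty(0)
                    se_index = None
                    placed = True
                    break
            else:
                n_events = _sample_truncated_poisson(rng, profile.count_mean)
            se_event = rng.uniform() < profile.se_prob
            try:
                durations, se_index = _draw_durations(rng, profile, n_events, se_event)
            except InvalidArgumentError:
                raise
            for _ in range(1000):
                latency = rng.lognormal(mu_l, sig_l)
                if (
                    latency >= min_latency
                    and marks.injection_time + latency + durations[0] < avail_end
                ):
                    break
            else:
                continue
            first_onset = marks.injection_time + latency
            try:
                onsets = _place_events(rng, durations, first_onset, avail_end)
            except GenerationError:
                continue
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place {profile.count_mean:.1f}-mean event load in "
                "the post-injection window"
            )

        for i, (onset, dur) in enumerate(zip(onsets, durations)):
            if se_index is not None and i == se_index:
                event_class = "spike_wave"
            elif rng.uniform() < profile.theta_prob:
                event_class = "theta"
            else:
                event_class = "spike_wave"
            band = THETA_BAND if event_class == "theta" else SPIKE_WAVE_BAND
            freq = rng.uniform(*band)
            amp = rng.uniform(*amplitude_pp_range)
            onset_channel = int(rng.choice([1, 2, 3, 4], p=profile.onset_probs))
            if rng.uniform() < profile.focal_prob:
                delays = {onset_channel: 0.0}
            else:
                delays = {onset_channel: 0.0}
                for ch in (1, 2, 3, 4):
                    if ch != onset_channel:
                        delays[ch] = float(rng.uniform(*delay_range))
            if render:
                for ch, delay in delays.items():
                    seg_dur = max(dur - delay, 1.0)
                    seg = generate_ictal_segment(
                        event_class, seg_dur, fs, freq, amp, rng
                    )
                    i0 = int(round((onset + delay) * fs))
                    samples[ch - 1, i0 : i0 + len(seg)] += seg[
                        : samples.shape[1] - i0
                    ]
            truth.append(
                GroundTruthEvent(
                    onset=float(onset),
                    duration=float(dur),
                    event_class=event_class,
                    dominant_freq=float(freq),
                    amplitude_pp=float(amp),
                    onset_channel=onset_channel,
                    channel_delays=delays,
                )
            )

    truth.sort(key=lambda e: e.onset)
    rec = Recording(
        samples=samples,
        fs=fs,
        montage=dict(DEFAULT_MONTAGE),
        marks=marks,
        animal_id=profile.animal_id,
        sex=profile.sex,
    )
    return rec, truth


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition plus the per-sex generative profiles."""

    male_profile: AnimalProfile
    female_profile: AnimalProfile
    n_male: int = 8
    n_female: int = 9
    n_nonresponder_male: int = 1
    n_nonresponder_female: int = 2
    fs: float = 500.0
    marks: TimelineMarks = TimelineMarks()
    delay_range: tuple[float, float] = (0.1, 2.0)

    def __post_init__(self) -> None:
        if min(self.n_male, self.n_female) < 0 or min(
            self.n_nonresponder_male, self.n_nonresponder_female
        ) < 0:
            raise InvalidArgumentError("cohort counts must be non-negative")
        if (
            self.n_nonresponder_male > self.n_male
            or self.n_nonresponder_female > self.n_female
        ):
            raise InvalidArgumentError("non-responders cannot exceed group size")


#: Onset-channel probabilities (ch1..ch4). Telencephalic mass is 32% right
#: (ch1) and 39% left (ch2) in both sexes; the posterior remainder is 19%
#: right-posterior in males and 24% left-posterior in females, the residual
#: going to the opposite posterior channel.
MALE_ONSET_PROBS = (0.32, 0.39, 0.10, 0.19)
FEMALE_ONSET_PROBS = (0.32, 0.39, 0.24, 0.05)


def paper_cohort(
    fs: float = 500.0,
    seizing_only: bool = False,
    marks: TimelineMarks | None = None,
    delay_range: tuple[float, float] = (0.1, 2.0),
) -> CohortConfig:
    """The study-cohort preset: 8 males + 9 females, 3 non-responders.

    Responder profiles use the sex-specific summary statistics of the
    PTZ cohort: mean event counts 6.50 (male) / 3.38 (female), mean event
    durations 79 s / 88 s, mean first-event latencies 269 s / 462 s from
    injection, SE probabilities 0.50 / 0.25, and the onset-channel split
    above. ``seizing_only=True`` drops the three non-responders, leaving
    the 14 seizing animals (7 + 7).
    """
    male = AnimalProfile(
        sex="male",
        count_mean=6.50,
        duration_mean_s=79.0,
        latency_mean_s=269.0,
        onset_probs=MALE_ONSET_PROBS,
        se_prob=0.50,
    )
    female = AnimalProfile(
        sex="female",
        count_mean=3.38,
        duration_mean_s=88.0,
        latency_mean_s=462.0,
        onset_probs=FEMALE_ONSET_PROBS,
        se_prob=0.25,
    )
    kw = dict(
        male_profile=male,
        female_profile=female,
        fs=fs,
        marks=marks or TimelineMarks(),
        delay_range=delay_range,
    )
    if seizing_only:
        return CohortConfig(
            n_male=7, n_female=7, n_nonresponder_male=0, n_nonresponder_female=0, **kw
        )
    return CohortConfig(
        n_male=8, n_female=9, n_nonresponder_male=1, n_nonresponder_female=2, **kw
    )


def demo_small(fs: float = 250.0, **kw) -> CohortConfig:
    """A tiny, fast cohort (2 + 2 animals, 15-min sessions) for demos and
    smoke tests; not calibrated to the study statistics."""
    marks = kw.pop("marks", None) or TimelineMarks(
        injection_time=120.0, session_end=900.0
    )
    male = AnimalProfile(
        sex="male", count_mean=3.0, duration_mean_s=30.0, duration_cv=0.3,
        latency_mean_s=90.0, onset_probs=MALE_ONSET_PROBS,
    )
    female = AnimalProfile(
        sex="female", count_mean=2.0, duration_mean_s=30.0, duration_cv=0.3,
        latency_mean_s=120.0, onset_probs=FEMALE_ONSET_PROBS,
    )
    return CohortConfig(
        male_profile=male, female_profile=female,
        n_male=2, n_female=2,
        n_nonresponder_male=0, n_nonresponder_female=1,
        fs=fs, marks=marks, **kw,
    )


PRESETS = {
    "paper_cohort": paper_cohort,
    "paper_cohort_seizing": lambda **kw: paper_cohort(seizing_only=True, **kw),
    "demo_small": demo_small,
}


def generate_cohort(
    config: CohortConfig, seed: int = 0, render: bool = True
) -> list[tuple[Recording, list[GroundTruthEvent]]]:
    """Generate all recordings of a cohort, deterministic per (config, seed).

    Each animal gets an independent child seed from a SeedSequence, so the
    cohort is reproducible and individual animals are decoupled.
    """
    roster: list[AnimalProfile] = []
    for i in range(config.n_male):
        responder = i >= config.n_nonresponder_male
        roster.append(
            replace(
                config.male_profile,
                responder=responder,
                animal_id=f"m{i + 1:02d}",
            )
        )
    for i in range(config.n_female):
        responder = i >= config.n_nonresponder_female
        roster.append(
            replace(
                config.female_profile,
                responder=responder,
                animal_id=f"f{i + 1:02d}",
            )
        )
    out = []
    children = np.random.SeedSequence(seed).spawn(len(roster))
    for profile, child in zip(roster, children):
        rng = np.random.default_rng(child)
        out.append(
            generate_recording(
                profile,
                config.marks,
                config.fs,
                rng,
                delay_range=config.delay_range,
                render=render,
            )
        )
    return out
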