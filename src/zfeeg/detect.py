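"""Automated epileptiform-discharge detection and classification.

The screening rule: an epileptiform discharge is a high-voltage repetitive
discharge faster than 2.5 Hz with polyphasic spike/wave complexes. It is
realized as the conjunction of

1. an amplitude rule — the rectified, 0.5-s-smoothed envelope exceeds
   ``k`` times the per-channel MAD of the pre-injection control window
   (k = 4 by default; the smoothing window covers at least one full cycle
   of the slowest 2 Hz spike-wave class, keeping the envelope steady
   within an event); and
2. a repetition-rate rule — suprathreshold peaks of the rectified signal
   arrive at more than 2.5 per second in a sliding 2-s window. Polyphasic
   complexes contribute several peaks per cycle, which is what lets 2–3 Hz
   spike-wave runs satisfy a ">2.5 Hz" rule.

Candidates are restricted to t ≥ stabilization_end (the 90 s after
injection are excluded), merged within a per-channel gap, unified across
channels when they overlap in time, and discarded when shorter than 5 s.
Events are classified by the dominant spectral peak of the onset channel:
theta (5–7 Hz band, accepted in [4.5, 7.5]) vs absence-like spike-wave
(2–3 Hz band, accepted in [1.5, 3.5]); anything longer than 5 min is
flagged as a status-epilepticus-like event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .types import (
    BaselineStats,
    ConfigurationError,
    InvalidArgumentError,
    Recording,
    SeizureEvent,
)

SE_THRESHOLD_S = 300.0  # "longer than 5 min" (strict)
MIN_EVENT_DURATION_S = 5.0
THETA_CLASS_BAND = (4.5, 7.5)
SPIKE_WAVE_CLASS_BAND = (1.5, 3.5)


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the screening rule."""

    k: float = 4.0  # envelope threshold in baseline-MAD units
    min_rate_hz: float = 2.5  # peaks/s, strict ">"
    rate_window_s: float = 2.0
    envelope_window_s: float = 0.5
    merge_gap_s: float = 2.0
    min_duration_s: float = MIN_EVENT_DURATION_S

    def validate(self) -> None:
        if self.k <= 0:
            raise InvalidArgumentError("threshold multiplier k must be positive")
        if self.merge_gap_s < 0:
            raise InvalidArgumentError("merge_gap must be non-negative")


def compute_baseline_stats(recording: Recording) -> BaselineStats:
    """Robust per-channel amplitude statistics from the control window.

    Uses strictly [control_start, injection_time); a window shorter than
    60 s is refused, and an all-constant channel (zero scale) is treated
    as degenerate.
    """
    marks = recording.marks
    if marks.injection_time - marks.control_start < 60.0:
        raise ConfigurationError("control window must be at least 60 s")
    i0 = int(round(marks.control_start * recording.fs))
    i1 = int(round(marks.injection_time * recording.fs))
    ctrl = recording.samples[:, i0:i1]
    med = np.median(ctrl, axis=1, keepdims=True)
    mad = np.median(np.abs(ctrl - med), axis=1)
    win = int(round(2.0 * recording.fs))
    step = int(round(recording.fs))
    pp = []
    for c in range(ctrl.shape[0]):
        w = [
            np.ptp(ctrl[c, j : j + win])
            for j in range(0, ctrl.shape[1] - win + 1, step)
        ]
        pp.append(np.median(w))
    return BaselineStats(mad=mad, p2p_reference=np.asarray(pp))


def _candidate_mask(
    x: np.ndarray,
    fs: float,
    threshold: float,
    params: DetectorParams,
) -> np.ndarray:
    """Boolean mask where both the amplitude and the rate rule hold."""
    rect = np.abs(x)
    env = uniform_filter1d(rect, max(int(params.envelope_window_s * fs), 1))
    # one count per discharge complex: a 0.1-s refractory spacing ignores
    # the extra phases/ringing of a single spike while a 2 Hz spike-wave
    # run still counts its spike and wave peaks separately (4/s > 2.5)
    peaks, _ = signal.find_peaks(
        rect, height=threshold, distance=max(int(0.1 * fs), 1)
    )
    impulses = np.zeros(len(x))
    impulses[peaks] = 1.0
    win = max(int(params.rate_window_s * fs), 1)
    rate = uniform_filter1d(impulses, win) * fs  # peaks per second, centered
    return (env > threshold) & (rate > params.min_rate_hz)


def detect_discharges(
    recording: Recording,
    baseline: BaselineStats,
    params: DetectorParams | None = None,
) -> list[list[tuple[float, float]]]:
    """Per-channel candidate intervals (seconds), onset-sorted.

    Candidates never start before ``stabilization_end``.
    """
    params = params or DetectorParams()
    params.validate()
    fs = recording.fs
    start = int(round(recording.marks.stabilization_end * fs))
    out: list[list[tuple[float, float]]] = []
    for c in range(recording.n_channels):
        mask = _candidate_mask(
            recording.samples[c], fs, params.k * baseline.mad[c], params
        )
        mask[:start] = False
        out.append(_runs_to_intervals(mask, fs))
    return out


def _runs_to_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return [(s / fs, e / fs) for s, e in zip(starts, stops)]


def _merge_intervals(
    intervals: list[tuple[float, float]], gap: float
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def segment_events(
    candidates: list[list[tuple[float, float]]],
    merge_gap: float = 2.0,
    min_duration: float = MIN_EVENT_DURATION_S,
) -> list[SeizureEvent]:
    """Merge per-channel candidates and unify them into multichannel events.

    Per-channel candidates closer than ``merge_gap`` are merged; candidates
    from different channels that overlap by at least one sample become one
    event whose per-channel onsets are each channel's earliest candidate
    start. Events shorter than ``min_duration`` are discarded (the 5-s
    exclusion rule).
    """
    if merge_gap < 0:
        raise InvalidArgumentError("merge_gap must be non-negative")
    per_channel = [
        _merge_intervals(sorted(ch), merge_gap) for ch in candidates
    ]
    tagged = sorted(
        (s, e, ch + 1)
        for ch, ivs in enumerate(per_channel)
        for (s, e) in ivs
    )
    events: list[SeizureEvent] = []
    cluster: list[tuple[float, float, int]] = []

    def _flush() -> None:
        if not cluster:
            return
        onset = min(s for s, _, _ in cluster)
        offset = max(e for _, e, _ in cluster)
        if offset - onset < min_duration:
            return
        pco: dict[int, float] = {}
        for s, _, ch in cluster:
            pco[ch] = min(pco.get(ch, np.inf), s)
        events.append(
            SeizureEvent(onset=onset, offset=offset, per_channel_onset=pco)
        )

    cur_end = -np.inf
    for s, e, ch in tagged:
        if s < cur_end:  # overlaps the running cluster
            cluster.append((s, e, ch))
            cur_end = max(cur_end, e)
        else:
            _flush()
            cluster = [(s, e, ch)]
            cur_end = e
    _flush()
    return sorted(events, key=lambda ev: ev.onset)


def classify_event(
    event: SeizureEvent, recording: Recording
) -> SeizureEvent:
    """Assign dominant frequency and class from the onset channel's
    spectrum over [1, 40] Hz."""
    fs = recording.fs
    channels = sorted(event.per_channel_onset) or list(
        range(1, recording.n_channels + 1)
    )
    ch = min(
        event.per_channel_onset, key=lambda c: (event.per_channel_onset[c], c)
    ) if event.per_channel_onset else channels[0]
    i0 = int(round(event.onset * fs))
    i1 = int(round(event.offset * fs))
    seg = recording.samples[ch - 1, i0:i1]
    nperseg = min(len(seg), int(8 * fs))
    freqs, pxx = signal.welch(seg, fs=fs, nperseg=nperseg)
    band = (freqs >= 1.0) & (freqs <= 40.0)
    dominant = float(freqs[band][np.argmax(pxx[band])])
    if THETA_CLASS_BAND[0] <= dominant <= THETA_CLASS_BAND[1]:
        cls = "theta"
    elif SPIKE_WAVE_CLASS_BAND[0] <= dominant <= SPIKE_WAVE_CLASS_BAND[1]:
        cls = "spike_wave"
    else:
        cls = "other"
    event.dominant_freq = dominant
    event.event_class = cls
    return event


def flag_se(events: list[SeizureEvent]) -> list[SeizureEvent]:
    """Mark status-epilepticus-like events: duration strictly > 5 min."""
    for ev in events:
        ev.is_SE = ev.duration > SE_THRESHOLD_S
    return events


def detect_events(
    recording: Recording,
    params: DetectorParams | None = None,
    baseline: BaselineStats | None = None,
) -> list[SeizureEvent]:
    """Full per-recording detection: baseline stats → candidates →
    segmentation → classification → SE flag → spread/onset channel.

    The recording is expected to be band-passed already.
    """
    from .localize import annotate_events  # local import avoids a cycle

    params = params or DetectorParams()
    baseline = baseline or compute_baseline_stats(recording)
    candidates = detect_discharges(recording, baseline, params)
    events = segment_events(
        candidates, merge_gap=params.merge_gap_s, min_duration=params.min_duration_s
    )
    for ev in events:
        classify_event(ev, recording)
    flag_se(events)
    annotate_events(events, n_channels=recording.n_channels)
    return events
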