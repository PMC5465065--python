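"""Shared domain types for the zebrafish EEG pipeline.

All signal amplitudes are in microvolts (μV), times in seconds from the
start of the recording session, frequencies in hertz, and impedances in
ohms unless a field says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

Sex = Literal["male", "female"]
EventClass = Literal["theta", "spike_wave", "other"]
Spread = Literal["focal", "generalized"]


class ZfeegError(Exception):
    """Base class for pipeline errors."""


class InvalidArgumentError(ZfeegError, ValueError):
    """An argument violates a documented precondition."""


class GenerationError(ZfeegError, RuntimeError):
    """Synthetic-event placement could not be satisfied."""


class ParseError(ZfeegError, ValueError):
    """A file did not conform to the expected schema."""


class ConfigurationError(ZfeegError, ValueError):
    """A run configuration references something that does not exist."""


class FittingError(ZfeegError, RuntimeError):
    """A model fit failed to converge."""


class InsufficientDataError(ZfeegError, ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True)
class TimelineMarks:
    """Session timeline: control window, convulsant injection, stabilization.

    The default timeline is a 10-min control recording, injection at 600 s,
    a 90-s stabilization window that is excluded from analysis, and a 60-min
    total session.
    """

    control_start: float = 0.0
    injection_time: float = 600.0
    stabilization_end: float | None = None
    session_end: float = 3600.0

    def __post_init__(self) -> None:
        if self.stabilization_end is None:
            object.__setattr__(self, "stabilization_end", self.injection_time + 90.0)
        if not (
            self.control_start < self.injection_time
            and self.injection_time < self.stabilization_end <= self.session_end
        ):
            raise InvalidArgumentError(
                "timeline must satisfy control_start < injection_time < "
                f"stabilization_end <= session_end, got {self}"
            )


@dataclass(frozen=True)
class AnimalProfile:
    """Generative profile of one animal.

    ``count_mean`` is the mean number of events per session for a responder
    (realized as a zero-truncated Poisson); ``duration_mean_s`` /
    ``duration_cv`` parameterize the log-normal per-event duration;
    ``latency_mean_s`` / ``latency_cv`` the log-normal latency of the first
    event measured from ``injection_time``. ``onset_probs`` is the
    probability of each of the 4 channels being the seizure-onset channel.
    ``se_prob`` is the probability that the animal develops one
    status-epilepticus-like event (> 300 s). Non-responders produce no
    events regardless of the distributions.
    """

    sex: Sex
    responder: bool = True
    count_mean: float = 4.93
    count_fixed: int | None = None  # degenerate count distribution
    duration_mean_s: float = 85.0
    duration_cv: float = 0.5
    latency_mean_s: float = 379.0
    latency_cv: float = 0.5
    onset_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    se_prob: float = 0.0
    se_duration_range_s: tuple[float, float] = (310.0, 420.0)
    theta_prob: float = 0.8
    focal_prob: float = 0.3
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        if abs(sum(self.onset_probs) - 1.0) > 1e-9:
            raise InvalidArgumentError("onset_probs must sum to 1 within 1e-9")
        if min(self.count_mean, self.duration_mean_s, self.latency_mean_s) <= 0:
            raise InvalidArgumentError("distribution means must be positive")
        if not 0.0 <= self.se_prob <= 1.0:
            raise InvalidArgumentError("se_prob must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One planted ictal event, exactly as the generator placed it.

    ``channel_delays`` maps channel number (1-based) to onset delay in
    seconds relative to ``onset``; channels absent from the map are not
    involved in the event.
    """

    onset: float
    duration: float
    event_class: EventClass
    dominant_freq: float
    amplitude_pp: float
    onset_channel: int
    channel_delays: dict[int, float]

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def generalized(self) -> bool:
        return len(self.channel_delays) == 4


@dataclass
class Recording:
    """A multichannel voltage trace with montage and session metadata."""

    samples: np.ndarray  # (n_channels, n_samples), μV
    fs: float
    montage: dict[int, str]
    marks: TimelineMarks
    animal_id: str = "animal"
    sex: Sex | None = None

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) / self.fs

    def validate(self) -> None:
        if self.samples.ndim != 2:
            raise InvalidArgumentError("samples must be 2-D (channels x time)")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("recording contains non-finite samples")


@dataclass(frozen=True)
class FilterSpec:
    """Acquisition band-pass: 0.1–55 Hz by default, to stay clear of 60 Hz
    line noise, applied forward-backward (zero phase)."""

    low_cut: float = 0.1
    high_cut: float = 55.0
    order: int = 14
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low_cut < self.high_cut):
            raise InvalidArgumentError("need 0 < low_cut < high_cut")
        if self.high_cut >= fs / 2:
            raise InvalidArgumentError(
                f"high_cut {self.high_cut} Hz must be below Nyquist ({fs / 2} Hz)"
            )


@dataclass(frozen=True)
class BaselineStats:
    """Per-channel robust amplitude statistics from the pre-injection
    control window only."""

    mad: np.ndarray  # per-channel median absolute deviation, μV
    p2p_reference: np.ndarray  # per-channel median 2-s peak-to-peak, μV

    def __post_init__(self) -> None:
        if np.any(self.mad <= 0):
            raise InvalidArgumentError(
                "degenerate baseline: non-positive amplitude scale"
            )


@dataclass
class SeizureEvent:
    """One detected (or recorded ground-truth) epileptiform event."""

    onset: float
    offset: float
    per_channel_onset: dict[int, float] = field(default_factory=dict)
    event_class: EventClass = "other"
    dominant_freq: float = float("nan")
    is_SE: bool = False
    spread: Spread = "focal"
    onset_channel: int = 0
    onset_tie: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_channel_onset"] = dict(self.per_channel_onset)
        return d


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the series skin-electrode equivalent circuit
    R_s + (R_sub || C_sub) + (R_ct || CPE), with CPE impedance
    Z = 1 / (Q (jω)^n).

    Units: resistances Ω, C_sub farad, Q in S·s^n, n dimensionless in
    [0, 1] (n = 1 is an ideal capacitor). The subcutaneous block
    (R_sub, C_sub) may be absent (None) in the reduced 4-parameter model
    used for sparse magnitude-only spectra.
    """

    R_s: float
    R_ct: float
    Q: float
    n: float
    R_sub: float | None = None
    C_sub: float | None = None

    def __post_init__(self) -> None:
        if min(self.R_s, self.R_ct, self.Q) <= 0:
            raise InvalidArgumentError("resistances and Q must be positive")
        if not 0.0 <= self.n <= 1.0:
            raise InvalidArgumentError("CPE exponent n must lie in [0, 1]")
        if (self.R_sub is None) != (self.C_sub is None):
            raise InvalidArgumentError("R_sub and C_sub must be given together")
        if self.R_sub is not None and (self.R_sub <= 0 or self.C_sub <= 0):
            raise InvalidArgumentError("R_sub and C_sub must be positive")


@dataclass(frozen=True)
class EISSpectrum:
    """Impedance magnitude spectrum (optionally with phase in degrees)."""

    freqs: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise InvalidArgumentError("freqs and magnitude must be matching 1-D")
        if np.any(np.diff(f) <= 0):
            raise InvalidArgumentError("frequencies must be strictly increasing")
        if np.any(m <= 0):
            raise InvalidArgumentError("magnitudes must be positive")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "magnitude", m)


@dataclass(frozen=True)
class AnimalMetrics:
    """Per-animal seizure summary over one session."""

    animal_id: str
    sex: Sex | None
    n_events: int
    n_long_events: int  # events lasting > 120 s
    mean_duration: float  # s; NaN when n_events == 0
    latency_first: float  # s from injection_time; NaN when n_events == 0
    has_SE: bool

    def __post_init__(self) -> None:
        if self.n_long_events > self.n_events:
            raise InvalidArgumentError("n_long_events cannot exceed n_events")


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance two-sample Student t comparison of one metric."""

    metric: str
    statistic: float
    df: int
    p_value: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
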