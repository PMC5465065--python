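"""Morlet-wavelet time-frequency analysis.

Scalograms are computed with the complex Morlet wavelet (centre frequency
ω0 = 6 by default, the standard admissibility-respecting choice) on a
log-spaced frequency grid over [0.5, 50] Hz, which covers the 0–50 Hz
range in which ictal activity in this model is expressed. The transform
is delegated to PyWavelets' ``cmorB-C`` wavelet with B = 2 and
C = ω0 / 2π, the mapping of the standard Morlet ψ(t) = π^{-1/4}
e^{iω0 t} e^{-t²/2} onto pywt's parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .types import InvalidArgumentError, SeizureEvent

DEFAULT_FREQS = np.geomspace(0.5, 50.0, 100)
DEFAULT_OMEGA0 = 6.0


@dataclass
class TFMap:
    """Time × frequency power map (μV²)."""

    times: np.ndarray  # seconds
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_freqs, n_times), >= 0
    coi_masked: bool = False

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise InvalidArgumentError("power dimensions must match grids")


def _wavelet(omega0: float) -> pywt.ContinuousWavelet:
    centre = omega0 / (2 * np.pi)
    return pywt.ContinuousWavelet(f"cmor2.0-{centre:.6f}")


def morlet_cwt(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    omega0: float = DEFAULT_OMEGA0,
    mask_coi: bool = True,
) -> TFMap:
    """Complex Morlet continuous wavelet transform; power = |W|².

    The cone of influence (edges within half a wavelet width, taken as
    ω0 / (2π f) seconds) is zeroed unless ``mask_coi`` is False.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise InvalidArgumentError("frequency grid is empty")
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise InvalidArgumentError("frequencies must lie in (0, fs/2)")
    w = _wavelet(omega0)
    scales = pywt.frequency2scale(w, freqs / fs)
    coef, actual = pywt.cwt(np.asarray(x, dtype=float), scales, w, sampling_period=1.0 / fs)
    power = np.abs(coef) ** 2
    times = np.arange(len(x)) / fs
    if mask_coi:
        for i, f in enumerate(freqs):
            half_width = int(round(omega0 / (2 * np.pi * f) * fs))
            if half_width > 0:
                power[i, :half_width] = 0.0
                power[i, len(x) - half_width :] = 0.0
    return TFMap(times=times, freqs=freqs, power=power, coi_masked=mask_coi)


def global_wavelet_spectrum(tfmap: TFMap) -> np.ndarray:
    """Time-averaged power per frequency (the global wavelet spectrum)."""
    return tfmap.power.mean(axis=1)


def onset_confirmation(
    tfmaps: dict[int, TFMap],
    event: SeizureEvent,
    band: tuple[float, float] | None = None,
    ratio: float = 10.0,
    pre_window_s: float = 30.0,
) -> int | None:
    """Earliest channel whose band-limited power crosses ``ratio`` × its
    pre-event median; a time-frequency cross-check of localization.

    Returns the channel number, or None when no channel crosses the
    threshold inside the event (a baseline-only interval). Simultaneous
    crossings resolve to the lowest channel index.
    """
    if not tfmaps:
        raise InvalidArgumentError("need at least one channel map")
    spans = {ch: (m.times[0], m.times[-1]) for ch, m in tfmaps.items()}
    if len(set(spans.values())) != 1:
        raise InvalidArgumentError("per-channel maps cover different intervals")
    if band is None:
        if event.event_class == "spike_wave":
            band = (1.5, 3.5)
        elif event.event_class == "theta":
            band = (4.5, 7.5)
        else:
            band = (1.0, 40.0)
    best: tuple[float, int] | None = None
    for ch in sorted(tfmaps):
        m = tfmaps[ch]
        sel = (m.freqs >= band[0]) & (m.freqs <= band[1])
        if not np.any(sel):
            raise InvalidArgumentError("band does not intersect the frequency grid")
        bp = m.power[sel].mean(axis=0)
        pre = (m.times >= event.onset - pre_window_s) & (m.times < event.onset)
        ref = np.median(bp[pre]) if np.any(pre) else np.median(bp)
        during = (m.times >= event.onset) & (m.times <= event.offset)
        # floor the reference at 0.1% of the in-event peak so a numerically
        # silent pre-event window cannot make the wavelet tails cross early
        floor = max(ref, 1e-3 * bp[during].max(initial=0.0), np.finfo(float).tiny)
        idx = np.flatnonzero(during & (bp > ratio * floor))
        if idx.size:
            t_cross = m.times[idx[0]]
            if best is None or t_cross < best[0]:
                best = (t_cross, ch)
    return None if best is None else best[1]


def save_tfmap_csv(tfmap: TFMap, path) -> None:
    """Write the power matrix as CSV with frequency rows and time columns."""
    import pandas as pd

    df = pd.DataFrame(
        tfmap.power,
        index=[f"{f:.4f}" for f in tfmap.freqs],
        columns=[f"{t:.4f}" for t in tfmap.times],
    )
    df.index.name = "freq_hz"
    df.to_csv(path)


def save_tfmap_png(tfmap: TFMap, path, title: str = "") -> None:
    """Render the scalogram as a log-frequency heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    mesh = ax.pcolormesh(
        tfmap.times, tfmap.freqs, tfmap.power, shading="auto", cmap="magma"
    )
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="power (μV²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
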