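"""Recording and event I/O, plus the acquisition band-pass filter.

Recordings travel as 16-bit EDF (the interchange format of clinical EEG)
or as a plain long-form CSV (``time_s, ch1..chN``). The EDF writer here is
a minimal single-data-record-per-second implementation sufficient for
continuous equal-rate channels; reading goes through MNE's EDF reader.

The band-pass reproduces the acquisition chain of skin-surface zebrafish
EEG: 0.1–55 Hz, chosen to exclude 60 Hz line noise, realized as a
4th-order Butterworth applied forward-backward (zero phase).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import CHANNEL_LABELS, DEFAULT_MONTAGE
from .types import (
    FilterSpec,
    InvalidArgumentError,
    ParseError,
    Recording,
    SeizureEvent,
    TimelineMarks,
)

EDF_PHYS_RANGE_UV = 500.0  # default EDF physical range; clipping is an error

_EVENT_COLUMNS = [
    "onset",
    "offset",
    "event_class",
    "dominant_freq",
    "is_SE",
    "spread",
    "onset_channel",
    "onset_tie",
    "per_channel_onset",
]


def _pad(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    recording: Recording,
    path: str | Path,
    labels: tuple[str, ...] = CHANNEL_LABELS,
    phys_range_uv: float = EDF_PHYS_RANGE_UV,
) -> None:
    """Write a recording as 16-bit EDF with physical dimension μV.

    Samples outside ±``phys_range_uv`` raise rather than saturate
    silently. One data record holds one second per channel; a final
    partial second is zero-padded.
    """
    data = np.asarray(recording.samples, dtype=float)
    nch, nsamp = data.shape
    if len(labels) < nch:
        raise InvalidArgumentError("need one label per channel")
    if np.abs(data).max(initial=0.0) > phys_range_uv:
        raise InvalidArgumentError(
            f"samples exceed the EDF physical range ±{phys_range_uv} μV; "
            "increase phys_range_uv"
        )
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise InvalidArgumentError("EDF writer requires an integer sampling rate")
    nrec = int(np.ceil(nsamp / spr))
    padded = np.zeros((nch, nrec * spr))
    padded[:, :nsamp] = data
    pmin, pmax = -phys_range_uv, phys_range_uv
    dmin, dmax = -32768, 32767
    ints = np.round(
        (padded - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"{recording.animal_id} {recording.sex or 'X'} X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(256 * (nch + 1), 8),
            _pad("", 44),
            _pad(nrec, 8),
            _pad(1, 8),
            _pad(nch, 4),
        ]
    )
    header += b"".join(_pad(lab, 16) for lab in labels[:nch])
    header += b"".join(_pad("AgAgCl skin electrode", 80) for _ in range(nch))
    header += b"".join(_pad("uV", 8) for _ in range(nch))
    header += b"".join(_pad(pmin, 8) for _ in range(nch))
    header += b"".join(_pad(pmax, 8) for _ in range(nch))
    header += b"".join(_pad(dmin, 8) for _ in range(nch))
    header += b"".join(_pad(dmax, 8) for _ in range(nch))
    header += b"".join(_pad("HP:0.1Hz LP:55Hz", 80) for _ in range(nch))
    header += b"".join(_pad(spr, 8) for _ in range(nch))
    header += b"".join(_pad("", 32) for _ in range(nch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(nrec):
            for c in range(nch):
                fh.write(ints[c, r * spr : (r + 1) * spr].tobytes())


def write_csv(recording: Recording, path: str | Path) -> None:
    """Write a recording as long-form CSV: time_s, ch1..chN (μV)."""
    nch = recording.n_channels
    df = pd.DataFrame({"time_s": recording.times})
    for c in range(nch):
        df[f"ch{c + 1}"] = recording.samples[c]
    df.to_csv(path, index=False, float_format="%.4f")


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    marks: TimelineMarks | None = None,
    fs: float | None = None,
) -> Recording:
    """Read a recording from EDF or CSV.

    The format is inferred from the suffix unless ``fmt`` is given. CSV
    files must carry a header naming a time column (``time_s``) and the
    channel columns; ``fs`` is inferred from the time column if absent.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path, marks)
    if fmt == "csv":
        return _read_csv(path, marks, fs)
    raise InvalidArgumentError(f"unknown recording format {fmt!r}")


def _read_edf(path: Path, marks: TimelineMarks | None) -> Recording:
    import mne

    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    units = raw._orig_units if hasattr(raw, "_orig_units") else {}
    for ch, unit in units.items():
        if unit not in ("uV", "µV", "mV", "n/a"):
            raise ParseError(f"channel {ch}: unsupported unit {unit!r}")
    data_uv = raw.get_data() * 1e6  # MNE holds volts internally
    return Recording(
        samples=data_uv,
        fs=float(raw.info["sfreq"]),
        montage=dict(DEFAULT_MONTAGE),
        marks=marks or TimelineMarks(),
        animal_id=path.stem,
    )


def _read_csv(
    path: Path, marks: TimelineMarks | None, fs: float | None
) -> Recording:
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time_s'")
    chans = [c for c in df.columns if c.startswith("ch")]
    if not chans:
        raise ParseError(f"{path}: no channel columns (ch1..chN) found")
    if df[chans].isna().any().any():
        bad = df[chans].isna().any(axis=1).idxmax()
        raise ParseError(f"{path}: missing sample value near row {bad + 2}")
    t = df["time_s"].to_numpy()
    if fs is None:
        dt = np.diff(t)
        if len(dt) == 0 or np.ptp(dt) > 1e-6:
            raise ParseError(f"{path}: time column is not uniformly sampled")
        fs = 1.0 / dt[0]
    return Recording(
        samples=df[chans].to_numpy().T,
        fs=float(fs),
        montage=dict(DEFAULT_MONTAGE),
        marks=marks or TimelineMarks(),
        animal_id=path.stem,
    )


def bandpass(recording: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase Butterworth band-pass, defaulting to 0.1–55 Hz.

    Gain is within ±1 dB at 10 Hz and attenuation at 60 Hz exceeds 20 dB
    for the default spec at fs ≥ 200 Hz.
    """
    spec = spec or FilterSpec()
    spec.validate(recording.fs)
    sos = signal.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="band",
        fs=recording.fs,
        output="sos",
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.samples, axis=1)
    return Recording(
        samples=filtered,
        fs=recording.fs,
        montage=dict(recording.montage),
        marks=recording.marks,
        animal_id=recording.animal_id,
        sex=recording.sex,
    )


def write_events(events: list[SeizureEvent], path: str | Path) -> None:
    """Write events as a tidy CSV; per-channel onsets are packed as
    ``ch:onset`` pairs separated by ``;`` in one column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLUMNS)
        for ev in sorted(events, key=lambda e: e.onset):
            pco = ";".join(
                f"{ch}:{t:.6f}" for ch, t in sorted(ev.per_channel_onset.items())
            )
            w.writerow(
                [
                    f"{ev.onset:.6f}",
                    f"{ev.offset:.6f}",
                    ev.event_class,
                    f"{ev.dominant_freq:.6f}",
                    int(ev.is_SE),
                    ev.spread,
                    ev.onset_channel,
                    int(ev.onset_tie),
                    pco,
                ]
            )


def read_events(path: str | Path) -> list[SeizureEvent]:
    """Read an event CSV written by :func:`write_events`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    events: list[SeizureEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_EVENT_COLUMNS) - set(reader.fieldnames):
            missing = set(_EVENT_COLUMNS) - set(reader.fieldnames or [])
            raise ParseError(f"{path}: missing event columns {sorted(missing)}")
        for i, row in enumerate(reader):
            try:
                pco = {}
                if row["per_channel_onset"]:
                    for pair in row["per_channel_onset"].split(";"):
                        ch, t = pair.split(":")
                        pco[int(ch)] = float(t)
                events.append(
                    SeizureEvent(
                        onset=float(row["onset"]),
                        offset=float(row["offset"]),
                        per_channel_onset=pco,
                        event_class=row["event_class"],
                        dominant_freq=float(row["dominant_freq"]),
                        is_SE=bool(int(row["is_SE"])),
                        spread=row["spread"],
                        onset_channel=int(row["onset_channel"]),
                        onset_tie=bool(int(row["onset_tie"])),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: bad event row {i + 2}: {exc}") from exc
    return events
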