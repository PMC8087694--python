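"""Reading, writing and segmenting ECG and behaviour recordings.

Two recording styles flow through the same containers:

* human polysomnography-style ECG: one continuous trace (EDF), cut into
  fixed 10,000-sample analysis sweeps;
* rodent telemetry: pre-cut 10-s ECG sweeps recorded every 5 min, with
  companion locomotor-activity and body-temperature channels on the same
  5-min grid (CSV dialect written by :mod:`chronoecg.synthio`).

Conventions: sample values in mV, sampling rate in Hz, timestamps in
seconds from the recording start, 0-based sample indices and half-open
windows.  Zeitgeber time is derived from the schedule's lights-on hour.
"""

from __future__ import annotations

import datetime as _dt
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SWEEP_LEN = 10_000  # samples per analysis sweep

#: anchor used when serialising relative timestamps to ISO-8601 and back
TIME_ANCHOR = _dt.datetime(2000, 1, 1, 0, 0, 0)


@dataclass
class EcgTrace:
    """A continuous sampled ECG voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    fs : float
        Sampling rate in Hz.
    species : {"mouse", "human"}
    start_time : float
        Seconds from the recording anchor at which the first sample falls.
    label : str
        Channel label.
    """

    samples: np.ndarray
    fs: float
    species: str = "human"
    start_time: float = 0.0
    label: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Sweep:
    """One fixed-length analysis window of an ECG recording."""

    samples: np.ndarray
    fs: float
    t0: float  # seconds from recording anchor
    species: str = "human"
    start: int = 0  # sample offset into the parent trace
    sweep_id: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class ActivityTrace:
    """Locomotor activity counts (and optional body temperature) per bin."""

    t0: np.ndarray  # bin start, seconds from anchor
    counts: np.ndarray  # nonnegative counts per bin; 0 == inactive
    bin_s: float = 300.0
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t0 = np.asarray(self.t0, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be nonnegative")


def segment_sweeps(trace: EcgTrace, sweep_len: int = SWEEP_LEN) -> list[Sweep]:
    """Cut a continuous trace into consecutive non-overlapping sweeps.

    The trailing window is emitted only when complete; a shorter remainder
    is dropped (flagged via a warning).  A trace shorter than one sweep
    yields an empty list with a warning.
    """
    n = len(trace)
    if n < sweep_len:
        warnings.warn(
            f"trace of {n} samples is shorter than one {sweep_len}-sample sweep",
            stacklevel=2,
        )
        return []
    sweeps = []
    for k, start in enumerate(range(0, n - sweep_len + 1, sweep_len)):
        sweeps.append(
            Sweep(
                samples=trace.samples[start : start + sweep_len],
                fs=trace.fs,
                t0=trace.start_time + start / trace.fs,
                species=trace.species,
                start=start,
                sweep_id=k,
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channel: str | None = None,
             species: str = "human") -> EcgTrace:
    """Read one ECG channel from an EDF/EDF+ file.

    Physical units are normalised to mV (µV auto-converted); any other unit
    raises.  A missing channel raises with the available labels listed.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = raw.ch_names
    if channel is None:
        channel = labels[0]
    if channel not in labels:
        raise ValueError(
            f"channel {channel!r} not found; available channels: {labels}"
        )
    orig_units = getattr(raw, "_orig_units", {}) or {}
    unit = str(orig_units.get(channel, "uV")).strip()
    # mne rescales recognised units to SI volts internally
    data = raw.get_data(picks=[channel])[0]
    if unit.lower() in {"mv", "millivolt", "uv", "µv", "microvolt"}:
        samples_mv = data * 1e3  # V -> mV
    else:
        raise ValueError(f"unsupported physical unit {unit!r} for {channel!r}")
    return EcgTrace(samples=samples_mv, fs=float(raw.info["sfreq"]),
                    species=species, label=channel)


def write_edf(path: str | Path, trace: EcgTrace) -> None:
    """Write a single-channel EDF file (16-bit, 1-s data records).

    The trace is padded to a whole number of 1-s records with the final
    sample value.  Quantisation follows the EDF physical/digital scaling.
    """
    fs = trace.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    x = trace.samples
    n_rec = int(np.ceil(len(x) / fs))
    pad = n_rec * fs - len(x)
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1])])

    phys_min = float(np.min(x))
    phys_max = float(np.max(x))
    if phys_max <= phys_min:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((x - phys_min) * gain) + dig_min,
                      dig_min, dig_max).astype("<i2")

    start = TIME_ANCHOR + _dt.timedelta(seconds=trace.start_time)

    def f(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        f("0", 8),
        f("X X X X", 80),
        f("synthetic ECG", 80),
        f(start.strftime("%d.%m.%y"), 8),
        f(start.strftime("%H.%M.%S"), 8),
        f(str(256 + 256), 8),
        f("", 44),
        f(str(n_rec), 8),
        f("1", 8),          # record duration, seconds
        f("1", 4),          # number of signals
    ])
    sig_header = b"".join([
        f(trace.label, 16),
        f("ECG electrode", 80),
        f("mV", 8),
        f(f"{phys_min:.6g}", 8),
        f(f"{phys_max:.6g}", 8),
        f(str(dig_min), 8),
        f(str(dig_max), 8),
        f("", 80),
        f(str(fs), 8),
        f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.reshape(n_rec, fs).tobytes())


# ---------------------------------------------------------------------------
# Telemetry CSV dialect
# ---------------------------------------------------------------------------

def _iso(t_s: float) -> str:
    return (TIME_ANCHOR + _dt.timedelta(seconds=float(t_s))).isoformat()


def _from_iso(stamp: str) -> float:
    return (_dt.datetime.fromisoformat(stamp) - TIME_ANCHOR).total_seconds()


def write_telemetry_csv(ecg_path: str | Path, sweeps: list[Sweep],
                        behavior_path: str | Path | None = None,
                        activity: ActivityTrace | None = None) -> None:
    """Write telemetry-style sweep CSV and companion behaviour CSV.

    Sweep rows: ``sweep_id, t0_iso8601, fs, species, s0, s1, ...`` with the
    samples in mV.  Behaviour rows: ``t0_iso8601, activity, temperature``
    on the 5-min grid.
    """
    rows = []
    for sw in sweeps:
        rows.append(
            [sw.sweep_id, _iso(sw.t0), sw.fs, sw.species]
            + [f"{v:.6g}" for v in sw.samples]
        )
    n_samp = max(len(sw) for sw in sweeps)
    cols = ["sweep_id", "t0_iso8601", "fs", "species"] + [
        f"s{i}" for i in range(n_samp)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(ecg_path, index=False)

    if behavior_path is not None and activity is not None:
        temp = (activity.temperature if activity.temperature is not None
                else np.full(len(activity.counts), np.nan))
        pd.DataFrame({
            "t0_iso8601": [_iso(t) for t in activity.t0],
            "activity": activity.counts,
            "temperature": temp,
        }).to_csv(behavior_path, index=False)


def read_telemetry_csv(ecg_path: str | Path,
                       behavior_path: str | Path | None = None
                       ) -> tuple[list[Sweep], ActivityTrace | None]:
    """Read the telemetry CSV dialect back into sweeps (+ behaviour).

    Malformed rows and duplicate sweep ids raise with the offending row
    identified.  When no behaviour file is given the activity component is
    ``None`` and downstream activity analyses will refuse to run.
    """
    df = pd.read_csv(ecg_path)
    required = {"sweep_id", "t0_iso8601", "fs", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"sweep CSV missing columns {required - set(df.columns)}")
    if df["sweep_id"].duplicated().any():
        dup = df.loc[df["sweep_id"].duplicated(), "sweep_id"].iloc[0]
        raise ValueError(f"duplicate sweep_id {dup}")
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    sweeps = []
    for i, row in df.iterrows():
        samples = row[sample_cols].to_numpy(dtype=float)
        samples = samples[np.isfinite(samples)]
        if samples.size == 0:
            raise ValueError(f"malformed sweep row {i}: no samples")
        try:
            t0 = _from_iso(row["t0_iso8601"])
        except ValueError as exc:
            raise ValueError(f"malformed timestamp in row {i}") from exc
        sweeps.append(Sweep(samples=samples, fs=float(row["fs"]), t0=t0,
                            species=str(row["species"]),
                            sweep_id=int(row["sweep_id"])))

    activity = None
    if behavior_path is not None:
        bdf = pd.read_csv(behavior_path)
        temp = bdf["temperature"].to_numpy(dtype=float)
        activity = ActivityTrace(
            t0=np.array([_from_iso(s) for s in bdf["t0_iso8601"]]),
            counts=bdf["activity"].to_numpy(dtype=float),
            temperature=None if np.all(np.isnan(temp)) else temp,
        )
    return sweeps, activity


def write_annotations_csv(path: str | Path, annotations: pd.DataFrame) -> None:
    """Write the per-beat annotation dialect.

    Columns: ``beat_time_s, label, sweep_id`` plus 0-based sample indices
    ``P, Poff, Qon, R, Tpk, Toff`` relative to the containing sweep.
    """
    annotations.to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def zt_hours(t_s: np.ndarray | float, lights_on_h: float = 0.0) -> np.ndarray:
    """Convert anchored seconds to zeitgeber time (hours after lights-on)."""
    return (np.asarray(t_s, dtype=float) / 3600.0 - lights_on_h) % 24.0
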