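"""Species-dialect PQRST delineation and per-sweep interval summaries.

Landmark rules (per beat, on a lightly smoothed trace):

* P peak: maximal point between the previous beat (its T offset) and the
  current R wave, excluding a QRS guard.
* P offset: mouse - first positive deflection right of the P peak;
  human - first crossing of the isoelectric line right of the P peak.
* Q onset: mouse - first positive deflection left of the R peak (the QRS
  trough); human - the first negative deflection left of that trough (the
  Q-wave departure from baseline).
* T peak: extremum between the current R wave and the next beat's P
  region - a maximum in humans, a minimum in mice (inverted T).
* T offset: mouse - return to the isoelectric line after the T trough;
  human - first positive deflection after crossing the isoelectric line.

A "deflection" is a sustained sign change of the first difference of the
smoothed trace; a "crossing" is the first sample at or beyond the
isoelectric level.  The isoelectric level is the median of the baseline
segment between the previous T offset and a guard before the P peak.
Landmarks that cannot be located (empty window, ordering violation) are
flagged invalid for the affected interval only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beatdet import BeatSet, QCResult
from .io import Sweep


@dataclass
class DelineationConfig:
    """Search-window and smoothing settings (ms unless stated)."""

    smooth_width: int = 3      # samples, centred moving average
    sustain: int = 3           # samples a deflection must persist
    offset_smooth_width: int = 7  # heavier smoothing for offset searches
    net_span: int = 3          # span of the net-change deflection test
    qrs_guard_ms: float = 12.0     # half-extent of the QRS search region
    p_guard_ms: float = 8.0        # gap between iso segment and P peak
    t_guard_ms: float = 10.0       # gap after R before the T search
    t_end_frac: float = 0.75       # T search end, fraction of local RR
    iso_gap_ms: float = 2.0        # gap after previous T offset
    min_iso_samples: int = 5
    p_min_amp_mv: float = 0.05     # P validity threshold above iso
    t_min_amp_mv: float = 0.05

    @classmethod
    def for_species(cls, species: str) -> "DelineationConfig":
        if species == "mouse":
            return cls()
        # polysomnography rates (128-256 Hz): coarser samples carry more
        # signal per step, so lighter smoothing and a shorter span suffice
        return cls(qrs_guard_ms=80.0, p_guard_ms=60.0, t_guard_ms=60.0,
                   iso_gap_ms=15.0, offset_smooth_width=3, net_span=2)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    if width % 2 == 0:
        width += 1
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _first_rising(d: np.ndarray, start: int, stop: int, sustain: int) -> int:
    """First index in [start, stop) where d >= 0 holds for `sustain` samples."""
    for i in range(start, min(stop, len(d) - sustain + 1)):
        if np.all(d[i : i + sustain] >= 0):
            return i
    return -1


def _falling_to_flat(s2: np.ndarray, start: int, stop: int,
                     smooth_width: int, span: int) -> int:
    """Locate where a descending limb flattens out ("first positive
    deflection" on a noisy trace).

    ``s2`` is the trace smoothed with the heavier ``smooth_width`` moving
    average; the test is a net-change over ``span`` samples (robust to
    sample-to-sample noise flips) and the smoothing delay is corrected so
    that on a clean compact-support wave the returned index is exactly
    the support edge.
    """
    corr = (smooth_width - 1) // 2
    hi = min(stop, len(s2) - span)
    for i in range(start, hi):
        if s2[i + span] >= s2[i]:
            return max(start, i - corr)
    return -1


def estimate_isoelectric(samples: np.ndarray, start: int, stop: int,
                         min_samples: int = 5) -> float:
    """Median of the pre-P baseline segment ``[start, stop)``; NaN when the
    segment is shorter than ``min_samples`` (landmarks depending on the
    isoelectric level are then flagged invalid)."""
    start = max(0, start)
    stop = min(len(samples), stop)
    if stop - start < min_samples:
        return np.nan
    return float(np.median(samples[start:stop]))


def annotate_beat(sweep: Sweep, r_index: int, *,
                  prev_r: int | None = None, next_r: int | None = None,
                  prev_toff: int | None = None, rr_est: float | None = None,
                  config: DelineationConfig | None = None,
                  smoothed: np.ndarray | None = None,
                  smoothed_heavy: np.ndarray | None = None) -> dict:
    """Locate P peak/offset, Q onset, T peak/offset for one beat.

    Returns a dict of sample indices (NaN for invalid landmarks) plus the
    isoelectric level.  First/last beats of a sweep receive the partial
    annotation their windows allow.
    """
    cfg = config or DelineationConfig.for_species(sweep.species)
    fs = sweep.fs
    x = sweep.samples
    s = smoothed if smoothed is not None else _smooth(x, cfg.smooth_width)
    s2 = (smoothed_heavy if smoothed_heavy is not None
          else _smooth(x, cfg.offset_smooth_width))
    d = np.diff(s)
    ms = fs / 1000.0
    guard = int(round(cfg.qrs_guard_ms * ms))
    out = {"R": int(r_index), "P": np.nan, "Poff": np.nan, "Qon": np.nan,
           "Tpk": np.nan, "Toff": np.nan, "iso": np.nan}
    r = int(r_index)

    if rr_est is None:
        if prev_r is not None:
            rr_est = (r - prev_r) / ms
        elif next_r is not None:
            rr_est = (next_r - r) / ms
        else:
            rr_est = 120.0 * cfg.qrs_guard_ms / 12.0  # generic fallback

    # ---- P search window -------------------------------------------------
    if prev_toff is not None and np.isfinite(prev_toff):
        w_start = int(prev_toff) + int(round(cfg.iso_gap_ms * ms))
    elif prev_r is not None:
        w_start = prev_r + int(round(0.55 * (r - prev_r)))
    else:
        w_start = max(0, r - int(round(0.6 * rr_est * ms)))
    w_stop = r - guard
    p = -1
    if w_stop - w_start >= 2:
        p = w_start + int(np.argmax(s[w_start:w_stop]))

    # ---- isoelectric level ----------------------------------------------
    p_guard = int(round(cfg.p_guard_ms * ms))
    iso_stop = (p - p_guard) if p >= 0 else w_stop
    iso = estimate_isoelectric(x, w_start, iso_stop, cfg.min_iso_samples)
    if not np.isfinite(iso):
        # fall back to the whole pre-QRS window so later beats still work
        iso = estimate_isoelectric(x, w_start, w_stop, cfg.min_iso_samples)
    out["iso"] = iso

    p_valid = (p >= 0 and np.isfinite(iso)
               and s[p] - iso >= cfg.p_min_amp_mv)
    if p_valid:
        out["P"] = p
        # ---- P offset ----
        if sweep.species == "mouse":
            j = _falling_to_flat(s2, p + 1, w_stop + guard,
                                 cfg.offset_smooth_width, cfg.net_span)
            if j > p:
                out["Poff"] = j
        else:
            seg = np.flatnonzero(s[p:w_stop] <= iso)
            if seg.size:
                out["Poff"] = p + int(seg[0])

    # ---- Q onset ---------------------------------------------------------
    q_lo = max(0, r - guard)
    if r - q_lo >= 2:
        # the QRS trough is deep relative to noise: locate it on the raw
        # trace (smoothing skews the asymmetric Q+R overlap by a sample)
        trough = q_lo + int(np.argmin(x[q_lo:r]))
        if sweep.species == "mouse":
            out["Qon"] = trough
        else:
            # scan left from the trough until the descent into the Q wave
            # stops (mirrored net-change test, smoothing-delay corrected)
            span = cfg.net_span
            corr = (cfg.offset_smooth_width - 1) // 2
            qon = q_lo
            for k in range(trough - 1, max(q_lo - guard, span) - 1, -1):
                if s2[k - span] <= s2[k]:
                    qon = min(trough, k + corr)
                    break
            out["Qon"] = qon

    # ---- T search --------------------------------------------------------
    t_lo = r + int(round(cfg.t_guard_ms * ms))
    if next_r is not None:
        t_hi = r + int(round(cfg.t_end_frac * (next_r - r)))
    else:
        t_hi = min(len(s), r + int(round(cfg.t_end_frac * rr_est * ms)))
    t_hi = min(t_hi, len(s) - 1)
    if t_hi - t_lo >= 2:
        seg = s[t_lo:t_hi]
        tpk = t_lo + (int(np.argmin(seg)) if sweep.species == "mouse"
                      else int(np.argmax(seg)))
        amp_ok = (np.isfinite(iso)
                  and abs(s[tpk] - iso) >= cfg.t_min_amp_mv)
        if amp_ok:
            out["Tpk"] = tpk
            stop = min(len(s), t_hi + guard)
            if sweep.species == "mouse":
                cross = np.flatnonzero(s[tpk:stop] >= iso)
                if cross.size:
                    out["Toff"] = tpk + int(cross[0])
            else:
                cross = np.flatnonzero(s[tpk:stop] <= iso)
                if cross.size:
                    c = tpk + int(cross[0])
                    j = _falling_to_flat(s2, c, stop,
                                         cfg.offset_smooth_width,
                                         cfg.net_span)
                    out["Toff"] = max(j, c) if j >= 0 else c

    # ---- ordering invariant ----------------------------------------------
    if np.isfinite(out["Poff"]) and np.isfinite(out["P"]) \
            and not out["P"] < out["Poff"]:
        out["Poff"] = np.nan
    if np.isfinite(out["Poff"]) and np.isfinite(out["Qon"]) \
            and not out["Poff"] <= out["Qon"]:
        out["Poff"] = np.nan
    if np.isfinite(out["Tpk"]) and not r < out["Tpk"]:
        out["Tpk"] = np.nan
        out["Toff"] = np.nan
    if np.isfinite(out["Toff"]) and np.isfinite(out["Tpk"]) \
            and not out["Tpk"] <= out["Toff"]:
        out["Toff"] = np.nan
    return out


def delineate_sweep(sweep: Sweep, beats: BeatSet,
                    config: DelineationConfig | None = None) -> pd.DataFrame:
    """Annotate every included beat of a sweep, left to right.

    The previous beat's T offset bounds the next beat's baseline segment.
    """
    cfg = config or DelineationConfig.for_species(sweep.species)
    s = _smooth(sweep.samples, cfg.smooth_width)
    s2 = _smooth(sweep.samples, cfg.offset_smooth_width)
    r_idx = beats.r_indices
    rr_est = (float(np.median(np.diff(r_idx))) / (sweep.fs / 1000.0)
              if len(r_idx) > 1 else None)
    rows = []
    prev_toff = None
    for j, r in enumerate(r_idx):
        prev_r = int(r_idx[j - 1]) if j > 0 else None
        next_r = int(r_idx[j + 1]) if j + 1 < len(r_idx) else None
        ann = annotate_beat(sweep, int(r), prev_r=prev_r, next_r=next_r,
                            prev_toff=prev_toff, rr_est=rr_est,
                            config=cfg, smoothed=s, smoothed_heavy=s2)
        prev_toff = ann["Toff"] if np.isfinite(ann["Toff"]) else None
        rows.append(ann)
    df = pd.DataFrame(rows, columns=["R", "P", "Poff", "Qon", "Tpk", "Toff",
                                     "iso"])
    df.insert(0, "sweep_id", sweep.sweep_id)
    return df


def compute_intervals(fids: pd.DataFrame, fs: float) -> pd.DataFrame:
    """Per-beat RR, PR segment and QT in ms from landmark indices.

    RR is the gap to the next beat's R; PR segment is Q onset minus P
    offset; QT is T offset minus Q onset.  An invalid landmark leaves the
    affected interval absent for that beat only.
    """
    ms = 1000.0 / fs
    r = fids["R"].to_numpy(dtype=float)
    rr = np.full(len(fids), np.nan)
    if len(fids) > 1:
        rr[:-1] = np.diff(r) * ms
    pr = (fids["Qon"].to_numpy(dtype=float)
          - fids["Poff"].to_numpy(dtype=float)) * ms
    qt = (fids["Toff"].to_numpy(dtype=float)
          - fids["Qon"].to_numpy(dtype=float)) * ms
    out = fids[["sweep_id", "R"]].copy()
    out["rr_ms"] = rr
    out["pr_ms"] = pr
    out["qt_ms"] = qt
    return out


@dataclass
class SweepIntervals:
    """Per-sweep median ECG parameters with QC pass-through."""

    sweep_id: int
    t0: float
    rr_ms: float
    pr_ms: float
    qt_ms: float
    hr_bpm: float
    n_valid_beats: int
    qc_pass: bool
    excluded: bool


def summarize_sweep(sweep: Sweep, intervals: pd.DataFrame,
                    qc: QCResult) -> SweepIntervals:
    """Reduce per-beat intervals to sweep medians; HR = 60000 / median RR.

    QC-failed sweeps (or sweeps with no valid beats) are returned flagged
    ``excluded`` so downstream binning can drop them.
    """
    n = int(intervals[["rr_ms", "pr_ms", "qt_ms"]].notna().any(axis=1).sum())
    med = intervals[["rr_ms", "pr_ms", "qt_ms"]].median()
    rr = float(med["rr_ms"])
    hr = 60000.0 / rr if np.isfinite(rr) and rr > 0 else np.nan
    excluded = (not qc.passed) or n == 0
    return SweepIntervals(sweep_id=sweep.sweep_id, t0=sweep.t0,
                          rr_ms=rr, pr_ms=float(med["pr_ms"]),
                          qt_ms=float(med["qt_ms"]), hr_bpm=hr,
                          n_valid_beats=n, qc_pass=qc.passed,
                          excluded=excluded)
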