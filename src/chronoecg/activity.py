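"""Acute locomotor-activity effects on ECG parameters.

Daily rhythms in RR/QT/PR mix a circadian component with the direct
effect of movement.  To separate them, a 24-h constrained sine is fitted
to *at-rest* points only (no activity in the preceding 30 min); deviations
from that rest curve then quantify the acute activity response with the
circadian phase removed.  "Inactive" means an activity count of zero in a
5-min telemetry bin; a "bout" is a maximal run of nonzero bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ActivityTrace
from .rhythms import Cosinor, CosinorResults


@dataclass
class RestFit:
    """24-h constrained sine fitted to rest-only points."""

    results: CosinorResults
    lookback_min: float
    n_rest_points: int
    rest_fraction: float

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        return self.results.predict(times_h)


@dataclass
class AlignedResponse:
    """Event-aligned mean parameter deviation on a relative-time grid."""

    rel_min: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    anchor: str  # 'activity_cessation' | 'bout_onset'
    n_dropped: int = 0


def _rest_mask(activity: ActivityTrace, lookback_min: float) -> np.ndarray:
    """True for bins with zero activity in this bin and the preceding
    lookback window."""
    zero = activity.counts == 0
    k = int(round(lookback_min * 60.0 / activity.bin_s))
    mask = zero.copy()
    for j in range(1, k + 1):
        shifted = np.ones_like(zero)
        shifted[j:] = zero[:-j]
        shifted[:j] = False  # unknown history: not certified at rest
        mask &= shifted
    return mask


def _sweep_bins(t_s: np.ndarray, activity: ActivityTrace) -> np.ndarray:
    return np.clip(((np.asarray(t_s) - activity.t0[0]) //
                    activity.bin_s).astype(int),
                   0, len(activity.counts) - 1)


def at_rest_profile(t_s: np.ndarray, values: np.ndarray,
                    activity: ActivityTrace | None,
                    lookback_min: float = 30.0) -> RestFit:
    """Fit the circadian rest profile of a parameter.

    Only sweeps in which the animal had zero activity counts through the
    current and the preceding ``lookback_min`` bins contribute.
    """
    if activity is None:
        raise ValueError("activity trace absent; rest analysis refused")
    t = np.asarray(t_s, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = _rest_mask(activity, lookback_min)
    rest = mask[_sweep_bins(t, activity)] & np.isfinite(v)
    if rest.sum() == 0:
        raise ValueError("no rest points (animal always active)")
    try:
        res = Cosinor(v[rest], t[rest] / 3600.0).fit()
    except ValueError as exc:
        raise ValueError(
            f"insufficient rest coverage for a 24-h fit: {exc}") from exc
    return RestFit(results=res, lookback_min=lookback_min,
                   n_rest_points=int(rest.sum()),
                   rest_fraction=float(rest.mean()))


def _bouts(activity: ActivityTrace) -> list[tuple[int, int]]:
    """Maximal runs of nonzero activity bins as (start, end) inclusive."""
    nz = activity.counts > 0
    edges = np.diff(nz.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if nz[0]:
        starts.insert(0, 0)
    if nz[-1]:
        ends.append(len(nz) - 1)
    return list(zip(starts, ends))


def _align(events: list[int], rel_bins: np.ndarray, t_s: np.ndarray,
           deviations: np.ndarray, activity: ActivityTrace,
           anchor: str, bin_min: float, n_dropped: int) -> AlignedResponse:
    sweep_bin = _sweep_bins(t_s, activity)
    per_event = []
    for e in events:
        row = np.full(len(rel_bins), np.nan)
        for i, db in enumerate(rel_bins):
            b = e + db
            hits = deviations[sweep_bin == b]
            hits = hits[np.isfinite(hits)]
            if hits.size:
                row[i] = hits.mean()
        per_event.append(row)
    arr = np.asarray(per_event) if per_event else np.empty((0, len(rel_bins)))
    mean, sem = _nan_mean_sem(arr, len(rel_bins))
    return AlignedResponse(rel_min=rel_bins * bin_min, mean=mean, sem=sem,
                           n_events=len(events), anchor=anchor,
                           n_dropped=n_dropped)


def _nan_mean_sem(arr: np.ndarray, width: int) -> tuple:
    if len(arr) == 0:
        return np.full(width, np.nan), np.full(width, np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sem = (np.nanstd(arr, axis=0, ddof=1)
               / np.sqrt(np.sum(np.isfinite(arr), axis=0)))
    return mean, sem


def inactivity_aligned_response(t_s: np.ndarray, values: np.ndarray,
                                activity: ActivityTrace, rest: RestFit,
                                run_min: float = 45.0,
                                pre_min: float = 15.0) -> AlignedResponse:
    """Parameter relaxation after activity ends.

    Events are activity bouts followed by ``run_min`` of complete
    inactivity (every 5-min bin zero); time 0 is the cessation of
    activity.  Values are deviations from the at-rest circadian fit at the
    matching phase, averaged across events.
    """
    bin_min = activity.bin_s / 60.0
    run_bins = int(round(run_min / bin_min))
    pre_bins = int(round(pre_min / bin_min))
    zero = activity.counts == 0
    events = []
    for start, end in _bouts(activity):
        a = end + 1
        if a + run_bins > len(zero):
            continue
        if np.all(zero[a : a + run_bins]):
            events.append(a)
    t = np.asarray(t_s, dtype=float)
    dev = np.asarray(values, dtype=float) - rest.predict(t / 3600.0)
    rel = np.arange(-pre_bins, run_bins)
    return _align(events, rel, t, dev, activity, "activity_cessation",
                  bin_min, 0)


def transient_bout_response(t_s: np.ndarray, values: np.ndarray,
                            activity: ActivityTrace,
                            pre_min: float = 5.0,
                            post_min: float = 20.0) -> AlignedResponse:
    """Response to a sporadic single-bin activity bout.

    Events are activity bouts confined to one 5-min bin, preceded by more
    than ``pre_min`` and followed by more than ``post_min`` of inactivity.
    Values are expressed relative to the mean of the preceding rest bin;
    events whose windows overlap an earlier event are dropped (counted).
    """
    bin_min = activity.bin_s / 60.0
    pre_bins = max(1, int(round(pre_min / bin_min)))
    post_bins = int(round(post_min / bin_min))
    zero = activity.counts == 0
    n = len(zero)
    candidates = []
    for start, end in _bouts(activity):
        if end != start:
            continue  # multi-bin bout: not a transient
        if start - pre_bins < 0 or start + post_bins >= n:
            continue
        if np.all(zero[start - pre_bins : start]) \
                and np.all(zero[start + 1 : start + post_bins + 1]):
            candidates.append(start)
    events, n_dropped = [], 0
    last_end = -1
    for c in candidates:
        if c - pre_bins <= last_end:
            n_dropped += 1
            continue
        events.append(c)
        last_end = c + post_bins
    t = np.asarray(t_s, dtype=float)
    v = np.asarray(values, dtype=float)
    sweep_bin = _sweep_bins(t, activity)
    # subtract each event's own preceding-rest baseline
    rel = np.arange(-pre_bins, post_bins + 1)
    rows = []
    for e in events:
        base = v[(sweep_bin == e - 1) & np.isfinite(v)]
        if base.size == 0:
            n_dropped += 1
            continue
        b0 = base.mean()
        row = np.full(len(rel), np.nan)
        for i, db in enumerate(rel):
            hits = v[(sweep_bin == e + db) & np.isfinite(v)]
            if hits.size:
                row[i] = hits.mean() - b0
        rows.append(row)
    arr = np.asarray(rows) if rows else np.empty((0, len(rel)))
    mean, sem = _nan_mean_sem(arr, len(rel))
    return AlignedResponse(rel_min=rel * bin_min, mean=mean, sem=sem,
                           n_events=len(arr), anchor="bout_onset",
                           n_dropped=n_dropped)


def siesta_contrast(t_s: np.ndarray, values: np.ndarray,
                    activity: ActivityTrace | None = None,
                    siesta_window_zt: tuple | None = None,
                    comparison_h: float = 2.0,
                    lights_on_h: float = 0.0) -> pd.DataFrame:
    """Per-day paired contrast: siesta window vs the preceding window.

    When no window is given it defaults to the 2-h window minimising mean
    activity within ZT 18-24.  The comparison window immediately precedes
    the siesta window and must have the same length.
    """
    t = np.asarray(t_s, dtype=float)
    v = np.asarray(values, dtype=float)
    zt = (t / 3600.0 - lights_on_h) % 24.0
    if siesta_window_zt is None:
        if activity is None:
            raise ValueError("need activity or an explicit siesta window")
        azt = (activity.t0 / 3600.0 - lights_on_h) % 24.0
        best, best_mean = None, np.inf
        for start in np.arange(18.0, 24.0 - comparison_h + 1e-9, 0.25):
            m = (azt >= start) & (azt < start + comparison_h)
            if m.sum() and activity.counts[m].mean() < best_mean:
                best_mean = activity.counts[m].mean()
                best = (start, start + comparison_h)
        siesta_window_zt = best
    lo, hi = siesta_window_zt
    if abs((hi - lo) - comparison_h) > 1e-9:
        raise ValueError("siesta and comparison windows must match in length")
    if t.size == 0 or lo * 3600 > t.max():
        raise ValueError("siesta window outside the recording")
    day = np.floor(t / 86400.0).astype(int)
    rows = []
    for d in np.unique(day):
        in_d = day == d
        m_s = in_d & (zt >= lo) & (zt < hi) & np.isfinite(v)
        m_p = in_d & (zt >= lo - comparison_h) & (zt < lo) & np.isfinite(v)
        if m_s.sum() and m_p.sum():
            rows.append({"day": int(d), "siesta_mean": v[m_s].mean(),
                         "pre_mean": v[m_p].mean(),
                         "diff": v[m_s].mean() - v[m_p].mean()})
    return pd.DataFrame(rows, columns=["day", "siesta_mean", "pre_mean",
                                       "diff"])
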