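"""Rule-based ventricular ectopy labeling and episode calling.

A ventricular premature complex (VPC) is recognised by its morphology:
a QRS widened beyond ``width_factor`` times the sweep template's QRS
width, together with a gross change of the signed R-wave amplitude
relative to the template (which captures fully inverted complexes as well
as the alternate axis of bidirectional runs).  Prematurity (preceding RR
below 0.8x the local median) is computed and flagged but not required.

Episodes: a maximal run of at least four consecutive VPCs is ventricular
tachycardia (VT); a VT run whose signed R amplitudes alternate in sign
beat-to-beat is bidirectional VT (BVT).  Episode duration is recorded
(in vivo BVT episodes typically last tens of seconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beatdet import BeatSet
from .fiducials import _smooth
from .io import Sweep


def qrs_width_ms(samples: np.ndarray, r_index: int, iso: float, fs: float,
                 frac: float = 0.5, max_ms: float | None = None,
                 smooth_width: int = 3) -> float:
    """Width (ms) of the contiguous region around R where the rectified
    deflection stays above ``frac`` of the R amplitude.  NaN when the
    amplitude is too small to measure."""
    s = _smooth(np.asarray(samples, dtype=float), smooth_width)
    r = int(r_index)
    amp = s[r] - iso
    if abs(amp) < 1e-6:
        return np.nan
    thresh = frac * abs(amp)
    dev = (s - iso) * np.sign(amp)
    lim = int(round((max_ms or 1e9) * fs / 1000.0))
    left = r
    while left > 0 and dev[left - 1] >= thresh and r - left < lim:
        left -= 1
    right = r
    while right < len(s) - 1 and dev[right + 1] >= thresh and right - r < lim:
        right += 1
    return (right - left + 1) * 1000.0 / fs


@dataclass
class BeatLabelSeries:
    """Per-beat morphology labels for one sweep."""

    table: pd.DataFrame  # r_index, time_s, label, qrs_width_ms,
    #                      signed_amp_mv, premature
    template_width_ms: float
    template_amp_mv: float
    n_unmeasurable: int = 0


@dataclass
class VTEpisode:
    start_beat: int  # positional index into the label table
    end_beat: int    # inclusive
    length: int
    kind: str        # 'VT' | 'BVT'
    duration_s: float = np.nan

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("an episode requires at least 4 beats")


def classify_beats(sweep: Sweep, beats: BeatSet,
                   width_factor: float = 1.5,
                   amp_dev_frac: float = 0.5,
                   premature_factor: float = 0.8,
                   width_frac: float = 0.5) -> BeatLabelSeries:
    """Label each candidate beat normal or VPC against the sweep template.

    VPC requires BOTH a widened QRS (> ``width_factor`` x template
    width) and a signed R amplitude deviating from the template's by more
    than ``amp_dev_frac`` of its magnitude; a widened beat with normal
    amplitude/polarity is not a VPC.  Beats whose width cannot be
    measured are left unlabeled and counted.
    """
    if beats.template is None:
        raise ValueError("sweep template unavailable (too few beats)")
    fs = sweep.fs
    iso = float(np.median(sweep.samples))
    half = (len(beats.template) - 1) // 2
    tmpl_amp = float(beats.template[half] - np.median(beats.template))
    tmpl_width = qrs_width_ms(beats.template, half,
                              float(np.median(beats.template)), fs,
                              frac=width_frac)
    cand = beats.candidates
    rr_prev = np.full(len(cand), np.nan)
    if len(cand) > 1:
        rr_prev[1:] = np.diff(cand) * 1000.0 / fs
    local_med = np.nanmedian(rr_prev) if np.isfinite(rr_prev).any() else np.nan

    rows = []
    n_unmeas = 0
    for j, r in enumerate(cand):
        amp = float(sweep.samples[r] - iso)
        width = qrs_width_ms(sweep.samples, r, iso, fs, frac=width_frac,
                             max_ms=4 * tmpl_width if np.isfinite(tmpl_width)
                             else None)
        premature = bool(np.isfinite(rr_prev[j]) and np.isfinite(local_med)
                         and rr_prev[j] < premature_factor * local_med)
        if not np.isfinite(width) or not np.isfinite(tmpl_width):
            label = None
            n_unmeas += 1
        else:
            widened = width > width_factor * tmpl_width
            deviant = abs(amp - tmpl_amp) > amp_dev_frac * abs(tmpl_amp)
            label = "vpc" if (widened and deviant) else "normal"
        rows.append({"r_index": int(r), "time_s": sweep.t0 + r / fs,
                     "label": label, "qrs_width_ms": width,
                     "signed_amp_mv": amp, "premature": premature})
    table = pd.DataFrame(rows, columns=["r_index", "time_s", "label",
                                        "qrs_width_ms", "signed_amp_mv",
                                        "premature"])
    return BeatLabelSeries(table=table, template_width_ms=float(tmpl_width),
                           template_amp_mv=tmpl_amp,
                           n_unmeasurable=n_unmeas)


def call_episodes(labels: BeatLabelSeries) -> list[VTEpisode]:
    """Find VT/BVT episodes among the labeled beats.

    Maximal runs of >= 4 consecutive VPCs are VT; a run whose signed R
    amplitudes alternate in sign at every step is BVT.
    """
    tab = labels.table
    is_vpc = (tab["label"] == "vpc").to_numpy()
    amps = tab["signed_amp_mv"].to_numpy()
    times = tab["time_s"].to_numpy()
    episodes = []
    i = 0
    n = len(tab)
    while i < n:
        if not is_vpc[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_vpc[j + 1]:
            j += 1
        length = j - i + 1
        if length >= 4:
            signs = np.sign(amps[i : j + 1])
            alternating = bool(np.all(signs[1:] * signs[:-1] < 0))
            episodes.append(VTEpisode(
                start_beat=i, end_beat=j, length=length,
                kind="BVT" if alternating else "VT",
                duration_s=float(times[j] - times[i])))
        i = j + 1
    return episodes


def susceptible(trial_episodes: list[list[VTEpisode]]) -> bool:
    """A subject showing VT on every trial is classified susceptible."""
    return all(len(ep) > 0 for ep in trial_episodes)


@dataclass
class IncidenceResult:
    chi2: float
    df: int
    p_value: float
    odds_ratio: float
    table: np.ndarray


def incidence_test(table) -> IncidenceResult:
    """Pearson chi-square (no continuity correction) on a 2x2 incidence
    table, with the odds ratio reported alongside.

    Rows are conditions (e.g. time of day), columns outcomes
    (e.g. VT / no VT).  A zero row or column margin raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("incidence table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in the incidence table")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    a, b = t[0]
    c, d = t[1]
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return IncidenceResult(chi2=float(chi2), df=int(dof), p_value=float(p),
                           odds_ratio=float(odds), table=t.astype(int))
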