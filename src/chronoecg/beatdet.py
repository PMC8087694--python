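"""R-wave detection, template filtering and per-sweep quality control.

Beats are detected per sweep by amplitude thresholding of local extrema,
then filtered by correlation against the mean beat waveform of the sweep.
Three sweep-level rules exclude sweeps from further analysis:

1. the mean amplitude of the discriminated beat waveforms is below 3x the
   lower limit of the amplitude window,
2. baseline variation exceeds 1/3 of that lower limit,
3. more than 20% of detected events were removed by template matching.

Candidate peaks are taken on the absolute (baseline-referenced) signal so
that inverted ectopic complexes remain visible to the downstream
arrhythmia classifier; the signed amplitude at the detected sample is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Sweep

#: default refractory period (ms) by species: a physiological upper bound
#: on heart rate, wide enough that the T wave of the current beat cannot
#: register as a separate amplitude-window candidate
REFRACTORY_MS = {"mouse": 50.0, "human": 300.0}

#: default half-width (ms) of the beat/template window around R
TEMPLATE_HALFWIDTH_MS = {"mouse": 40.0, "human": 250.0}


@dataclass
class AmplitudeWindow:
    """Accepted |R| amplitude range in mV (an operator setting)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError("require 0 < lower < upper")

    @classmethod
    def from_signal(cls, samples: np.ndarray, lower_frac: float = 0.25,
                    upper_frac: float = 2.5) -> "AmplitudeWindow":
        """Default window derived from a near-peak amplitude quantile.

        The reference is the 99.9th percentile of the baseline-referenced
        rectified signal - essentially the R-peak level (R waves occupy a
        small fraction of samples, so lower quantiles would sit at T-wave
        level and the window would reject the R peaks themselves).
        """
        x = np.asarray(samples, dtype=float)
        ref = float(np.percentile(np.abs(x - np.median(x)), 99.9))
        ref = max(ref, 1e-9)
        return cls(lower=lower_frac * ref, upper=upper_frac * ref)


@dataclass
class BeatSet:
    """Candidate beats of one sweep with template-matching results."""

    candidates: np.ndarray  # R sample indices
    template: np.ndarray | None  # mean beat waveform, odd length, R centred
    included: np.ndarray  # bool mask over candidates
    mismatch: np.ndarray  # 1 - Pearson r against the template
    n_edge_truncated: int = 0
    flagged: bool = False  # too few candidates to build a template

    @property
    def r_indices(self) -> np.ndarray:
        return self.candidates[self.included]

    @property
    def rejection_fraction(self) -> float:
        if len(self.candidates) == 0:
            return 0.0
        return 1.0 - np.sum(self.included) / len(self.candidates)


@dataclass
class QCResult:
    """Outcome of the three sweep-exclusion rules."""

    passed: bool
    rule_failures: set = field(default_factory=set)
    mean_beat_amplitude: float = np.nan
    baseline_variation: float = np.nan
    rejection_fraction: float = np.nan

    def __post_init__(self) -> None:
        assert self.passed == (len(self.rule_failures) == 0)


def detect_r_peaks(sweep: Sweep, win: AmplitudeWindow,
                   refractory_ms: float | None = None) -> np.ndarray:
    """Detect candidate R peaks by amplitude thresholding.

    Local maxima of the baseline-referenced absolute signal with amplitude
    inside ``[lower, upper]`` are accepted greedily by decreasing
    amplitude, enforcing the refractory separation; amplitude ties break
    to the earlier sample.  An empty result is valid (the sweep will fail
    QC downstream).
    """
    if refractory_ms is None:
        refractory_ms = REFRACTORY_MS[sweep.species]
    if refractory_ms <= 0:
        raise ValueError("refractory must be positive")
    refr = int(round(refractory_ms * sweep.fs / 1000.0))
    x = np.abs(sweep.samples - np.median(sweep.samples))
    if len(x) < 3:
        return np.array([], dtype=int)
    interior = x[1:-1]
    is_peak = (interior > x[:-2]) & (interior >= x[2:])
    cand = np.flatnonzero(is_peak) + 1
    amp = x[cand]
    keep = (amp >= win.lower) & (amp <= win.upper)
    cand, amp = cand[keep], amp[keep]
    if len(cand) == 0:
        return cand
    order = np.lexsort((cand, -amp))  # amplitude desc, earlier-first ties
    accepted: list[int] = []
    taken = np.zeros(len(sweep), dtype=bool)
    for j in order:
        i = cand[j]
        lo, hi = max(0, i - refr), min(len(sweep), i + refr + 1)
        if not taken[lo:hi].any():
            accepted.append(i)
            taken[i] = True
    return np.array(sorted(accepted), dtype=int)


def _beat_windows(samples: np.ndarray, candidates: np.ndarray,
                  half: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract fixed windows around each candidate; flag edge truncation."""
    ok = (candidates - half >= 0) & (candidates + half < len(samples))
    full = candidates[ok]
    if len(full) == 0:
        return np.empty((0, 2 * half + 1)), ok
    idx = full[:, None] + np.arange(-half, half + 1)[None, :]
    return samples[idx], ok


def template_filter(sweep: Sweep, candidates: np.ndarray,
                    theta: float = 0.2,
                    halfwidth_ms: float | None = None) -> BeatSet:
    """Remove beats whose waveform departs from the sweep's mean beat.

    The template is the mean of the candidate beat windows (odd length,
    centred on R); the per-beat mismatch is ``1 - Pearson r`` against it
    and beats with mismatch above ``theta`` are excluded.  Beats whose
    window is truncated by the sweep edge are excluded and counted as
    rejected.  With fewer than two candidates all beats are retained and
    the set is flagged.
    """
    candidates = np.asarray(candidates, dtype=int)
    if halfwidth_ms is None:
        halfwidth_ms = TEMPLATE_HALFWIDTH_MS[sweep.species]
    half = max(1, int(round(halfwidth_ms * sweep.fs / 1000.0)))
    if len(candidates) < 2:
        return BeatSet(candidates=candidates, template=None,
                       included=np.ones(len(candidates), dtype=bool),
                       mismatch=np.zeros(len(candidates)), flagged=True)
    windows, ok = _beat_windows(sweep.samples, candidates, half)
    mismatch = np.full(len(candidates), np.inf)
    included = np.zeros(len(candidates), dtype=bool)
    if len(windows) == 0:
        return BeatSet(candidates=candidates, template=None,
                       included=included, mismatch=mismatch,
                       n_edge_truncated=int(np.sum(~ok)), flagged=True)
    template = windows.mean(axis=0)
    tc = template - template.mean()
    tn = np.sqrt(np.sum(tc * tc))
    wc = windows - windows.mean(axis=1, keepdims=True)
    wn = np.sqrt(np.sum(wc * wc, axis=1))
    denom = np.maximum(wn * tn, 1e-30)
    r = (wc @ tc) / denom
    mismatch[ok] = 1.0 - r
    included[ok] = mismatch[ok] <= theta
    return BeatSet(candidates=candidates, template=template,
                   included=included, mismatch=mismatch,
                   n_edge_truncated=int(np.sum(~ok)))


def baseline_variation(sweep: Sweep, beats: BeatSet,
                       halfwidth_ms: float | None = None) -> float:
    """Robust spread (MAD x 1.4826) of samples outside the beat windows."""
    if halfwidth_ms is None:
        halfwidth_ms = TEMPLATE_HALFWIDTH_MS[sweep.species]
    half = max(1, int(round(halfwidth_ms * sweep.fs / 1000.0)))
    mask = np.ones(len(sweep), dtype=bool)
    for i in beats.candidates:
        mask[max(0, i - half) : i + half + 1] = False
    base = sweep.samples[mask]
    if base.size < 10:
        return np.nan
    return 1.4826 * float(np.median(np.abs(base - np.median(base))))


def sweep_qc(sweep: Sweep, beats: BeatSet, win: AmplitudeWindow,
             max_rejection: float = 0.2,
             halfwidth_ms: float | None = None) -> QCResult:
    """Apply the three sweep-exclusion rules.

    A sweep fails when (1) the mean baseline-referenced |R| amplitude of
    included beats is strictly below ``3 * win.lower``, (2) the baseline
    spread strictly exceeds ``win.lower / 3``, or (3) the template
    rejection fraction strictly exceeds ``max_rejection``.  A sweep with
    no included beats fails with ``low_amplitude``.
    """
    failures = set()
    r_idx = beats.r_indices
    base_med = float(np.median(sweep.samples))
    if len(r_idx) == 0:
        mean_amp = 0.0
        failures.add("low_amplitude")
    else:
        mean_amp = float(np.mean(np.abs(sweep.samples[r_idx] - base_med)))
        if mean_amp < 3.0 * win.lower:
            failures.add("low_amplitude")
    spread = baseline_variation(sweep, beats, halfwidth_ms)
    if np.isfinite(spread) and spread > win.lower / 3.0:
        failures.add("baseline_noise")
    rej = beats.rejection_fraction
    if rej > max_rejection:
        failures.add("high_rejection")
    return QCResult(passed=not failures, rule_failures=failures,
                    mean_beat_amplitude=mean_amp,
                    baseline_variation=spread,
                    rejection_fraction=rej)
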