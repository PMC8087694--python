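"""Geometric heart-rate-variability measure on relative RR intervals.

Time-domain HRV statistics such as SDNN scale with absolute heart rate,
and frequency-domain measures need stationary, gap-free recordings, so
neither suits continuous long-term telemetry.  The measure here works on
*relative* RR intervals

    r_i = 2 (RR_i - RR_{i-1}) / (RR_i + RR_{i-1}),

which are exactly invariant under a uniform rescaling of all RR, and
summarises the Poincare cloud of consecutive pairs (r_i, r_{i+1}) by the
median Euclidean distance from its component-wise median (x100) - a
robust, outlier-insensitive spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HRVResult:
    measure: float          # dimensionless, percent
    n_pairs: int
    relative_rr: np.ndarray
    poincare: np.ndarray    # (n_pairs, 2) consecutive relative-RR pairs


def relative_rr(rr_ms: np.ndarray) -> np.ndarray:
    """Relative successive RR differences, dimensionless.

    Requires at least two strictly positive intervals.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be strictly positive")
    return 2.0 * np.diff(rr) / (rr[1:] + rr[:-1])


def geometric_hrv(rr_ms: np.ndarray) -> HRVResult:
    """Robust geometric HRV of an RR sequence (>= 3 intervals).

    Returns the median distance of consecutive relative-RR pairs from the
    pairs' component-wise median, scaled by 100.  NaN when fewer than two
    pairs exist.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        return HRVResult(measure=np.nan, n_pairs=0,
                         relative_rr=np.array([]),
                         poincare=np.empty((0, 2)))
    r = relative_rr(rr)
    pts = np.column_stack([r[:-1], r[1:]])
    center = np.median(pts, axis=0)
    dist = np.sqrt(np.sum((pts - center) ** 2, axis=1))
    return HRVResult(measure=100.0 * float(np.median(dist)),
                     n_pairs=len(pts), relative_rr=r, poincare=pts)


def sliding_hrv(rr_ms: np.ndarray, window: int = 50,
                step: int = 10) -> np.ndarray:
    """Geometric HRV over a sliding window of beats (e.g. for displaying
    the collapse of variability under autonomic blockade)."""
    rr = np.asarray(rr_ms, dtype=float)
    out = []
    for start in range(0, max(1, len(rr) - window + 1), step):
        out.append(geometric_hrv(rr[start : start + window]).measure)
    return np.asarray(out)
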