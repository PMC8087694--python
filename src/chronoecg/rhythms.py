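"""Circadian rhythmometry and longitudinal-profile statistics.

Per-subject pipeline: z-score the per-sweep parameter series across the
full session, average into fixed time bins (default 5 min) with coverage
bookkeeping, then

* :class:`Cosinor` - least-squares fit of a fixed-period (24 h) sinusoid,
  M + A cos(2*pi*(t - phi)/P), with a zero-amplitude F-test;
* :func:`watson_williams` - circular one-way comparison of group
  acrophases;
* :func:`crosscorr_phase` / :func:`cohort_phase_delay` - cross-correlogram
  between two parameter profiles, Gaussian fit to the correlogram peak,
  and a cohort one-sample t-test of the fitted lag means against zero;
* :func:`delta_dependency` - acute coupling curves: changes of one
  z-scored parameter between sequential bins against the concurrent
  change in RR, averaged within dRR magnitude bins;
* :func:`smooth_profile`, :func:`detrend_moving_average`,
  :func:`rr_heatmap` - profile smoothing, 24-h moving-average detrending
  and the time-of-day x RR-interval occupancy heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d


# ---------------------------------------------------------------------------
# Normalisation and binning
# ---------------------------------------------------------------------------

def zscore_session(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score a parameter series across the full session (sample SD).

    Only finite entries contribute to the mean/SD; non-finite entries stay
    NaN.  A zero SD raises.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to z-score")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero standard deviation; series is constant")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


@dataclass
class BinnedSeries:
    """A per-subject, time-binned (z-scored) parameter profile."""

    bin_centers_h: np.ndarray  # hours from session start
    values: np.ndarray         # bin means; NaN for empty bins
    coverage: np.ndarray       # fraction of expected sweeps present per bin
    subject: str = ""
    parameter: str = ""
    bin_width_h: float = 5.0 / 60.0
    excluded: bool = False     # too many empty bins for waveform analysis

    @property
    def nonempty_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.values)))


def bin_series(t_s: np.ndarray, values: np.ndarray,
               width_min: float = 5.0, coverage_min: float = 0.7,
               expected_per_bin: float | None = None,
               subject: str = "", parameter: str = "") -> BinnedSeries:
    """Average a sweep-level series into fixed time bins.

    The subject is flagged ``excluded`` for waveform analyses when the
    fraction of nonempty bins falls below ``coverage_min``.
    """
    if (24 * 60) % width_min != 0:
        raise ValueError("bin width must divide 24 h")
    t = np.asarray(t_s, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    width_s = width_min * 60.0
    n_bins = int(np.ceil((t.max() + 1e-9) / width_s)) if t.size else 0
    idx = np.clip((t / width_s).astype(int), 0, max(n_bins - 1, 0))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    np.add.at(sums, idx[ok], v[ok])
    np.add.at(counts, idx[ok], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if expected_per_bin is None:
        expected_per_bin = max(1.0, float(np.median(counts[counts > 0]))
                               if np.any(counts > 0) else 1.0)
    coverage = np.clip(counts / expected_per_bin, 0.0, 1.0)
    centers = (np.arange(n_bins) + 0.5) * width_s / 3600.0
    series = BinnedSeries(bin_centers_h=centers, values=means,
                          coverage=coverage, subject=subject,
                          parameter=parameter, bin_width_h=width_min / 60.0)
    series.excluded = series.nonempty_fraction < coverage_min
    return series


# ---------------------------------------------------------------------------
# Cosinor
# ---------------------------------------------------------------------------

class Cosinor:
    """Fixed-period cosinor model, M + A cos(2*pi*(t - phi)/period).

    Parameters
    ----------
    values : array
        Observations (NaN entries are dropped).
    times_h : array
        Observation times in hours.
    period : float
        Rhythm period in hours (default 24).

    Examples
    --------
    >>> t = np.arange(0, 48, 0.5)
    >>> y = 1.0 + 0.5 * np.cos(2 * np.pi * (t - 6.0) / 24.0)
    >>> res = Cosinor(y, t).fit()
    >>> round(res.acrophase_h, 6)
    6.0
    """

    def __init__(self, values, times_h, period: float = 24.0):
        v = np.asarray(values, dtype=float)
        t = np.asarray(times_h, dtype=float)
        ok = np.isfinite(v) & np.isfinite(t)
        self.values = v[ok]
        self.times_h = t[ok]
        self.period = float(period)
        if len(self.values) < 8:
            raise ValueError("need at least 8 observations for a cosinor fit")
        # circular phase coverage: period minus the largest phase gap
        phases = np.sort(np.unique(self.times_h % self.period))
        gaps = np.diff(np.concatenate([phases, [phases[0] + self.period]]))
        span = self.period - float(gaps.max())
        if span <= self.period / 2:
            raise ValueError("observations must span more than half a period")

    @classmethod
    def from_binned(cls, binned: BinnedSeries, period: float = 24.0
                    ) -> "Cosinor":
        return cls(binned.values, binned.bin_centers_h, period=period)

    def fit(self) -> "CosinorResults":
        """Ordinary least squares on the harmonic regressors.

        Rhythmicity p-value is the F-test of the two harmonic terms
        against the intercept-only model.
        """
        t = self.times_h
        w = 2 * np.pi / self.period
        X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
        beta, _, rank, _ = np.linalg.lstsq(X, self.values, rcond=None)
        if rank < 3:
            raise ValueError("degenerate design (collinear harmonic terms)")
        fitted = X @ beta
        resid = self.values - fitted
        n = len(self.values)
        rss = float(resid @ resid)
        tss = float(np.sum((self.values - self.values.mean()) ** 2))
        df_resid = n - 3
        if df_resid <= 0:
            raise ValueError("not enough observations")
        if rss <= 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ((tss - rss) / 2.0) / (rss / df_resid)
            p = float(stats.f.sf(f_stat, 2, df_resid))
        mesor, bc, bs = beta
        amplitude = float(np.hypot(bc, bs))
        acrophase = float((np.arctan2(bs, bc) / w) % self.period)
        sigma2 = rss / df_resid
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return CosinorResults(model=self, mesor=float(mesor),
                              amplitude=amplitude, acrophase_h=acrophase,
                              p_rhythm=p, f_stat=float(f_stat),
                              resid_var=sigma2, nobs=n, beta=beta, cov=cov)


@dataclass
class CosinorResults:
    """Cosinor estimates with delta-method uncertainties."""

    model: Cosinor
    mesor: float
    amplitude: float
    acrophase_h: float
    p_rhythm: float
    f_stat: float
    resid_var: float
    nobs: int
    beta: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def bse(self) -> dict:
        """Standard errors for mesor, amplitude and acrophase (h)."""
        se_m = float(np.sqrt(self.cov[0, 0]))
        bc, bs = self.beta[1], self.beta[2]
        a = max(self.amplitude, 1e-12)
        g_amp = np.array([0.0, bc / a, bs / a])
        se_a = float(np.sqrt(g_amp @ self.cov @ g_amp))
        w = 2 * np.pi / self.model.period
        g_phi = np.array([0.0, -bs / a**2, bc / a**2]) / w
        se_phi = float(np.sqrt(g_phi @ self.cov @ g_phi))
        return {"mesor": se_m, "amplitude": se_a, "acrophase_h": se_phi}

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        w = 2 * np.pi / self.model.period
        return self.mesor + self.amplitude * np.cos(w * (t - self.acrophase_h))

    def p_permutation(self, n_perm: int = 1000, seed: int = 0) -> float:
        """Permutation alternative to the zero-amplitude F-test."""
        rng = np.random.default_rng(seed)
        y = self.model.values.copy()
        t = self.model.times_h
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(y)
            res = Cosinor(perm, t, self.model.period).fit()
            if res.f_stat >= self.f_stat:
                count += 1
        return (count + 1) / (n_perm + 1)

    def plot(self, ax=None):
        """Observations with the fitted sinusoid overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.times_h, self.model.values, ".", ms=3,
                alpha=0.5, label="observed")
        grid = np.linspace(self.model.times_h.min(),
                           self.model.times_h.max(), 400)
        ax.plot(grid, self.predict(grid), "-",
                label=f"cosinor (phi={self.acrophase_h:.1f} h)")
        ax.set_xlabel("time (h)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Cosinor fit (period = %.1f h)" % self.model.period,
            "n obs:      %d" % self.nobs,
            "mesor:      %10.4f  (SE %.4f)" % (self.mesor, se["mesor"]),
            "amplitude:  %10.4f  (SE %.4f)" % (self.amplitude,
                                               se["amplitude"]),
            "acrophase:  %10.4f h (SE %.4f)" % (self.acrophase_h,
                                                se["acrophase_h"]),
            "rhythm F:   %10.4f  p = %.4g" % (self.f_stat, self.p_rhythm),
            "resid var:  %10.4f" % self.resid_var,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Circular statistics: Watson-Williams
# ---------------------------------------------------------------------------

def _circ_mean_resultant(angles: np.ndarray) -> tuple[float, float]:
    z = np.exp(1j * angles)
    m = z.mean()
    return float(np.angle(m)), float(np.abs(m))


def _kappa_ml(r: float) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant
    length (standard piecewise approximation)."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


@dataclass
class WatsonWilliamsResult:
    f_stat: float
    df: tuple
    p_value: float
    group_means_h: list
    mean_resultant: float
    reliable: bool


def watson_williams(groups_h: list, period: float = 24.0
                    ) -> WatsonWilliamsResult:
    """Watson-Williams test for equal mean directions across groups.

    Acrophases are given in hours on the period's circle.  The F statistic
    carries the standard concentration correction 1 + 3/(8*kappa); the
    result is flagged unreliable when the pooled mean resultant length is
    below 0.45 (low concentration invalidates the test's assumptions).
    """
    k = len(groups_h)
    if k < 2 or any(len(g) < 2 for g in groups_h):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    w = 2 * np.pi / period
    angles = [np.asarray(g, dtype=float) * w for g in groups_h]
    all_angles = np.concatenate(angles)
    n_total = len(all_angles)
    Rs = []
    means = []
    for a in angles:
        mu, r = _circ_mean_resultant(a)
        Rs.append(r * len(a))
        means.append((mu / w) % period)
    _, r_all = _circ_mean_resultant(all_angles)
    R_total = r_all * n_total
    sum_R = float(np.sum(Rs))
    rw = sum_R / n_total
    kappa = _kappa_ml(rw)
    denom = n_total - sum_R
    if denom <= 0:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = ((n_total - k) / (k - 1)) * (sum_R - R_total) / denom
        f_stat *= (1 + 3 / (8 * kappa))
        p = float(stats.f.sf(f_stat, k - 1, n_total - k))
    return WatsonWilliamsResult(f_stat=float(f_stat),
                                df=(k - 1, n_total - k), p_value=p,
                                group_means_h=means, mean_resultant=rw,
                                reliable=rw >= 0.45)


def circular_mean_h(hours: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of clock hours (wraparound-aware)."""
    w = 2 * np.pi / period
    mu, _ = _circ_mean_resultant(np.asarray(hours, dtype=float) * w)
    return (mu / w) % period


# ---------------------------------------------------------------------------
# Cross-correlogram phase delays
# ---------------------------------------------------------------------------

def crosscorr(a: np.ndarray, b: np.ndarray, bin_h: float,
              max_lag_h: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlogram of two binned series over lags of +/- max_lag_h.

    At lag tau, ``a[t]`` is paired with ``b[t + tau]`` over pairwise
    complete bins, so a positive fitted lag mean means b is delayed
    relative to a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must share the bin grid")
    max_k = int(round(max_lag_h / bin_h))
    lags = np.arange(-max_k, max_k + 1)
    corr = np.full(len(lags), np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            x, y = a[: len(a) - k], b[k:]
        else:
            x, y = a[-k:], b[: len(b) + k]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            corr[i] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return lags * bin_h, corr


def _gauss(x, height, mean, sd, offset):
    return offset + height * np.exp(-0.5 * ((x - mean) / sd) ** 2)


@dataclass
class GaussianLagFit:
    mean_h: float
    sd_h: float
    height: float
    converged: bool


def fit_correlogram_peak(lags_h: np.ndarray, corr: np.ndarray
                         ) -> GaussianLagFit:
    """Gaussian fit to the correlogram, initialised at its argmax.

    When the correlogram has no positive peak a ValueError is raised; on
    optimisation failure the argmax lag is returned, flagged.
    """
    ok = np.isfinite(corr)
    if not np.any(ok) or np.nanmax(corr) <= 0:
        raise ValueError("correlogram has no positive peak")
    lags, c = lags_h[ok], corr[ok]
    i0 = int(np.argmax(c))
    p0 = [c[i0] - c.min(), lags[i0], max(1.0, (lags[-1] - lags[0]) / 8),
          c.min()]
    try:
        popt, _ = optimize.curve_fit(
            _gauss, lags, c, p0=p0,
            bounds=([0.0, lags[0], 1e-3, -2.0],
                    [2.5, lags[-1], lags[-1] - lags[0] + 1e-3, 2.0]),
            maxfev=5000)
        return GaussianLagFit(mean_h=float(popt[1]), sd_h=float(popt[2]),
                              height=float(popt[0]), converged=True)
    except RuntimeError:
        return GaussianLagFit(mean_h=float(lags[i0]), sd_h=np.nan,
                              height=float(c[i0]), converged=False)


@dataclass
class PhaseDelayResult:
    """Cohort phase-delay analysis between two ECG parameters."""

    subject_lags_h: np.ndarray
    subject_fits: list
    t_stat: float
    df: int
    p_value: float
    n_excluded: int = 0


def cohort_phase_delay(pairs: list, bin_h: float,
                       max_lag_h: float = 12.0) -> PhaseDelayResult:
    """Per-subject correlogram lag (Gaussian-fit mean) tested against 0.

    ``pairs`` is a list of (series_a, series_b) per subject on a common
    bin grid.  Subjects whose correlogram lacks a positive peak are
    excluded and counted.
    """
    lags_list, fits = [], []
    n_excl = 0
    for a, b in pairs:
        try:
            lags, corr = crosscorr(a, b, bin_h, max_lag_h)
            fit = fit_correlogram_peak(lags, corr)
        except ValueError:
            n_excl += 1
            continue
        lags_list.append(fit.mean_h)
        fits.append(fit)
    lag_arr = np.asarray(lags_list)
    if len(lag_arr) < 2:
        raise ValueError("need >= 2 subjects with a correlogram peak")
    t_res = stats.ttest_1samp(lag_arr, 0.0)
    return PhaseDelayResult(subject_lags_h=lag_arr, subject_fits=fits,
                            t_stat=float(t_res.statistic),
                            df=len(lag_arr) - 1,
                            p_value=float(t_res.pvalue), n_excluded=n_excl)


# ---------------------------------------------------------------------------
# Acute dependency curves
# ---------------------------------------------------------------------------

@dataclass
class DependencyCurve:
    """Mean change of a parameter within bins of the concurrent dRR."""

    bin_centers: np.ndarray  # z-units of dRR
    mean_delta: np.ndarray
    n_per_bin: np.ndarray
    pairs: np.ndarray = field(repr=False, default=None)  # (dRR, dparam)

    def slope(self) -> tuple[float, float]:
        """Regression slope (and its SE) of dparam on dRR over all
        sequential-bin pairs."""
        d = self.pairs
        res = stats.linregress(d[:, 0], d[:, 1])
        return float(res.slope), float(res.stderr)


def delta_dependency(rr_binned: np.ndarray, other_binned: np.ndarray,
                     bin_width: float = 0.5) -> DependencyCurve:
    """Acute coupling of a parameter to RR between sequential time bins.

    Differences are taken over consecutive *nonempty* bins only (a gap
    skips the pair); dRR values are grouped in bins of ``bin_width``
    z-units (0.25 SD for humans, 0.5 SD for mice) and the concurrent
    parameter changes averaged per bin.
    """
    rr = np.asarray(rr_binned, dtype=float)
    other = np.asarray(other_binned, dtype=float)
    if len(rr) != len(other):
        raise ValueError("series must share the bin grid")
    ok = np.isfinite(rr) & np.isfinite(other)
    consec = ok[1:] & ok[:-1]
    drr = (rr[1:] - rr[:-1])[consec]
    dot = (other[1:] - other[:-1])[consec]
    if drr.size == 0:
        raise ValueError("no consecutive nonempty bin pairs")
    lo = np.floor(drr.min() / bin_width) * bin_width
    hi = np.ceil(drr.max() / bin_width) * bin_width + 1e-9
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx = np.clip(np.digitize(drr, edges) - 1, 0, len(edges) - 2)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mean_delta = np.full(len(centers), np.nan)
    n_per = np.zeros(len(centers), dtype=int)
    for j in range(len(centers)):
        m = idx == j
        n_per[j] = m.sum()
        if n_per[j]:
            mean_delta[j] = dot[m].mean()
    return DependencyCurve(bin_centers=centers, mean_delta=mean_delta,
                           n_per_bin=n_per,
                           pairs=np.column_stack([drr, dot]))


# ---------------------------------------------------------------------------
# Profile smoothing, detrending, heatmaps
# ---------------------------------------------------------------------------

def smooth_profile(subject_profiles: np.ndarray, bin_centers_h: np.ndarray,
                   frac: float = 0.3) -> pd.DataFrame:
    """Locally weighted (LOWESS) smooth of a group-mean profile.

    ``subject_profiles`` is (n_subjects, n_bins).  Returns the smoothed
    group mean and the SEM band from subject-level spread (NaN SEM for a
    single subject).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    profiles = np.atleast_2d(np.asarray(subject_profiles, dtype=float))
    mean = np.nanmean(profiles, axis=0)
    n_sub = profiles.shape[0]
    if n_sub > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            sem = (np.nanstd(profiles, axis=0, ddof=1)
                   / np.sqrt(np.sum(np.isfinite(profiles), axis=0)))
    else:
        sem = np.full_like(mean, np.nan)
    ok = np.isfinite(mean)
    sm = lowess(mean[ok], bin_centers_h[ok], frac=frac, return_sorted=False)
    smoothed = np.full_like(mean, np.nan)
    smoothed[ok] = sm
    return pd.DataFrame({"time_h": bin_centers_h, "mean": mean,
                         "smoothed": smoothed, "sem": sem})


def detrend_moving_average(values: np.ndarray, times_h: np.ndarray,
                           window_h: float = 24.0) -> np.ndarray:
    """Subtract the centred moving average over ``window_h`` hours.

    Edge samples without a full window are returned NaN.  Useful for
    removing slow drift from e.g. bioluminescence traces while leaving
    24-h periodic components intact.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if len(v) < 2:
        raise ValueError("series too short")
    dt = float(np.median(np.diff(t)))
    w = int(round(window_h / dt))
    if w >= len(v):
        raise ValueError("series shorter than the detrending window")
    if w % 2 == 0:
        # centred even-span average: half weights at both endpoints, so a
        # whole-period window annihilates periodic components exactly
        kernel = np.ones(w + 1)
        kernel[0] = kernel[-1] = 0.5
        kernel /= w
        half = w // 2
    else:
        kernel = np.ones(w) / w
        half = w // 2
    ma = np.convolve(v, kernel, mode="same")
    out = v - ma
    out[:half] = np.nan
    out[len(v) - half:] = np.nan
    return out


@dataclass
class RRHeatmap:
    """Time-of-day x RR-interval occupancy probability map."""

    time_edges_h: np.ndarray
    rr_edges_ms: np.ndarray
    prob: np.ndarray  # (n_rr_bins, n_time_bins); columns sum to 1
    smoothed: bool
    empty_columns: np.ndarray

    def plot(self, ax=None, cmap="magma"):
        """Occupancy map with time of day on x and RR interval on y."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(self.time_edges_h, self.rr_edges_ms, self.prob,
                      cmap=cmap, shading="flat")
        ax.set_xlabel("time of day (h)")
        ax.set_ylabel("RR interval (ms)")
        return ax


def rr_heatmap(rr_ms: np.ndarray, t_s: np.ndarray,
               time_bin_min: float = 15.0, rr_bin_ms: float = 1.5,
               smooth_sd_bins: float = 5.0, truncate: float = 3.0,
               rr_range: tuple | None = None,
               smooth: bool = True) -> RRHeatmap:
    """Distribution of RR intervals across the 24-h day.

    RR values are folded onto time-of-day, binned into 15-min x 1.5-ms
    cells and converted column-wise to probabilities.  Optional 2-D
    Gaussian smoothing (kernel SD in bins) uses circular padding on the
    time axis (the day wraps) and reflection on the RR axis; columns are
    renormalised to unit mass afterwards.  Empty columns stay zero and
    are flagged.
    """
    rr = np.asarray(rr_ms, dtype=float)
    tod_h = (np.asarray(t_s, dtype=float) / 3600.0) % 24.0
    ok = np.isfinite(rr) & np.isfinite(tod_h)
    rr, tod_h = rr[ok], tod_h[ok]
    n_time = int(round(24 * 60 / time_bin_min))
    time_edges = np.linspace(0, 24, n_time + 1)
    if rr_range is None:
        lo = np.floor(rr.min() / rr_bin_ms) * rr_bin_ms
        hi = np.ceil(rr.max() / rr_bin_ms) * rr_bin_ms
    else:
        lo, hi = rr_range
    n_rr = max(1, int(round((hi - lo) / rr_bin_ms)))
    rr_edges = lo + np.arange(n_rr + 1) * rr_bin_ms
    hist, _, _ = np.histogram2d(rr, tod_h, bins=[rr_edges, time_edges])
    colsum = hist.sum(axis=0)
    empty = colsum == 0
    prob = np.divide(hist, np.where(colsum == 0, 1.0, colsum)[None, :])
    if smooth:
        prob = gaussian_filter1d(prob, smooth_sd_bins, axis=1, mode="wrap",
                                 truncate=truncate)
        prob = gaussian_filter1d(prob, smooth_sd_bins, axis=0,
                                 mode="reflect", truncate=truncate)
        colsum2 = prob.sum(axis=0)
        prob = np.divide(prob, np.where(colsum2 == 0, 1.0, colsum2)[None, :])
    return RRHeatmap(time_edges_h=time_edges, rr_edges_ms=rr_edges,
                     prob=prob, smoothed=smooth, empty_columns=empty)
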