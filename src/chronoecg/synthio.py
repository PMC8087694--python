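"""Synthetic ECG, behaviour and arrhythmia generator with known ground truth.

The generator emulates two telemetry designs:

* mouse: 10-s ECG sweeps every 5 min with locomotor activity and body
  temperature per 5-min bin, nocturnal activity with an optional late-night
  "siesta", light/dark phase-shift protocols with gradual re-entrainment;
* human: continuous ECG at polysomnography rates, diurnal schedule,
  optional total-sleep-deprivation night.

Interval structure
------------------
Per-sweep RR (ms) follows a 24-h cosinor plus an acute locomotor-activity
effect and Gaussian noise::

    RR(t) = M_RR + A_RR cos(2*pi*(t - phi_RR)/24) + g*activity(t) + eps

QT and the PR segment carry their own cosinor terms; their *acute*
deviations are coupled to RR on the standardized scale: the dimensionless
coupling ``c`` is the regression slope of standardized parameter deviations
on standardized RR deviations (``dev = sd * (c*z_RR + sqrt(1-c^2)*eta)``).
Defining the coupling on the z-scale makes it directly recoverable by the
z-scored dependency analyses downstream, for any noise level.

Waveform morphology
-------------------
Each wave (P, Q, R, S, T) is a raised-cosine (Hann) bump with compact
support.  Unlike a Gaussian, a Hann bump returns *exactly* to the
isoelectric line at its support edge, so wave offsets defined through
"returns to the isoelectric line" / "first deflection" rules are exact to
one sample on clean traces.  The mouse T wave is rendered inverted
(negative), the human T wave upright.  Fiducial annotations are snapped to
the sample grid so that annotated interval differences reproduce the true
intervals exactly at the rendering rate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ActivityTrace, EcgTrace, Sweep

__all__ = [
    "CircadianParams",
    "WaveSpec",
    "MorphologyProfile",
    "ScheduleSpec",
    "GroundTruthRecord",
    "SynthRecording",
    "synth_behavior",
    "synth_beat_train",
    "synth_arrhythmia_episode",
    "synth_ecg_waveform",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CircadianParams:
    """Cosinor parameters (ms) of the interval generator.

    ``*_acrophase`` are in hours ZT on [0, 24); the rhythm period is fixed
    at 24 h.  ``coupling_*_rr`` are dimensionless standardized regression
    slopes of acute parameter deviations on acute RR deviations.
    ``activity_gain`` is in ms per activity count (negative values shorten
    RR during activity).  ``noise_sd_*`` set the sweep-level deviation SD;
    ``*_jitter_sd`` the additional beat-to-beat SD within a sweep.
    """

    rr_mesor: float = 100.0
    rr_amplitude: float = 7.0
    rr_acrophase: float = 6.0
    qt_mesor: float = 45.0
    qt_amplitude: float = 0.0
    qt_acrophase: float = 6.0
    pr_mesor: float = 15.0
    pr_amplitude: float = 1.5
    pr_acrophase: float = 7.5
    period: float = 24.0
    coupling_qt_rr: float = 0.8
    coupling_pr_rr: float = 0.0
    activity_gain: float = -0.25
    activity_tau_min: float = 0.0  # exponential decay of the activity
    #                                effect; 0 = instantaneous only
    noise_sd_rr: float = 2.0
    noise_sd_qt: float = 2.5
    noise_sd_pr: float = 0.5
    rr_jitter_sd: float = 1.5
    qt_jitter_sd: float = 0.4
    pr_jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("rr_amplitude", "qt_amplitude", "pr_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rr_acrophase", "qt_acrophase", "pr_acrophase"):
            v = getattr(self, name)
            if not 0 <= v < 24:
                raise ValueError(f"{name} must lie in [0, 24)")
        if self.period != 24.0:
            raise ValueError("period is fixed at 24 h")

    @classmethod
    def mouse(cls, **kw) -> "CircadianParams":
        return cls(**kw)

    @classmethod
    def human(cls, **kw) -> "CircadianParams":
        defaults = dict(
            rr_mesor=900.0, rr_amplitude=60.0, rr_acrophase=22.0,
            qt_mesor=380.0, qt_acrophase=22.0,
            pr_mesor=55.0, pr_amplitude=6.0, pr_acrophase=23.5,
            activity_gain=-2.0, noise_sd_rr=20.0, noise_sd_qt=10.0,
            noise_sd_pr=2.0, rr_jitter_sd=25.0, qt_jitter_sd=4.0,
            pr_jitter_sd=1.5,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class WaveSpec:
    """One ECG wave: a raised-cosine bump of ``amplitude`` mV whose compact
    support spans ``center +/- halfwidth_ms``."""

    amplitude: float
    halfwidth_ms: float


@dataclass
class MorphologyProfile:
    """Species-specific wave shapes; T amplitude is negative for the mouse."""

    species: str
    p: WaveSpec
    q: WaveSpec
    r: WaveSpec
    s: WaveSpec
    t: WaveSpec
    q_offset_ms: float  # Q bump center relative to the R peak (negative)
    s_offset_ms: float
    baseline_wander_amp: float = 0.0  # mV
    baseline_wander_period_s: float = 4.0
    white_noise_sd: float = 0.0  # mV
    vpc_widen_factor: float = 2.0
    vpc_polarities: tuple = (-1.0,)  # VT: constant inverted
    bvt_polarities: tuple = (-1.0, 0.35)  # BVT: alternating sign

    def __post_init__(self) -> None:
        others = [abs(w.amplitude) for w in (self.p, self.q, self.s, self.t)]
        if not abs(self.r.amplitude) > max(others):
            raise ValueError("R amplitude must dominate all other waves")
        if self.species == "mouse" and self.t.amplitude >= 0:
            raise ValueError("mouse T wave amplitude must be negative")
        if self.species == "human" and self.t.amplitude <= 0:
            raise ValueError("human T wave amplitude must be positive")

    @classmethod
    def mouse(cls, noise_sd: float = 0.05, wander: float = 0.03,
              **kw) -> "MorphologyProfile":
        defaults = dict(
            species="mouse",
            p=WaveSpec(0.15, 6.0),
            q=WaveSpec(-0.2, 3.0),
            r=WaveSpec(1.0, 4.0),
            s=WaveSpec(0.0, 3.0),
            t=WaveSpec(-0.3, 10.0),
            q_offset_ms=-4.0,
            s_offset_ms=5.0,
            baseline_wander_amp=wander,
            white_noise_sd=noise_sd,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def human(cls, noise_sd: float = 0.02, wander: float = 0.03,
              **kw) -> "MorphologyProfile":
        defaults = dict(
            species="human",
            p=WaveSpec(0.15, 50.0),
            q=WaveSpec(-0.15, 20.0),
            r=WaveSpec(1.2, 25.0),
            s=WaveSpec(-0.2, 15.0),
            t=WaveSpec(0.35, 80.0),
            q_offset_ms=-35.0,
            s_offset_ms=32.0,
            baseline_wander_amp=wander,
            white_noise_sd=noise_sd,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class ScheduleSpec:
    """Recording schedule: lighting, sweep cadence and protocol events.

    ``shift_hours > 0`` is an advance of the light/dark cycle (lights-on
    moves earlier) applied at the start of ``phase_shift_day`` (0-based);
    behaviour re-entrains at ``reentrain_rate_h_per_day``.
    """

    days: float = 5.0
    lights_on: float = 0.0
    lights_off: float = 12.0
    nocturnal: bool = True
    phase_shift_day: int | None = None
    shift_hours: float = 0.0
    siesta_window: tuple | None = None  # ZT hours, e.g. (18, 20)
    sleep_deprivation_day: int | None = None
    sweep_cadence_s: float | None = 300.0  # None -> continuous recording
    sweep_len_s: float = 10.0
    reentrain_rate_h_per_day: float = 1.5

    def __post_init__(self) -> None:
        if not (-12.0 < self.shift_hours <= 12.0):
            raise ValueError("shift_hours must lie in (-12, 12]")
        for name in ("lights_on", "lights_off"):
            if not 0 <= getattr(self, name) < 24:
                raise ValueError(f"{name} must lie in [0, 24)")
        if self.siesta_window is not None:
            lo, hi = self.siesta_window
            if not (0 <= lo < hi <= 24):
                raise ValueError("siesta_window must lie within 0-24 h")

    @classmethod
    def mouse(cls, **kw) -> "ScheduleSpec":
        defaults = dict(days=5.0, siesta_window=(18.0, 20.0))
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def human(cls, days: float = 4.0, **kw) -> "ScheduleSpec":
        defaults = dict(days=days, nocturnal=False, lights_on=8.0,
                        lights_off=23.0, siesta_window=None,
                        sweep_cadence_s=None)
        defaults.update(kw)
        return cls(**defaults)

    def internal_phase_advance(self, t_s: np.ndarray) -> np.ndarray:
        """Hours by which the internal (behavioural) clock has advanced at
        time ``t_s``, ramping from 0 toward ``shift_hours`` after the shift
        day at the configured re-entrainment rate."""
        t_day = np.asarray(t_s, dtype=float) / 86400.0
        if self.phase_shift_day is None or self.shift_hours == 0:
            return np.zeros_like(t_day)
        ramp = self.reentrain_rate_h_per_day * (t_day - self.phase_shift_day)
        sign = np.sign(self.shift_hours)
        return sign * np.clip(ramp, 0.0, abs(self.shift_hours))

    def internal_zt(self, t_s: np.ndarray) -> np.ndarray:
        """Internal zeitgeber time (h) driving behaviour and physiology."""
        t_h = np.asarray(t_s, dtype=float) / 3600.0
        return (t_h - self.lights_on + self.internal_phase_advance(t_s)) % 24.0


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthRecord:
    """True beat times, intervals, labels and episode annotations."""

    species: str
    beat_times: np.ndarray  # s, absolute
    rr_ms: np.ndarray  # interval to next beat within the sweep (NaN at ends)
    pr_ms: np.ndarray
    qt_ms: np.ndarray
    labels: np.ndarray  # 'normal' | 'vpc'
    sweep_id: np.ndarray
    sweep_t0: np.ndarray
    sweep_params: pd.DataFrame  # per-sweep t0_s, rr/pr/qt level, activity
    episodes: list = field(default_factory=list)  # (start, end, kind, dur_s)
    qrs_polarity: np.ndarray | None = None
    qrs_widen: np.ndarray | None = None
    activity: ActivityTrace | None = None
    schedule: ScheduleSpec | None = None
    circadian: CircadianParams | None = None
    n_resampled: int = 0

    def __post_init__(self) -> None:
        if self.qrs_polarity is None:
            self.qrs_polarity = np.ones(len(self.beat_times))
        if self.qrs_widen is None:
            self.qrs_widen = np.ones(len(self.beat_times))
        for arr in (self.rr_ms, self.pr_ms, self.qt_ms):
            finite = arr[np.isfinite(arr)]
            if np.any(finite <= 0):
                raise ValueError("interval series must be strictly positive")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)


@dataclass
class SynthRecording:
    """Rendered sweeps plus sample-accurate fiducial annotations."""

    sweeps: list
    fs: float
    annotations: pd.DataFrame
    truth: GroundTruthRecord


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def synth_behavior(sched: ScheduleSpec, seed: int,
                   rate_active: float = 25.0, rate_rest_bout: float = 8.0,
                   temp_mean: float = 36.5, temp_amp: float = 0.8,
                   temp_noise: float = 0.08) -> ActivityTrace:
    """Generate locomotor activity counts and body temperature per 5-min bin.

    Activity alternates between moving and quiescent states via a
    two-state Markov chain whose transition rates depend on circadian
    phase: long movement bouts with brief naps in the behavioural active
    phase (dark for a nocturnal species), short sporadic bouts amid long
    immobility in the rest phase and during the siesta window.  Quiescent
    bins carry exactly zero counts; moving bins draw Poisson counts at
    the phase-appropriate rate.  After a light/dark shift the behavioural
    phase re-entrains gradually and temperature phase-locks to the
    re-entraining component.
    """
    rng = np.random.default_rng(seed)
    bin_s = 300.0
    n_bins = int(round(sched.days * 86400.0 / bin_s))
    t0 = np.arange(n_bins) * bin_s
    zt = sched.internal_zt(t0 + bin_s / 2.0)

    dark = (zt >= 12.0) & (zt < 24.0)
    active_phase = dark if sched.nocturnal else ~dark
    if sched.siesta_window is not None:
        lo, hi = sched.siesta_window
        active_phase = active_phase & ~((zt >= lo) & (zt < hi))
    if sched.sleep_deprivation_day is not None:
        day = np.floor(t0 / 86400.0).astype(int)
        active_phase = active_phase | (day == sched.sleep_deprivation_day)

    # (P(move -> quiet), P(quiet -> move)) per behavioural phase
    p_enter_quiet = np.where(active_phase, 0.02, 0.45)
    p_exit_quiet = np.where(active_phase, 0.15, 0.10)
    lam = np.where(active_phase, rate_active, rate_rest_bout)

    counts = np.zeros(n_bins)
    moving = bool(active_phase[0])
    u = rng.uniform(size=n_bins)
    for i in range(n_bins):
        if moving:
            counts[i] = max(1.0, rng.poisson(lam[i]))
            moving = u[i] >= p_enter_quiet[i]
        else:
            counts[i] = 0.0
            moving = u[i] < p_exit_quiet[i]

    temp_phase = 18.0 if sched.nocturnal else 16.0
    temperature = (temp_mean
                   + temp_amp * np.cos(2 * np.pi * (zt - temp_phase) / 24.0)
                   + rng.normal(0.0, temp_noise, n_bins))
    return ActivityTrace(t0=t0, counts=counts, bin_s=bin_s,
                         temperature=temperature)


# ---------------------------------------------------------------------------
# Beat trains
# ---------------------------------------------------------------------------

def _cos24(t_h, mesor, amp, acro):
    return mesor + amp * np.cos(2 * np.pi * (np.asarray(t_h) - acro) / 24.0)


# rendering feasibility margins (ms): PR + P wave + isoelectric gap + QRS
_MARGIN_MS = {"mouse": 30.0, "human": 180.0}
_EDGE_MS = {"mouse": 60.0, "human": 800.0}


def synth_beat_train(circ: CircadianParams, sched: ScheduleSpec,
                     activity: ActivityTrace | None = None,
                     seed: int = 0, species: str = "mouse"
                     ) -> GroundTruthRecord:
    """Generate per-sweep interval levels and per-beat ground truth.

    Beat times accumulate from per-beat RR draws inside each scheduled
    sweep.  Non-positive interval draws are resampled (counted); more than
    1% resampling aborts.  Per-beat QT is clamped so that the full PQRST
    morphology fits inside the beat (clamps are counted in
    ``sweep_params.attrs['n_qt_clamped']``).
    """
    rng = np.random.default_rng(seed)
    cadence = sched.sweep_cadence_s or sched.sweep_len_s
    n_sweeps = int(round(sched.days * 86400.0 / cadence))
    sweep_t0 = np.arange(n_sweeps) * cadence
    t_mid_h = (sweep_t0 + sched.sweep_len_s / 2.0) / 3600.0
    zt = sched.internal_zt(sweep_t0 + sched.sweep_len_s / 2.0)

    if activity is not None:
        counts = activity.counts
        if circ.activity_tau_min > 0:
            from scipy.signal import lfilter
            alpha = np.exp(-(activity.bin_s / 60.0) / circ.activity_tau_min)
            counts = lfilter([1.0], [1.0, -alpha], counts)
        idx = np.clip((sweep_t0 // activity.bin_s).astype(int),
                      0, len(counts) - 1)
        act = counts[idx]
    else:
        act = np.zeros(n_sweeps)

    n_resampled = 0

    def _draw_pos(mean, sd, size=None):
        nonlocal n_resampled
        x = rng.normal(mean, sd, size)
        bad = x <= 0
        rounds = 0
        while np.any(bad):
            n_resampled += int(np.sum(bad))
            rounds += 1
            if rounds > 50:
                raise ValueError(
                    f"interval draws around mean {np.min(mean):.3g} ms keep "
                    f"coming out non-positive ({n_resampled} resampled); "
                    "parameters are unphysiological")
            x = np.where(bad, rng.normal(mean, sd, np.shape(x)), x)
            bad = x <= 0
        return x

    rr_sweep = (_cos24(zt, circ.rr_mesor, circ.rr_amplitude, circ.rr_acrophase)
                + circ.activity_gain * act
                + rng.normal(0.0, circ.noise_sd_rr, n_sweeps))
    dev = rr_sweep - rr_sweep.mean()
    sd = dev.std()
    z_rr = dev / sd if sd > 0 else np.zeros(n_sweeps)

    def _coupled(mesor, amp, acro, c, noise_sd):
        eta = rng.standard_normal(n_sweeps)
        return (_cos24(zt, mesor, amp, acro)
                + noise_sd * (c * z_rr + np.sqrt(max(0.0, 1 - c * c)) * eta))

    qt_sweep = _coupled(circ.qt_mesor, circ.qt_amplitude, circ.qt_acrophase,
                        circ.coupling_qt_rr, circ.noise_sd_qt)
    pr_sweep = _coupled(circ.pr_mesor, circ.pr_amplitude, circ.pr_acrophase,
                        circ.coupling_pr_rr, circ.noise_sd_pr)

    margin = _MARGIN_MS[species]
    edge = _EDGE_MS[species] / 1000.0
    beat_times, rr_l, pr_l, qt_l, swid = [], [], [], [], []
    n_clamped = 0
    total_draws = 0
    for k in range(n_sweeps):
        t = sweep_t0[k] + edge
        t_end = sweep_t0[k] + sched.sweep_len_s - edge
        times_k = []
        while t <= t_end:
            times_k.append(t)
            rr_b = float(_draw_pos(rr_sweep[k], circ.rr_jitter_sd))
            total_draws += 1
            t = t + rr_b / 1000.0
        nk = len(times_k)
        if nk == 0:
            continue
        times_k = np.asarray(times_k)
        rr_b = np.empty(nk)
        rr_b[:-1] = np.diff(times_k) * 1000.0
        rr_b[-1] = np.nan
        pr_b = _draw_pos(pr_sweep[k], circ.pr_jitter_sd, nk)
        qt_b = _draw_pos(qt_sweep[k], circ.qt_jitter_sd, nk)
        total_draws += 2 * nk
        # clamp QT so the T wave ends before the next beat's P wave
        limit = np.where(np.isfinite(rr_b), rr_b - pr_b - margin, np.inf)
        over = qt_b > limit
        n_clamped += int(np.sum(over))
        qt_b = np.minimum(qt_b, limit)
        if np.any(qt_b <= 0):
            raise ValueError(
                f"sweep {k}: RR too short to fit morphology (QT clamp <= 0)")
        beat_times.append(times_k)
        rr_l.append(rr_b)
        pr_l.append(pr_b)
        qt_l.append(qt_b)
        swid.append(np.full(nk, k))

    if total_draws and n_resampled > 0.01 * total_draws:
        raise ValueError(
            f"{n_resampled} of {total_draws} interval draws were non-positive "
            "and resampled (>1%); parameters are unphysiological")

    beat_times = np.concatenate(beat_times)
    sweep_params = pd.DataFrame({
        "sweep_id": np.arange(n_sweeps), "t0_s": sweep_t0,
        "zt_h": zt, "t_mid_h": t_mid_h,
        "rr_ms": rr_sweep, "pr_ms": pr_sweep, "qt_ms": qt_sweep,
        "activity": act,
    })
    sweep_params.attrs["n_qt_clamped"] = n_clamped
    n = len(beat_times)
    return GroundTruthRecord(
        species=species,
        beat_times=beat_times,
        rr_ms=np.concatenate(rr_l),
        pr_ms=np.concatenate(pr_l),
        qt_ms=np.concatenate(qt_l),
        labels=np.array(["normal"] * n, dtype=object),
        sweep_id=np.concatenate(swid).astype(int),
        sweep_t0=sweep_t0,
        sweep_params=sweep_params,
        activity=activity,
        schedule=sched,
        circadian=circ,
        n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# Arrhythmia injection
# ---------------------------------------------------------------------------

def synth_arrhythmia_episode(base: GroundTruthRecord, kind: str,
                             run_length: int, seed: int = 0,
                             sweep: int | None = None,
                             rr_factor: float = 0.6) -> GroundTruthRecord:
    """Insert a run of labeled ventricular premature complexes.

    The run shortens RR by ``rr_factor`` (tachycardia); BVT runs alternate
    QRS polarity beat-to-beat, VT runs keep a constant inverted polarity;
    both widen the QRS (rendered by :func:`synth_ecg_waveform`).  Runs of
    at least four beats are annotated as episodes of the given kind;
    shorter runs leave labeled VPCs without an episode annotation.
    """
    if kind not in {"VT", "BVT"}:
        raise ValueError("kind must be 'VT' or 'BVT'")
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    rng = np.random.default_rng(seed)
    rec = copy.deepcopy(base)

    candidates = [k for k in np.unique(rec.sweep_id)
                  if np.sum(rec.sweep_id == k) >= run_length + 2]
    if not candidates:
        raise ValueError("no sweep long enough to host the episode")
    k = sweep if sweep is not None else int(rng.choice(candidates))
    idx = np.flatnonzero(rec.sweep_id == k)
    if len(idx) < run_length + 2:
        raise ValueError(f"sweep {k} has too few beats for run_length")
    start_off = int(rng.integers(1, len(idx) - run_length))
    run = idx[start_off : start_off + run_length]

    # compress the run in time (premature beats) and shift later beats
    for j, b in enumerate(run):
        prev = b - 1
        new_rr = rec.rr_ms[prev] * rr_factor
        shift = (rec.rr_ms[prev] - new_rr) / 1000.0
        rec.rr_ms[prev] = new_rr
        rec.beat_times[b : idx[-1] + 1] -= shift

    rec.labels[run] = "vpc"
    rec.pr_ms[run] = np.nan
    rec.qt_ms[run] = np.nan
    pol = MorphologyProfile.mouse().bvt_polarities if kind == "BVT" \
        else MorphologyProfile.mouse().vpc_polarities
    for j, b in enumerate(run):
        rec.qrs_polarity[b] = pol[j % len(pol)]
        rec.qrs_widen[b] = MorphologyProfile.mouse().vpc_widen_factor
    if run_length >= 4:
        dur = float(rec.beat_times[run[-1]] - rec.beat_times[run[0]])
        rec.episodes.append((int(run[0]), int(run[-1]), kind, dur))
    return rec


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------

def _hann_bump(t_grid: np.ndarray, center: float, amp: float,
               hw_s: float) -> np.ndarray:
    """Raised-cosine bump, exactly zero outside ``center +/- hw_s``."""
    u = (t_grid - center) / hw_s
    out = np.zeros_like(t_grid)
    m = np.abs(u) < 1.0
    out[m] = amp * 0.5 * (1.0 + np.cos(np.pi * u[m]))
    return out


def _qrs_trough_offset(morph: MorphologyProfile) -> float:
    """Continuous-time offset (s) of the Q trough relative to the R peak.

    The Q bump overlaps the R upstroke, so the trough of the summed complex
    is located numerically on a fine grid.
    """
    lo = (morph.q_offset_ms - morph.q.halfwidth_ms) / 1000.0
    hi = 0.0
    t = np.arange(lo, hi, 1e-5)
    y = (_hann_bump(t, morph.q_offset_ms / 1000.0, morph.q.amplitude,
                    morph.q.halfwidth_ms / 1000.0)
         + _hann_bump(t, 0.0, morph.r.amplitude, morph.r.halfwidth_ms / 1000.0))
    return float(t[np.argmin(y)])


_MIN_FS = {"mouse": 500.0, "human": 128.0}


def synth_ecg_waveform(truth: GroundTruthRecord, morph: MorphologyProfile,
                       fs: float, seed: int = 0,
                       artifact_prob: float = 0.0,
                       missing_prob: float = 0.0) -> SynthRecording:
    """Render ECG sweeps from a beat train with sample-accurate annotations.

    Normal beats place the P/Q/R/S/T bumps so that the annotated
    P offset, Q onset (species convention), T peak and T offset reproduce
    the true PR segment and QT interval exactly on the sample grid; white
    noise and baseline wander are added last.  Ventricular premature beats
    are rendered as a widened QRS bump with the recorded (possibly
    alternating) polarity, without P or T waves.

    ``artifact_prob``/``missing_prob`` emulate telemetry dropouts: an
    artifactual sweep receives a large stationary noise burst (it should
    fail quality control downstream); a missing sweep is not emitted.
    """
    if fs < _MIN_FS[truth.species]:
        raise ValueError(
            f"fs {fs} below minimum {_MIN_FS[truth.species]} for "
            f"{truth.species}")
    rng = np.random.default_rng(seed)
    sched = truth.schedule
    sweep_len = int(round(sched.sweep_len_s * fs))
    p_hw = morph.p.halfwidth_ms / 1000.0
    t_hw = morph.t.halfwidth_ms / 1000.0
    dq = _qrs_trough_offset(morph)  # mouse Q-onset convention (trough)
    q_edge = (morph.q_offset_ms - morph.q.halfwidth_ms) / 1000.0  # human

    rows = []
    sweeps = []
    for k_pos, k in enumerate(np.unique(truth.sweep_id)):
        if missing_prob > 0 and rng.uniform() < missing_prob:
            continue
        artifact = artifact_prob > 0 and rng.uniform() < artifact_prob
        sel = np.flatnonzero(truth.sweep_id == k)
        t0 = truth.sweep_t0[k]
        grid = t0 + np.arange(sweep_len) / fs
        x = np.zeros(sweep_len)
        prev_toff = -np.inf
        for b in sel:
            r_s = int(round((truth.beat_times[b] - t0) * fs))
            r_time = t0 + r_s / fs
            if truth.labels[b] == "vpc":
                amp = morph.r.amplitude * truth.qrs_polarity[b]
                hw = (morph.r.halfwidth_ms / 1000.0) * truth.qrs_widen[b]
                x += _hann_bump(grid, r_time, amp, hw)
                rows.append((b, int(k), truth.beat_times[b], "vpc",
                             -1, -1, -1, r_s, -1, -1))
                prev_toff = r_time + hw
                continue
            pr = truth.pr_ms[b]
            qt = truth.qt_ms[b]
            if truth.species == "mouse":
                qon_s = r_s + int(round(dq * fs))
            else:
                qon_s = r_s + int(round(q_edge * fs))
            poff_s = qon_s - int(round(pr * fs / 1000.0))
            toff_s = qon_s + int(round(qt * fs / 1000.0))
            p_center = t0 + poff_s / fs - p_hw
            t_center = t0 + toff_s / fs - t_hw
            if p_center - p_hw < prev_toff - 1e-9:
                raise ValueError(
                    f"beat {b}: interval too short to fit morphology "
                    "(P wave overlaps previous T wave)")
            if p_center - p_hw < t0 or t_center + t_hw > t0 + sched.sweep_len_s:
                raise ValueError(
                    f"beat {b}: morphology extends past the sweep edge")
            x += _hann_bump(grid, p_center, morph.p.amplitude, p_hw)
            x += _hann_bump(grid, r_time + morph.q_offset_ms / 1000.0,
                            morph.q.amplitude, morph.q.halfwidth_ms / 1000.0)
            x += _hann_bump(grid, r_time, morph.r.amplitude,
                            morph.r.halfwidth_ms / 1000.0)
            if morph.s.amplitude != 0.0:
                x += _hann_bump(grid, r_time + morph.s_offset_ms / 1000.0,
                                morph.s.amplitude,
                                morph.s.halfwidth_ms / 1000.0)
            x += _hann_bump(grid, t_center, morph.t.amplitude, t_hw)
            p_peak_s = int(round((p_center - t0) * fs))
            t_peak_s = int(round((t_center - t0) * fs))
            rows.append((b, int(k), truth.beat_times[b], "normal",
                         p_peak_s, poff_s, qon_s, r_s, t_peak_s, toff_s))
            prev_toff = t_center + t_hw
        if morph.baseline_wander_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += morph.baseline_wander_amp * np.sin(
                2 * np.pi * (grid - t0) / morph.baseline_wander_period_s
                + phase)
        if morph.white_noise_sd > 0:
            x += rng.normal(0.0, morph.white_noise_sd, sweep_len)
        if artifact:
            x += rng.normal(0.0, 8.0 * morph.white_noise_sd + 0.05,
                            sweep_len)
        sweeps.append(Sweep(samples=x, fs=fs, t0=float(t0),
                            species=truth.species, sweep_id=int(k)))

    ann = pd.DataFrame(
        rows, columns=["beat", "sweep_id", "beat_time_s", "label",
                       "P", "Poff", "Qon", "R", "Tpk", "Toff"])
    return SynthRecording(sweeps=sweeps, fs=fs, annotations=ann, truth=truth)
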