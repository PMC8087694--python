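"""Generator contracts: intervals, morphology, behaviour, arrhythmia."""

import numpy as np
import pytest

import chronoecg as ce
from chronoecg.rhythms import Cosinor


def _flat_params(**kw):
    base = dict(rr_amplitude=0.0, qt_amplitude=0.0, pr_amplitude=0.0,
                noise_sd_rr=0.0, noise_sd_qt=0.0, noise_sd_pr=0.0,
                rr_jitter_sd=1e-12, qt_jitter_sd=1e-12, pr_jitter_sd=1e-12,
                activity_gain=0.0)
    base.update(kw)
    return ce.CircadianParams.mouse(**base)


def test_constant_case_rr_exact():
    """Zero amplitude and zero noise give a constant 100 ms RR train."""
    truth = ce.synth_beat_train(_flat_params(), ce.ScheduleSpec.mouse(days=0.01),
                                None, seed=0)
    rr = truth.rr_ms[np.isfinite(truth.rr_ms)]
    assert np.allclose(rr, 100.0, atol=1e-6)


def test_five_day_cadence_emits_1440_sweeps():
    sched = ce.ScheduleSpec.mouse(days=5)
    truth = ce.synth_beat_train(_flat_params(), sched, None, seed=0)
    assert len(truth.sweep_t0) == 1440  # 5 days x 24 h x 12 per hour


def test_seed_determinism():
    sched = ce.ScheduleSpec.mouse(days=0.02)
    circ = ce.CircadianParams.mouse()
    act = ce.synth_behavior(sched, seed=7)
    a = ce.synth_beat_train(circ, sched, act, seed=9)
    b = ce.synth_beat_train(circ, sched, act, seed=9)
    assert np.array_equal(a.beat_times, b.beat_times)
    assert np.array_equal(a.qt_ms, b.qt_ms, equal_nan=True)
    ra = ce.synth_ecg_waveform(a, ce.MorphologyProfile.mouse(), 1000.0, seed=3)
    rb = ce.synth_ecg_waveform(b, ce.MorphologyProfile.mouse(), 1000.0, seed=3)
    for sa, sb in zip(ra.sweeps, rb.sweeps):
        assert np.array_equal(sa.samples, sb.samples)


def test_nonpositive_draw_rate_aborts():
    circ = ce.CircadianParams.mouse(noise_sd_qt=50.0)  # QT often drawn <= 0
    with pytest.raises(ValueError, match="resampled"):
        ce.synth_beat_train(circ, ce.ScheduleSpec.mouse(days=0.05), None,
                            seed=1)


def test_pr_phase_offset_recovered_by_lagged_correlation():
    """PR acrophase 1.5 h after RR's shows up as a +1.5 h correlogram peak.

    Oracle: brute-force lagged Pearson correlation over all 5-min shifts.
    """
    circ = ce.CircadianParams.mouse(
        rr_acrophase=6.0, pr_acrophase=7.5, noise_sd_rr=0.0,
        noise_sd_qt=0.0, noise_sd_pr=0.0, activity_gain=0.0)
    truth = ce.synth_beat_train(circ, ce.ScheduleSpec.mouse(days=3), None,
                                seed=2)
    rr = truth.sweep_params["rr_ms"].to_numpy()
    pr = truth.sweep_params["pr_ms"].to_numpy()
    best_lag, best_c = None, -np.inf
    for k in range(-48, 49):  # +/- 4 h in 5-min steps
        if k >= 0:
            c = np.corrcoef(rr[: len(rr) - k or None], pr[k:])[0, 1]
        else:
            c = np.corrcoef(rr[-k:], pr[:k])[0, 1]
        if c > best_c:
            best_lag, best_c = k, c
    assert best_lag * 5.0 / 60.0 == pytest.approx(1.5, abs=1.0 / 12.0)


def test_interval_conservation_in_annotations(mouse_clean):
    """Annotated landmark differences reproduce true intervals to 1 sample."""
    ann = mouse_clean.annotations
    tr = mouse_clean.truth
    b = ann.beat.to_numpy()
    pr_ann = (ann.Qon - ann.Poff).to_numpy(dtype=float)  # samples at 1 kHz
    qt_ann = (ann.Toff - ann.Qon).to_numpy(dtype=float)
    assert np.all(np.abs(pr_ann - tr.pr_ms[b]) <= 1.0)
    assert np.all(np.abs(qt_ann - tr.qt_ms[b]) <= 1.0)
    # RR between consecutive annotated R samples within a sweep
    for sid, grp in ann.groupby("sweep_id"):
        rr_ann = np.diff(grp.R.to_numpy())
        rr_true = tr.rr_ms[grp.beat.to_numpy()[:-1]]
        assert np.all(np.abs(rr_ann - rr_true) <= 1.0)


def test_r_annotation_is_trace_argmax(mouse_clean):
    sw = mouse_clean.sweeps[0]
    ann = mouse_clean.annotations
    a = ann[ann.sweep_id == sw.sweep_id]
    for r in a.R.to_numpy(dtype=int)[:5]:
        lo = r - 25  # clear of the neighbouring beats
        assert lo + np.argmax(sw.samples[lo : r + 25]) == r


def test_mouse_t_peak_is_local_minimum(mouse_clean):
    sw = mouse_clean.sweeps[0]
    a = mouse_clean.annotations
    a = a[a.sweep_id == sw.sweep_id]
    for tpk in a.Tpk.to_numpy(dtype=int)[:10]:
        x = sw.samples
        assert x[tpk] <= x[tpk - 1] and x[tpk] <= x[tpk + 1]
        assert x[tpk] < 0  # inverted T


def test_human_t_amplitude_positive(human_clean):
    sw = human_clean.sweeps[0]
    a = human_clean.annotations
    a = a[a.sweep_id == sw.sweep_id]
    tpk = a.Tpk.to_numpy(dtype=int)
    assert np.all(sw.samples[tpk] > 0)


def test_qt_annotation_difference_matches_requested():
    """A 50 ms QT at 1 kHz spans exactly 50 samples in the annotation."""
    circ = _flat_params(qt_mesor=50.0)
    truth = ce.synth_beat_train(circ, ce.ScheduleSpec.mouse(days=0.01),
                                None, seed=4)
    rec = ce.synth_ecg_waveform(
        truth, ce.MorphologyProfile.mouse(noise_sd=0.0, wander=0.0),
        fs=1000.0, seed=5)
    ann = rec.annotations
    assert np.all((ann.Toff - ann.Qon).to_numpy() == 50)


def test_min_sampling_rate_enforced():
    truth = ce.synth_beat_train(_flat_params(), ce.ScheduleSpec.mouse(days=0.01),
                                None, seed=0)
    with pytest.raises(ValueError, match="fs"):
        ce.synth_ecg_waveform(truth, ce.MorphologyProfile.mouse(), 250.0)


def test_morphology_invariants():
    with pytest.raises(ValueError, match="T wave"):
        ce.MorphologyProfile.mouse(t=ce.synthio.WaveSpec(0.3, 10.0))
    with pytest.raises(ValueError, match="R amplitude"):
        ce.MorphologyProfile.mouse(r=ce.synthio.WaveSpec(0.1, 4.0))


def test_circadian_recoverability_grid_oracle():
    """Per-day acrophase recovered within 0.5 h by a brute-force grid fit
    on the true per-sweep RR (noise SD 10% of amplitude)."""
    circ = ce.CircadianParams.mouse(rr_amplitude=7.0, noise_sd_rr=0.7,
                                    activity_gain=0.0)
    truth = ce.synth_beat_train(circ, ce.ScheduleSpec.mouse(days=3), None,
                                seed=6)
    sp = truth.sweep_params
    for day in range(3):
        sel = (sp.t0_s >= day * 86400) & (sp.t0_s < (day + 1) * 86400)
        t = sp.t0_s[sel].to_numpy() / 3600.0
        y = sp.rr_ms[sel].to_numpy()
        # grid search over acrophase at fixed period
        phis = np.arange(0, 24, 0.05)
        rss = [np.sum((y - np.polyval(
            np.polyfit(np.cos(2 * np.pi * (t - phi) / 24), y, 1),
            np.cos(2 * np.pi * (t - phi) / 24))) ** 2) for phi in phis]
        # cosine fit is phase-symmetric: acro or acro+12 with negative amp
        best = phis[int(np.argmin(rss))]
        slope = np.polyfit(np.cos(2 * np.pi * (t - best) / 24), y, 1)[0]
        if slope < 0:
            best = (best + 12) % 24
        dist = min(abs(best - 6.0), 24 - abs(best - 6.0))
        assert dist <= 0.5


class TestBehavior:
    def test_siesta_reduces_activity(self):
        sched = ce.ScheduleSpec.mouse(days=5, siesta_window=(18, 20))
        act = ce.synth_behavior(sched, seed=8)
        zt = sched.internal_zt(act.t0 + 150)
        siesta = act.counts[(zt >= 18) & (zt < 20)].mean()
        before = act.counts[(zt >= 16) & (zt < 18)].mean()
        assert siesta < before

    def test_no_shift_stable_acrophase(self):
        sched = ce.ScheduleSpec.mouse(days=4, siesta_window=None)
        act = ce.synth_behavior(sched, seed=9)
        acros = []
        for day in range(4):
            sel = (act.t0 >= day * 86400) & (act.t0 < (day + 1) * 86400)
            acros.append(Cosinor(act.counts[sel],
                                 act.t0[sel] / 3600.0).fit().acrophase_h % 24)
        # Poisson counts on a square-wave profile jitter the daily fit
        assert np.ptp(acros) < 2.0

    def test_phase_shift_reentrains_at_configured_rate(self):
        sched = ce.ScheduleSpec.mouse(days=9, phase_shift_day=3,
                                      shift_hours=9.0,
                                      reentrain_rate_h_per_day=1.5,
                                      siesta_window=None)
        act = ce.synth_behavior(sched, seed=10)
        acros = []
        for day in (3, 4, 5, 6):
            sel = (act.t0 >= day * 86400) & (act.t0 < (day + 1) * 86400)
            acros.append(Cosinor(act.counts[sel],
                                 act.t0[sel] / 3600.0).fit().acrophase_h % 24)
        daily = -np.diff(np.unwrap(np.asarray(acros), period=24.0))
        assert np.all(np.abs(daily - 1.5) < 0.8)  # advances ~1.5 h/day

    def test_temperature_tracks_behavioral_phase(self):
        sched = ce.ScheduleSpec.mouse(days=3, siesta_window=None)
        act = ce.synth_behavior(sched, seed=11)
        res = Cosinor(act.temperature, act.t0 / 3600.0).fit()
        assert res.acrophase_h % 24 == pytest.approx(18.0, abs=1.0)


class TestArrhythmiaInjection:
    def _base(self):
        return ce.synth_beat_train(ce.CircadianParams.mouse(),
                                   ce.ScheduleSpec.mouse(days=0.02), None,
                                   seed=12)

    def test_bvt_run_of_4_annotated(self):
        rec = ce.synth_arrhythmia_episode(self._base(), "BVT", 4, seed=1)
        assert len(rec.episodes) == 1
        s, e, kind, dur = rec.episodes[0]
        assert kind == "BVT" and e - s + 1 == 4
        assert np.all(rec.labels[s : e + 1] == "vpc")

    def test_run_of_3_labels_but_no_episode(self):
        rec = ce.synth_arrhythmia_episode(self._base(), "BVT", 3, seed=2)
        assert rec.episodes == []
        assert np.sum(rec.labels == "vpc") == 3

    def test_bvt_polarities_alternate_in_sign(self):
        rec = ce.synth_arrhythmia_episode(self._base(), "BVT", 6, seed=3)
        s, e, _, _ = rec.episodes[0]
        pol = rec.qrs_polarity[s : e + 1]
        assert np.all(pol[1:] * pol[:-1] < 0)

    def test_vt_polarity_constant_inverted(self):
        rec = ce.synth_arrhythmia_episode(self._base(), "VT", 5, seed=4)
        s, e, kind, _ = rec.episodes[0]
        assert kind == "VT"
        assert np.all(rec.qrs_polarity[s : e + 1] == -1.0)

    def test_run_length_validation(self):
        with pytest.raises(ValueError):
            ce.synth_arrhythmia_episode(self._base(), "BVT", 0)
        with pytest.raises(ValueError):
            ce.synth_arrhythmia_episode(self._base(), "torsade", 4)
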