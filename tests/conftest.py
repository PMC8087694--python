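"""Shared synthetic fixtures (generated at test time, no stored data)."""

import numpy as np
import pytest

import chronoecg as ce


@pytest.fixture(scope="session")
def mouse_clean():
    """Short noiseless mouse recording with ground truth."""
    sched = ce.ScheduleSpec.mouse(days=0.02)  # 6 sweeps
    circ = ce.CircadianParams.mouse()
    truth = ce.synth_beat_train(circ, sched, None, seed=11, species="mouse")
    morph = ce.MorphologyProfile.mouse(noise_sd=0.0, wander=0.0)
    rec = ce.synth_ecg_waveform(truth, morph, fs=1000.0, seed=12)
    return rec


@pytest.fixture(scope="session")
def mouse_noisy():
    """Mouse recording at the reference noise level (5% of R amplitude)."""
    sched = ce.ScheduleSpec.mouse(days=0.15)  # ~43 sweeps
    circ = ce.CircadianParams.mouse()
    act = ce.synth_behavior(sched, seed=21)
    truth = ce.synth_beat_train(circ, sched, act, seed=22, species="mouse")
    morph = ce.MorphologyProfile.mouse(noise_sd=0.05, wander=0.03)
    rec = ce.synth_ecg_waveform(truth, morph, fs=1000.0, seed=23)
    return rec


@pytest.fixture(scope="session")
def human_clean():
    """Short noiseless human recording at 128 Hz."""
    sched = ce.ScheduleSpec.human(days=0.05, sweep_cadence_s=300.0)
    circ = ce.CircadianParams.human()
    truth = ce.synth_beat_train(circ, sched, None, seed=31, species="human")
    morph = ce.MorphologyProfile.human(noise_sd=0.0, wander=0.0)
    rec = ce.synth_ecg_waveform(truth, morph, fs=128.0, seed=32)
    return rec


@pytest.fixture(scope="session")
def mouse_cohort_sweeps():
    """Five-day mouse sweep-level truth (no waveforms) with behaviour."""
    sched = ce.ScheduleSpec.mouse(days=5)
    circ = ce.CircadianParams.mouse()
    act = ce.synth_behavior(sched, seed=41)
    truth = ce.synth_beat_train(circ, sched, act, seed=42, species="mouse")
    return truth


def analyzed(rec):
    return ce.analyze_sweeps(rec.sweeps)


@pytest.fixture(scope="session")
def mouse_noisy_analyzed(mouse_noisy):
    return analyzed(mouse_noisy)


def match_truth(per_beat, rec, tol: int = 2):
    """Join detected beats to annotated truth by R sample proximity."""
    ann = rec.annotations
    out = []
    for sid, a in ann.groupby("sweep_id"):
        d = per_beat[per_beat.sweep_id == sid]
        if d.empty:
            continue
        det_r = d["R"].to_numpy()
        for _, arow in a.iterrows():
            j = np.argmin(np.abs(det_r - arow.R))
            if abs(det_r[j] - arow.R) <= tol:
                out.append((int(arow.beat), d.iloc[j]))
    return out
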