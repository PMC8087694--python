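"""End-to-end sweep analysis: detection -> template QC -> delineation.

Glue that runs the per-sweep chain and returns tidy tables ready for the
rhythmometry and activity modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import beatdet, fiducials, hrv
from .beatdet import AmplitudeWindow
from .fiducials import DelineationConfig
from .io import Sweep


def analyze_sweeps(sweeps: list[Sweep],
                   window: AmplitudeWindow | None = None,
                   theta: float = 0.2,
                   refractory_ms: float | None = None,
                   config: DelineationConfig | None = None,
                   with_hrv: bool = True
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse a list of sweeps.

    Returns ``(per_sweep, per_beat)``: per-sweep median parameters with
    QC flags (and a geometric HRV column), and per-beat intervals with
    landmark indices.  The amplitude window defaults to the per-sweep
    data-derived setting.
    """
    sweep_rows = []
    beat_frames = []
    for sw in sweeps:
        win = window or AmplitudeWindow.from_signal(sw.samples)
        cand = beatdet.detect_r_peaks(sw, win, refractory_ms)
        beats = beatdet.template_filter(sw, cand, theta=theta)
        qc = beatdet.sweep_qc(sw, beats, win)
        fids = fiducials.delineate_sweep(sw, beats, config)
        intervals = fiducials.compute_intervals(fids, sw.fs)
        summary = fiducials.summarize_sweep(sw, intervals, qc)
        row = {
            "sweep_id": sw.sweep_id, "t0_s": sw.t0,
            "rr_ms": summary.rr_ms, "pr_ms": summary.pr_ms,
            "qt_ms": summary.qt_ms, "hr_bpm": summary.hr_bpm,
            "n_beats": summary.n_valid_beats,
            "qc_pass": summary.qc_pass, "excluded": summary.excluded,
            "qc_rules": ",".join(sorted(qc.rule_failures)),
        }
        if with_hrv:
            rr_beats = intervals["rr_ms"].dropna().to_numpy()
            row["hrv"] = hrv.geometric_hrv(rr_beats).measure \
                if rr_beats.size >= 3 else np.nan
        sweep_rows.append(row)
        merged = intervals.merge(
            fids[["R", "P", "Poff", "Qon", "Tpk", "Toff"]], on="R",
            how="left")
        merged.insert(1, "t0_s", sw.t0)
        beat_frames.append(merged)
    per_sweep = pd.DataFrame(sweep_rows)
    beat_frames = [f for f in beat_frames if not f.empty]
    per_beat = (pd.concat(beat_frames, ignore_index=True)
                if beat_frames else pd.DataFrame())
    return per_sweep, per_beat
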