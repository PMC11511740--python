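"""Biomarker extraction from converged waveforms.

The renal resistive index RI = (V_PSV - V_EDV) / V_PSV is computed from
the velocity waveform at each segmental-artery probe (V_PSV = cycle peak;
V_EDV = end-diastolic velocity, operationally the minimum over the final
third of the cycle, which is robust to the early-diastolic reverse-flow
notch) and averaged over the ten segmental sites (five per kidney).
Mean renal blood flow is the cycle average of volumetric flow at the main
renal artery, in ml/min per kidney; brachial SBP/DBP are the cycle
extrema of the brachial pressure waveform in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SimulationResult
from .units import m3s_to_mlmin, pa_to_mmhg


def resistive_index(velocity_series, edv_window: float = 1.0 / 3.0,
                    naive_minimum: bool = False) -> float:
    """RI = (V_PSV - V_EDV) / V_PSV over one cardiac cycle.

    ``V_EDV`` is the minimum over the final ``edv_window`` fraction of the
    cycle; set ``naive_minimum`` for the plain cycle minimum instead.
    """
    v = np.asarray(velocity_series, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity series")
    psv = float(v.max())
    if psv <= 0:
        raise ValueError("peak systolic velocity must be positive")
    if naive_minimum:
        edv = float(v.min())
    else:
        start = int(round((1.0 - edv_window) * v.size))
        edv = float(v[start:].min())
    return (psv - edv) / psv


def mean_flow(flow_series) -> float:
    """Cycle-averaged volumetric flow in ml/min (series covers one period)."""
    q = np.asarray(flow_series, dtype=float)
    return m3s_to_mlmin(float(q.mean()))


def brachial_pressures(result: SimulationResult,
                       probe: str = "brachial") -> tuple[float, float]:
    """(SBP, DBP) in mmHg: cycle max/min of brachial probe pressure."""
    if probe not in result.pressure:
        raise KeyError(f"missing probe '{probe}'")
    p = result.pressure[probe]
    return pa_to_mmhg(float(p.max())), pa_to_mmhg(float(p.min()))


def subject_RI(result: SimulationResult, probes: list[str],
               **kwargs) -> float:
    """Arithmetic mean of per-probe RI over the segmental probe set."""
    missing = [p for p in probes if p not in result.flow]
    if missing:
        raise KeyError(f"missing probes {missing}")
    vel = result.velocity
    return float(np.mean([resistive_index(vel[p], **kwargs) for p in probes]))


@dataclass
class BiomarkerRecord:
    """Per-subject biomarkers on the clinical scales."""

    subject_id: str
    age_group: str = ""
    stage: str = "healthy"
    sbp_mmhg: float = np.nan
    dbp_mmhg: float = np.nan
    ri_mean: float = np.nan          # mean over all ten segmental probes
    ri_left: float = np.nan
    ri_right: float = np.nan
    rbf_left_mlmin: float = np.nan   # single-kidney mean RBF
    rbf_right_mlmin: float = np.nan
    psv_ms: dict = field(default_factory=dict)
    edv_ms: dict = field(default_factory=dict)

    @property
    def rbf_total_mlmin(self) -> float:
        return self.rbf_left_mlmin + self.rbf_right_mlmin

    @property
    def rbf_single_mlmin(self) -> float:
        """Mean RBF through a single kidney (average of left and right)."""
        return 0.5 * (self.rbf_left_mlmin + self.rbf_right_mlmin)


def extract_biomarkers(result: SimulationResult, subject_id: str = "",
                       age_group: str = "", stage: str = "healthy",
                       edv_window: float = 1.0 / 3.0) -> BiomarkerRecord:
    """Full biomarker record from one converged simulation.

    Expects the baseline probe layout: main renal midpoints
    (renal_main_l/r), segmental midpoints (renal_seg_<side><1-5>) and the
    brachial midpoint.
    """
    sbp, dbp = brachial_pressures(result)
    rec = BiomarkerRecord(subject_id, age_group, stage, sbp, dbp)
    vel = result.velocity
    per_side = {}
    for side in ("l", "r"):
        names = [f"renal_seg_{side}{i}" for i in range(1, 6)]
        ris = []
        for name in names:
            v = vel[name]
            ris.append(resistive_index(v, edv_window))
            start = int(round((1.0 - edv_window) * v.size))
            rec.psv_ms[name] = float(v.max())
            rec.edv_ms[name] = float(v[start:].min())
        per_side[side] = float(np.mean(ris))
    rec.ri_left, rec.ri_right = per_side["l"], per_side["r"]
    rec.ri_mean = 0.5 * (rec.ri_left + rec.ri_right)
    rec.rbf_left_mlmin = mean_flow(result.flow["renal_main_l"])
    rec.rbf_right_mlmin = mean_flow(result.flow["renal_main_r"])
    return rec


def records_to_frame(records: list[BiomarkerRecord]) -> pd.DataFrame:
    """Tidy biomarker table (one row per subject)."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "age_group": r.age_group,
            "stage": r.stage, "sbp_mmhg": r.sbp_mmhg, "dbp_mmhg": r.dbp_mmhg,
            "ri_mean": r.ri_mean, "ri_left": r.ri_left, "ri_right": r.ri_right,
            "rbf_left_mlmin": r.rbf_left_mlmin,
            "rbf_right_mlmin": r.rbf_right_mlmin,
            "rbf_total_mlmin": r.rbf_total_mlmin,
            "rbf_single_mlmin": r.rbf_single_mlmin,
        })
    return pd.DataFrame(rows)
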