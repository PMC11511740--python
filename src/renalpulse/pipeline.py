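"""Study orchestration: configuration, cohort simulation, study recipes.

The recipes mirror the study design: an ageing cohort (sample healthy
subjects per age group, simulate, filter on brachial pressures, summarise
biomarkers per group) and a disease cohort (apply calibrated stage
multipliers to the filtered healthy subjects, re-simulate, and evaluate
RI / renal-blood-flow discrimination between diabetic and hypertensive
nephropathy with ROC curves).

Everything is seeded and deterministic; per-subject failures or
non-converged runs are excluded from biomarker tables and counted
separately from the physiology filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import roc_analysis, summarize
from .baseline import BASELINE_CO_LMIN, build_baseline_network
from .biomarkers import extract_biomarkers, records_to_frame
from .model import BloodProperties, NumericsConfig, generate_inlet_waveform
from .network import Network, read_network
from .population import (AGE_GROUPS, STAGES, AgeingDistributionTable,
                         VirtualSubject, apply_disease_scaling,
                         load_ageing_table, load_disease_scalings,
                         physiology_filter, sample_ageing_subjects)
from .units import lmin_to_m3s

log = logging.getLogger("renalpulse")

#: desk-scale population sizes per age group (the published study used
#: 2,000 per group; these defaults keep a full study within minutes)
DEFAULT_SIZES = {"20-29": 40, "30-39": 10, "40-49": 10,
                 "50-59": 52, "60-69": 10, "70-79": 36}


@dataclass
class StudyConfig:
    """Pipeline configuration; round-trips through YAML."""

    network: str = "baseline"
    heart_rate: float = 70.0
    seed: int = 1
    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_SIZES))
    stages: list = field(default_factory=lambda: list(STAGES))
    output_dir: str = "results"
    numerics: dict = field(default_factory=dict)
    blood: dict = field(default_factory=dict)
    stage_cap_per_group: int = 10
    roc_group: str = "50-59"
    roc_cap_per_stage: int = 48
    roc_stages: list = field(default_factory=lambda: list(STAGES))

    def __post_init__(self):
        if isinstance(self.n_per_group, int):
            self.n_per_group = {g: self.n_per_group for g in AGE_GROUPS}
        bad = [g for g, n in self.n_per_group.items() if n <= 0]
        if bad:
            raise ValueError(f"population sizes must be positive, bad groups: {bad}")

    def numerics_config(self) -> NumericsConfig:
        return NumericsConfig(**self.numerics)

    def load_network(self) -> Network:
        if self.network == "baseline":
            return build_baseline_network()
        return read_network(self.network)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        data = asdict(self)
        data.pop("output_dir")
        return hashlib.sha1(
            yaml.safe_dump(data, sort_keys=True).encode()).hexdigest()[:12]


# ----------------------------------------------------------------------
# cohort simulation
# ----------------------------------------------------------------------

def simulate_subject(subject: VirtualSubject, baseline: Network,
                     heart_rate: float = 70.0,
                     numerics: NumericsConfig | None = None,
                     blood_kwargs: dict | None = None):
    """Materialize, run and extract biomarkers for one subject."""
    from .solver import run_simulation

    net = subject.materialize(baseline)
    co = lmin_to_m3s(subject.cardiac_output_lmin)
    inlet = generate_inlet_waveform(co, heart_rate)
    kw = dict(blood_kwargs or {})
    kw["viscosity"] = kw.get("viscosity", 4.0e-3) * subject.factors.viscosity
    blood = BloodProperties(**kw)
    result = run_simulation(net, inlet, blood, numerics)
    record = extract_biomarkers(result, subject.subject_id,
                                subject.age_group, subject.stage)
    return result, record


def simulate_cohort(subjects: list[VirtualSubject], baseline: Network,
                    heart_rate: float = 70.0,
                    numerics: NumericsConfig | None = None,
                    blood_kwargs: dict | None = None):
    """Run a list of subjects; returns (biomarker frame, exclusions frame).

    Subjects whose simulation fails or does not reach periodic convergence
    are quarantined (listed with a reason) and excluded from the table.
    """
    from .solver import SimulationError

    records, excluded = [], []
    for s in subjects:
        try:
            result, record = simulate_subject(s, baseline, heart_rate,
                                              numerics, blood_kwargs)
        except SimulationError as exc:
            log.warning("subject %s failed: %s", s.subject_id, exc)
            excluded.append({"subject_id": s.subject_id, "reason": str(exc)})
            continue
        if not result.converged:
            log.warning("subject %s not converged in %d cycles",
                        s.subject_id, result.cycles_to_convergence)
            excluded.append({"subject_id": s.subject_id,
                             "reason": "not converged"})
            continue
        records.append(record)
    frame = records_to_frame(records)
    return frame, pd.DataFrame(excluded, columns=["subject_id", "reason"])


def sample_healthy_cohort(table: AgeingDistributionTable, n_per_group: dict,
                          seed: int, baseline: Network):
    """Seeded healthy subjects for each requested age group."""
    subjects = []
    for gi, group in enumerate(AGE_GROUPS):
        n = n_per_group.get(group, 0)
        if n > 0:
            subjects.extend(sample_ageing_subjects(
                table, group, n, seed=seed * 100 + gi, baseline=baseline))
    return subjects


# ----------------------------------------------------------------------
# study recipes
# ----------------------------------------------------------------------

@dataclass
class AgeingStudyOutput:
    biomarkers: pd.DataFrame          # all converged healthy subjects
    kept: pd.DataFrame                # after the physiology filter
    filter_report: pd.DataFrame
    exclusions: pd.DataFrame
    summaries: dict                   # per-variable, per-group SummaryStats


def ageing_study(config: StudyConfig, subjects=None) -> AgeingStudyOutput:
    """Sample -> simulate -> filter -> per-age-group biomarker summaries."""
    table = load_ageing_table()
    baseline = config.load_network()
    if subjects is None:
        subjects = sample_healthy_cohort(table, config.n_per_group,
                                         config.seed, baseline)
    log.info("ageing study: %d subjects", len(subjects))
    frame, excluded = simulate_cohort(subjects, baseline, config.heart_rate,
                                      config.numerics_config(), config.blood)
    kept, report = physiology_filter(frame, table)
    summaries = {}
    for var in ("sbp_mmhg", "dbp_mmhg", "ri_mean", "rbf_total_mlmin"):
        groups = {g: sub[var].to_numpy()
                  for g, sub in kept.groupby("age_group") if len(sub)}
        if groups:
            summaries[var] = summarize(groups)
    return AgeingStudyOutput(frame, kept, report, excluded, summaries)


@dataclass
class DiseaseStudyOutput:
    healthy: AgeingStudyOutput
    stage_frames: dict                # stage -> biomarker frame
    stage_exclusions: dict
    roc: dict                         # (pair, biomarker) -> ROCResult
    scalings: dict                    # stage -> DiseaseScaling applied


def _stage_subjects(kept_ids_by_group, subjects_by_id, scaling,
                    cap_per_group, roc_group=None, roc_cap=0):
    picked = []
    for g, ids in kept_ids_by_group.items():
        take = ids[:cap_per_group]
        if g == roc_group and roc_cap > cap_per_group:
            take = ids[:roc_cap]
        picked.extend(take)
    return [apply_disease_scaling(subjects_by_id[i], scaling) for i in picked]


def disease_study(config: StudyConfig, healthy: AgeingStudyOutput | None = None,
                  subjects=None) -> DiseaseStudyOutput:
    """Apply stage scalings to filtered healthy subjects; simulate; ROC.

    ROC pairs (early: Early.D vs Early.H, severe: Severe.D vs Severe.H)
    are evaluated in the ``roc_group`` age band with both biomarkers
    (single-kidney mean RBF and mean segmental RI), diabetic nephropathy
    as the positive class.
    """
    table = load_ageing_table()
    baseline = config.load_network()
    scalings = load_disease_scalings()
    if subjects is None:
        subjects = sample_healthy_cohort(table, config.n_per_group,
                                         config.seed, baseline)
    subjects_by_id = {s.subject_id: s for s in subjects}
    if healthy is None:
        healthy = ageing_study(config, subjects=subjects)
    kept_ids = {g: sub["subject_id"].tolist()
                for g, sub in healthy.kept.groupby("age_group")}

    stage_frames, stage_excl, applied = {}, {}, {}
    for stage in config.stages:
        sc = scalings[stage]
        roc_needed = stage in config.roc_stages
        staged = _stage_subjects(kept_ids, subjects_by_id, sc,
                                 config.stage_cap_per_group,
                                 config.roc_group if roc_needed else None,
                                 config.roc_cap_per_stage)
        log.info("stage %s: %d subjects", stage, len(staged))
        frame, excl = simulate_cohort(staged, baseline, config.heart_rate,
                                      config.numerics_config(), config.blood)
        stage_frames[stage] = frame
        stage_excl[stage] = excl
        applied[stage] = sc

    roc = {}
    pairs = [("early", "Early.D", "Early.H"), ("severe", "Severe.D", "Severe.H")]
    for pair_name, pos_stage, neg_stage in pairs:
        if pos_stage not in stage_frames or neg_stage not in stage_frames:
            continue
        sub_d = stage_frames[pos_stage]
        sub_h = stage_frames[neg_stage]
        sub_d = sub_d[sub_d["age_group"] == config.roc_group]
        sub_h = sub_h[sub_h["age_group"] == config.roc_group]
        if not len(sub_d) or not len(sub_h):
            continue
        labels = np.array(["DN"] * len(sub_d) + ["HN"] * len(sub_h))
        for biom, col in (("rbf", "rbf_single_mlmin"), ("ri", "ri_mean")):
            scores = np.concatenate([sub_d[col].to_numpy(),
                                     sub_h[col].to_numpy()])
            roc[(pair_name, biom)] = roc_analysis(scores, labels, "DN")
    return DiseaseStudyOutput(healthy, stage_frames, stage_excl, roc, applied)


# ----------------------------------------------------------------------
# acceptance quantities (used by scripts/acceptance.py and the tests)
# ----------------------------------------------------------------------

def acceptance_study(seed: int, n_per_group: dict | None = None,
                     stage_cap: int = 8, roc_cap: int = 30) -> dict:
    """Recompute the headline study quantities from scratch.

    Returns ``{"targets": {id: {"value": float, "n": int}}, ...}`` plus the
    underlying frames.  Target ids follow the study readout order: stage
    RI means (t1-t3), stage single-kidney RBF means (t4-t5), ageing RI and
    total RBF (t6-t8), early-stage ROC AUCs and the RBF Youden cut-off
    (t9-t11).
    """
    config = StudyConfig(seed=seed,
                         n_per_group=dict(n_per_group or DEFAULT_SIZES),
                         stages=["Early.D", "Severe.D", "Early.H"],
                         stage_cap_per_group=stage_cap,
                         roc_cap_per_stage=roc_cap,
                         roc_stages=["Early.D", "Early.H"])
    out = disease_study(config)
    kept = out.healthy.kept

    targets = {}

    def put(tid, value, n):
        targets[tid] = {"value": float(value), "n": int(n)}

    # stage means over the age-balanced subset (<= stage_cap per group)
    balanced = {}
    for stage in ("Early.D", "Severe.D", "Early.H"):
        frame = out.stage_frames[stage]
        sub = frame.groupby("age_group", sort=False).head(stage_cap)
        balanced[stage] = sub
    put("t1", balanced["Early.D"]["ri_mean"].mean(), len(balanced["Early.D"]))
    put("t2", balanced["Severe.D"]["ri_mean"].mean(), len(balanced["Severe.D"]))
    put("t3", balanced["Early.H"]["ri_mean"].mean(), len(balanced["Early.H"]))
    put("t4", balanced["Early.D"]["rbf_single_mlmin"].mean(), len(balanced["Early.D"]))
    put("t5", balanced["Early.H"]["rbf_single_mlmin"].mean(), len(balanced["Early.H"]))

    young = kept[kept["age_group"] == "20-29"]
    old = kept[kept["age_group"] == "70-79"]
    put("t6", young["ri_mean"].median(), len(young))
    put("t7", old["rbf_total_mlmin"].mean(), len(old))
    put("t8", young["rbf_total_mlmin"].mean(), len(young))

    roc_rbf = out.roc.get(("early", "rbf"))
    roc_ri = out.roc.get(("early", "ri"))
    n_roc = (len(out.stage_frames["Early.D"]
                 .query("age_group == @config.roc_group"))
             + len(out.stage_frames["Early.H"]
                   .query("age_group == @config.roc_group")))
    if roc_rbf is not None:
        put("t9", roc_rbf.auc, n_roc)
        put("t11", roc_rbf.cutoff, n_roc)
    if roc_ri is not None:
        put("t10", roc_ri.auc, n_roc)

    return {"targets": targets, "study": out, "config": config}


# ----------------------------------------------------------------------
# file-writing commands (used by the CLI and the analysis scripts)
# ----------------------------------------------------------------------

def _stamp(config: StudyConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed}


def _write(df: pd.DataFrame, path: Path, config: StudyConfig):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=False)
    log.info("wrote %s", path)


def cmd_simulate(config: StudyConfig, subject_id: str = "baseline"):
    """Simulate the (unscaled) baseline subject and write its waveforms."""
    from .solver import run_simulation

    baseline = config.load_network()
    inlet = generate_inlet_waveform(lmin_to_m3s(BASELINE_CO_LMIN),
                                    config.heart_rate)
    blood = BloodProperties(**config.blood)
    result = run_simulation(baseline, inlet, blood, config.numerics_config())
    rows = []
    for probe in result.probe_names:
        for i, t in enumerate(result.t):
            rows.append({"subject_id": subject_id, "probe": probe,
                         "t_s": t, "P_Pa": result.pressure[probe][i],
                         "Q_m3_s": result.flow[probe][i],
                         "A_m2": result.area[probe][i],
                         "u_m_s": result.velocity[probe][i]})
    df = pd.DataFrame(rows)
    outdir = Path(config.output_dir)
    _write(df, outdir / f"waveforms_{subject_id}.csv", config)
    diag = dict(result.diagnostics)
    diag.update(_stamp(config), converged=bool(result.converged),
                cycles=result.cycles_to_convergence)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"runlog_{subject_id}.json").write_text(
        json.dumps(diag, default=str, indent=1))
    return result


def cmd_ageing_study(config: StudyConfig) -> AgeingStudyOutput:
    out = ageing_study(config)
    outdir = Path(config.output_dir)
    _write(out.biomarkers, outdir / "ageing_biomarkers.csv", config)
    _write(out.kept, outdir / "ageing_biomarkers_kept.csv", config)
    _write(out.filter_report, outdir / "ageing_filter_report.csv", config)
    _write(out.exclusions, outdir / "ageing_exclusions.csv", config)
    rows = []
    for var, groups in out.summaries.items():
        for g, s in groups.items():
            rows.append({"variable": var, "age_group": g, "n": s.n,
                         "mean": s.mean, "sd": s.sd, "median": s.median,
                         "q1": s.q1, "q3": s.q3, "iqr": s.iqr,
                         "n_outliers": len(s.outliers)})
    _write(pd.DataFrame(rows), outdir / "ageing_summary.csv", config)
    return out


def cmd_disease_study(config: StudyConfig) -> DiseaseStudyOutput:
    out = disease_study(config)
    outdir = Path(config.output_dir)
    for stage, frame in out.stage_frames.items():
        _write(frame, outdir / f"stage_{stage}.csv", config)
    rows = []
    for (pair, biom), r in out.roc.items():
        _write(pd.DataFrame({"threshold": r.thresholds,
                             "sensitivity": r.sensitivity,
                             "specificity": r.specificity}),
               outdir / f"roc_{pair}_{biom}.csv", config)
        rows.append({"pair": pair, "biomarker": biom, "auc": r.auc,
                     "cutoff": r.cutoff, "sensitivity": r.cutoff_sensitivity,
                     "specificity": r.cutoff_specificity,
                     "youden_j": r.youden_j, "orientation": r.orientation})
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "roc_summary.json").write_text(json.dumps(
        {"results": rows, **_stamp(config)}, indent=1))
    # provenance: the multipliers actually applied per stage
    srows = []
    for stage, sc in out.scalings.items():
        srows.append({"stage": stage, "viscosity": sc.viscosity,
                      "cardiac_output": sc.cardiac_output,
                      "radius": json.dumps(sc.radius),
                      "youngs_modulus": json.dumps(sc.youngs_modulus),
                      "thickness": json.dumps(sc.thickness),
                      "pvr": sc.pvr, "pvc": sc.pvc})
    _write(pd.DataFrame(srows), outdir / "stage_multipliers.csv", config)
    return out


# ----------------------------------------------------------------------
# evaluators for sensitivity analysis and stage calibration
# ----------------------------------------------------------------------

#: grouped scaling parameters screened in the sensitivity analysis
SENSITIVITY_PARAMETERS = ("renal_radius", "renal_pvr", "renal_pvc",
                          "systemic_radius", "length", "youngs_modulus",
                          "thickness", "cardiac_output", "viscosity")


def make_ri_evaluator(network: Network | None = None,
                      heart_rate: float = 70.0,
                      numerics: NumericsConfig | None = None):
    """Deterministic model ``{grouped factor: value} -> mean segmental RI``.

    Each call scales the supplied network (default: the reduced
    single-kidney network, which keeps a Saltelli design affordable) by
    the grouped factors and runs one simulation.
    """
    from .baseline import build_reduced_renal_network
    from .solver import run_simulation

    if network is None:
        network = build_reduced_renal_network()
    seg_probes = [p.name for p in network.probes if "renal_seg" in p.name]

    def evaluate(factors: dict) -> float:
        from .biomarkers import subject_RI

        renal = {vid: factors.get("renal_radius", 1.0)
                 for vid in network.vessels if vid.startswith("renal")}
        radius = {vid: renal.get(vid, factors.get("systemic_radius", 1.0))
                  for vid in network.vessels}
        pvr = {oid: (factors.get("renal_pvr", 1.0) if oid.startswith("renal")
                     else 1.0) for oid in network.outlets}
        pvc = {oid: (factors.get("renal_pvc", 1.0) if oid.startswith("renal")
                     else 1.0) for oid in network.outlets}
        net = network.scaled(length=factors.get("length", 1.0),
                             radius=radius,
                             thickness=factors.get("thickness", 1.0),
                             youngs_modulus=factors.get("youngs_modulus", 1.0),
                             pvr=pvr, pvc=pvc)
        co = lmin_to_m3s(BASELINE_CO_LMIN * factors.get("cardiac_output", 1.0))
        inlet = generate_inlet_waveform(co, heart_rate)
        blood = BloodProperties(viscosity=4.0e-3 * factors.get("viscosity", 1.0))
        result = run_simulation(net, inlet, blood, numerics)
        return subject_RI(result, seg_probes)

    return evaluate


def make_stage_ri_evaluator(subjects: list[VirtualSubject],
                            baseline: Network | None = None,
                            heart_rate: float = 70.0,
                            numerics: NumericsConfig | None = None):
    """``DiseaseScaling -> population mean RI`` for the calibration search.

    ``subjects`` is a (small) healthy population; each evaluation applies
    the candidate scaling and re-simulates all of them.
    """
    if baseline is None:
        baseline = build_baseline_network()

    def evaluate(scaling) -> float:
        ris = []
        for s in subjects:
            _, rec = simulate_subject(apply_disease_scaling(s, scaling),
                                      baseline, heart_rate, numerics)
            ris.append(rec.ri_mean)
        return float(np.mean(ris))

    return evaluate
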