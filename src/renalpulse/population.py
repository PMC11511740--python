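"""Virtual-population generation: ageing sampling, disease scaling, filtering.

Healthy subjects are drawn by scaling the baseline network with
normalised Gaussian factors per age group (cardiac output once per
subject; length, radius, Young's modulus and wall thickness independently
per vessel; peripheral resistance and compliance independently per
outlet).  Disease stages apply fixed calibrated point multipliers on top
of a healthy subject.  The physiology filter removes subjects whose
simulated brachial pressures deviate by more than 2.575 SD from the
age-group reference means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .baseline import BASELINE_CO_LMIN
from .network import Network

AGE_GROUPS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
STAGES = ("Early.D", "Severe.D", "Early.H", "Severe.H")
_VESSEL_PARAMS = ("length", "radius", "youngs_modulus", "thickness")
#: half-width of the symmetric brachial-pressure acceptance band, in SDs
FILTER_SD = 2.575


def _data_path(name):
    return resources.files("renalpulse") / "data" / name


# ----------------------------------------------------------------------
# ageing distribution table
# ----------------------------------------------------------------------

@dataclass
class AgeingDistributionTable:
    """Normalised parameter distributions per age group.

    ``params[group][parameter] = (mean, sd)`` for cardiac_output, length,
    radius, youngs_modulus, thickness, pvr, pvc, plus brachial reference
    pressures sbp_mmhg / dbp_mmhg.
    """

    params: dict[str, dict[str, tuple[float, float]]]

    def __post_init__(self):
        missing = [g for g in AGE_GROUPS if g not in self.params]
        if missing:
            raise ValueError(f"missing age groups: {missing}")
        for g, tab in self.params.items():
            for p, (m, s) in tab.items():
                if s < 0:
                    raise ValueError(f"{g}/{p}: negative SD")
                if m <= 0:
                    raise ValueError(f"{g}/{p}: non-positive mean")

    @classmethod
    def from_csv(cls, path=None) -> "AgeingDistributionTable":
        df = pd.read_csv(path if path is not None else _data_path("ageing_table.csv"))
        params: dict[str, dict[str, tuple[float, float]]] = {}
        for _, row in df.iterrows():
            params.setdefault(row["age_group"], {})[row["parameter"]] = (
                float(row["mean"]), float(row["sd"]))
        return cls(params)

    def mean_sd(self, age_group: str, parameter: str) -> tuple[float, float]:
        try:
            return self.params[age_group][parameter]
        except KeyError:
            raise KeyError(f"no entry for ({age_group!r}, {parameter!r})")

    def brachial_bounds(self, age_group: str, n_sd: float = FILTER_SD):
        """(sbp_lo, sbp_hi, dbp_lo, dbp_hi) in mmHg for the filter."""
        sm, ss = self.mean_sd(age_group, "sbp_mmhg")
        dm, ds = self.mean_sd(age_group, "dbp_mmhg")
        return (sm - n_sd * ss, sm + n_sd * ss, dm - n_sd * ds, dm + n_sd * ds)


def load_ageing_table() -> AgeingDistributionTable:
    return AgeingDistributionTable.from_csv()


# ----------------------------------------------------------------------
# disease scalings
# ----------------------------------------------------------------------

def vessel_class(vessel_id: str) -> set[str]:
    """Classes a vessel belongs to, for disease multiplier overrides."""
    out = {"default"}
    if vessel_id.startswith("aorta") or vessel_id == "brachioceph":
        out.add("aorta")
    if vessel_id == "aorta_asc":
        out.add("ascending_aorta")
    if vessel_id.startswith("aorta_thor"):
        out.add("descending_aorta")
    if vessel_id.startswith("aorta_abd"):
        out.add("abdominal_aorta")
    if vessel_id.startswith("carotid"):
        out.add("carotid")
    if vessel_id.startswith("radial"):
        out.add("radial")
    if vessel_id.startswith("brachial"):
        out.add("brachial")
    if vessel_id.startswith("renal"):
        out.add("renal")
    return out


#: override precedence: most specific class wins
_CLASS_PRECEDENCE = ("ascending_aorta", "descending_aorta", "abdominal_aorta",
                     "renal", "carotid", "radial", "brachial", "aorta", "default")


@dataclass
class DiseaseScaling:
    """Calibrated point multipliers of one disease stage.

    Per-vessel-class multipliers for radius / Young's modulus / thickness
    carry named overrides (e.g. the ascending-aorta radius under
    hypertension); ``renal_radius`` / ``renal_pvr`` / ``renal_pvc``, when
    set, override the renal tree and renal beds specifically — these are
    the tunables exposed to the calibration search.  Literature Mean (SD)
    columns of the source tables are retained as metadata only.
    """

    stage: str
    viscosity: float = 1.0
    cardiac_output: float = 1.0
    radius: dict[str, float] = field(default_factory=lambda: {"default": 1.0})
    youngs_modulus: dict[str, float] = field(default_factory=lambda: {"default": 1.0})
    thickness: dict[str, float] = field(default_factory=lambda: {"default": 1.0})
    pvr: float = 1.0
    pvc: float = 1.0
    renal_radius: float | None = None
    renal_pvr: float | None = None
    renal_pvc: float | None = None
    literature: pd.DataFrame | None = None

    def __post_init__(self):
        vals = [self.viscosity, self.cardiac_output, self.pvr, self.pvc,
                *self.radius.values(), *self.youngs_modulus.values(),
                *self.thickness.values()]
        vals += [v for v in (self.renal_radius, self.renal_pvr, self.renal_pvc)
                 if v is not None]
        if any(not v > 0 for v in vals):
            raise ValueError("all disease multipliers must be > 0")

    def _lookup(self, table: dict[str, float], vessel_id: str) -> float:
        classes = vessel_class(vessel_id)
        for cls_name in _CLASS_PRECEDENCE:
            if cls_name in classes and cls_name in table:
                return table[cls_name]
        return 1.0

    def radius_factor(self, vessel_id: str) -> float:
        if self.renal_radius is not None and "renal" in vessel_class(vessel_id):
            return self.renal_radius
        return self._lookup(self.radius, vessel_id)

    def youngs_factor(self, vessel_id: str) -> float:
        return self._lookup(self.youngs_modulus, vessel_id)

    def thickness_factor(self, vessel_id: str) -> float:
        return self._lookup(self.thickness, vessel_id)

    def pvr_factor(self, outlet_id: str) -> float:
        if self.renal_pvr is not None and "renal" in vessel_class(outlet_id):
            return self.renal_pvr
        return self.pvr

    def pvc_factor(self, outlet_id: str) -> float:
        if self.renal_pvc is not None and "renal" in vessel_class(outlet_id):
            return self.renal_pvc
        return self.pvc


def load_disease_scalings(path=None) -> dict[str, DiseaseScaling]:
    df = pd.read_csv(path if path is not None else _data_path("disease_scalings.csv"))
    out = {}
    for stage, sub in df.groupby("stage"):
        kw = {"stage": stage, "radius": {}, "youngs_modulus": {}, "thickness": {}}
        for _, row in sub.iterrows():
            p = row["parameter"]
            m = float(row["multiplier"])
            if p in ("viscosity", "cardiac_output", "pvr", "pvc"):
                kw[p] = m
            else:
                kw[p][row["vessel_class"]] = m
        sc = DiseaseScaling(**kw)
        sc.literature = sub.reset_index(drop=True)
        out[stage] = sc
    missing = [s for s in STAGES if s not in out]
    if missing:
        raise ValueError(f"missing stages in scaling table: {missing}")
    return out


# ----------------------------------------------------------------------
# subjects
# ----------------------------------------------------------------------

@dataclass
class ScalingFactorSet:
    """All multiplicative factors of one subject (reproducible from seed)."""

    age_group: str
    stage: str                      # 'healthy' or a disease stage id
    seed: int                       # population base seed
    index: int                      # subject index within the population
    cardiac_output: float = 1.0
    viscosity: float = 1.0
    length: dict[str, float] = field(default_factory=dict)
    radius: dict[str, float] = field(default_factory=dict)
    youngs_modulus: dict[str, float] = field(default_factory=dict)
    thickness: dict[str, float] = field(default_factory=dict)
    pvr: dict[str, float] = field(default_factory=dict)
    pvc: dict[str, float] = field(default_factory=dict)


@dataclass
class VirtualSubject:
    """A scaled instance of the baseline model."""

    subject_id: str
    factors: ScalingFactorSet

    @property
    def age_group(self) -> str:
        return self.factors.age_group

    @property
    def stage(self) -> str:
        return self.factors.stage

    def materialize(self, baseline: Network) -> Network:
        f = self.factors
        return baseline.scaled(length=f.length, radius=f.radius,
                               thickness=f.thickness,
                               youngs_modulus=f.youngs_modulus,
                               pvr=f.pvr, pvc=f.pvc)

    @property
    def cardiac_output_lmin(self) -> float:
        return BASELINE_CO_LMIN * self.factors.cardiac_output


def _truncated_normal(rng, mean, sd, size):
    """Gaussian draws rejected outside (0, mean + 4 sd]."""
    if sd == 0.0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    hi = mean + 4.0 * sd
    bad = (out <= 0.0) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= 0.0) | (out > hi)
    return out


def sample_ageing_subjects(table: AgeingDistributionTable, age_group: str,
                           n: int, seed: int,
                           baseline: Network | None = None) -> list[VirtualSubject]:
    """Draw ``n`` healthy subjects for one age group.

    Every (parameter, vessel) pair is an independent Gaussian draw from
    the group's normalised distribution, truncated to (0, mean + 4 sd] by
    rejection.  Deterministic for a fixed seed: subject ``i`` is fully
    reproducible from ``(seed, i)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group '{age_group}'")
    if baseline is None:
        from .baseline import build_baseline_network
        baseline = build_baseline_network()
    vessel_ids = list(baseline.vessels)
    outlet_ids = list(baseline.outlets)

    subjects = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        f = ScalingFactorSet(age_group=age_group, stage="healthy",
                             seed=seed, index=i)
        m, s = table.mean_sd(age_group, "cardiac_output")
        f.cardiac_output = float(_truncated_normal(rng, m, s, 1)[0])
        for param, attr in zip(("length", "radius", "youngs_modulus", "thickness"),
                               ("length", "radius", "youngs_modulus", "thickness")):
            m, s = table.mean_sd(age_group, param)
            draws = _truncated_normal(rng, m, s, len(vessel_ids))
            setattr(f, attr, dict(zip(vessel_ids, draws.tolist())))
        for param, attr in zip(("pvr", "pvc"), ("pvr", "pvc")):
            m, s = table.mean_sd(age_group, param)
            draws = _truncated_normal(rng, m, s, len(outlet_ids))
            setattr(f, attr, dict(zip(outlet_ids, draws.tolist())))
        subjects.append(VirtualSubject(f"{age_group}_h{i:04d}_s{seed}", f))
    return subjects


def apply_disease_scaling(subject: VirtualSubject,
                          scaling: DiseaseScaling) -> VirtualSubject:
    """Scale a healthy subject's parameters by a stage's point multipliers.

    Severe stages are derived from the same healthy subject (each stage's
    multipliers are expressed relative to healthy, not to the earlier
    stage).
    """
    if subject.stage != "healthy":
        raise ValueError(
            f"disease scaling must start from a healthy subject, got '{subject.stage}'")
    if scaling.stage not in STAGES:
        raise ValueError(f"unknown stage id '{scaling.stage}'")
    f = subject.factors
    nf = replace(
        f,
        stage=scaling.stage,
        cardiac_output=f.cardiac_output * scaling.cardiac_output,
        viscosity=f.viscosity * scaling.viscosity,
        length=dict(f.length),
        radius={k: v * scaling.radius_factor(k) for k, v in f.radius.items()},
        youngs_modulus={k: v * scaling.youngs_factor(k)
                        for k, v in f.youngs_modulus.items()},
        thickness={k: v * scaling.thickness_factor(k)
                   for k, v in f.thickness.items()},
        pvr={k: v * scaling.pvr_factor(k) for k, v in f.pvr.items()},
        pvc={k: v * scaling.pvc_factor(k) for k, v in f.pvc.items()},
    )
    sid = subject.subject_id.replace("_h", f"_{scaling.stage}_", 1)
    return VirtualSubject(sid, nf)


# ----------------------------------------------------------------------
# physiology filter
# ----------------------------------------------------------------------

def physiology_filter(records: pd.DataFrame, table: AgeingDistributionTable,
                      n_sd: float = FILTER_SD):
    """Keep subjects whose brachial SBP and DBP lie within ``n_sd``
    standard deviations of the age-group reference means.

    ``records`` needs columns subject_id, age_group, sbp_mmhg, dbp_mmhg.
    Returns ``(kept, report)``: the kept subset (same columns, original
    order) and a per-group report with total / kept counts and keep rate.
    The filter is idempotent and order-independent.
    """
    for col in ("subject_id", "age_group", "sbp_mmhg", "dbp_mmhg"):
        if col not in records.columns:
            raise ValueError(f"records missing column '{col}'")
    if records[["sbp_mmhg", "dbp_mmhg"]].isna().any().any():
        bad = records.loc[records[["sbp_mmhg", "dbp_mmhg"]].isna().any(axis=1),
                          "subject_id"].tolist()
        raise ValueError(f"subjects missing pressures: {bad[:5]}")
    keep = pd.Series(False, index=records.index)
    rows = []
    for group, sub in records.groupby("age_group", sort=False):
        slo, shi, dlo, dhi = table.brachial_bounds(group, n_sd)
        ok = (sub["sbp_mmhg"].between(slo, shi)
              & sub["dbp_mmhg"].between(dlo, dhi))
        keep.loc[sub.index[ok]] = True
        rows.append({"age_group": group, "n_total": len(sub),
                     "n_kept": int(ok.sum()),
                     "keep_rate": float(ok.mean())})
    kept = records.loc[keep].copy()
    report = pd.DataFrame(rows)
    return kept, report
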