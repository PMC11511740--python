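"""Arterial network data model and its tabular on-disk format.

A :class:`Network` is a directed tree of elastic vessels rooted at a single
inlet.  Terminal vessels carry lumped R-C-R (Windkessel) outlet models for
the downstream vascular beds; named probes mark measurement sites (vessel +
fractional axial position).  Geometry and material data live on each
:class:`Vessel`; the tube-law stiffness is derived from them by the solver.

On disk a network is a CSV with one row per vessel (units: mm, kPa; outlet
resistance/compliance on the conventional 1e10 Pa s/m^3 and 1e-10 m^3/Pa
scales) plus a probes CSV and an optional JSON metadata sidecar.  All
quantities are SI in memory.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .units import MMHG_PA, PVC_SCALE, PVR_SCALE

ROLE_TAGS = ("systemic", "renal_main", "renal_segmental", "renal_interlobar")

#: sentinel for splitting total outlet resistance at the vessel's
#: characteristic impedance (minimises artificial wave reflections)
CHARACTERISTIC_IMPEDANCE = "characteristic-impedance"


class NetworkFormatError(ValueError):
    """Malformed network file; names the offending row and field."""

    def __init__(self, message, row=None, field=None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}"
        if field is not None:
            prefix += f" field '{field}'" if prefix else f"field '{field}'"
        super().__init__(f"{prefix}: {message}" if prefix else message)


@dataclass
class Vessel:
    """One elastic arterial segment with linear lumen taper."""

    id: str
    length: float  # m
    radius_proximal: float  # m
    radius_distal: float  # m
    wall_thickness: float  # m
    youngs_modulus: float  # Pa
    poisson_ratio: float = 0.5
    role_tag: str = "systemic"
    parent_id: str | None = None

    def reference_area(self, s: float = 0.0) -> float:
        """A0 at fractional axial position ``s`` (linear taper in radius)."""
        r = self.radius_proximal + (self.radius_distal - self.radius_proximal) * s
        return math.pi * r * r

    def findings(self) -> list[str]:
        out = []
        if not self.length > 0:
            out.append(f"vessel '{self.id}': length must be > 0")
        if not (self.radius_proximal > 0 and self.radius_distal > 0):
            out.append(f"vessel '{self.id}': radii must be > 0")
        elif self.radius_distal > self.radius_proximal * (1 + 1e-12):
            out.append(f"vessel '{self.id}': distal radius exceeds proximal radius")
        if not self.wall_thickness > 0:
            out.append(f"vessel '{self.id}': wall thickness must be > 0")
        if not self.youngs_modulus > 0:
            out.append(f"vessel '{self.id}': Young's modulus must be > 0")
        if not 0.0 < self.poisson_ratio < 1.0:
            out.append(f"vessel '{self.id}': Poisson ratio must lie in (0, 1)")
        if self.role_tag not in ROLE_TAGS:
            out.append(f"vessel '{self.id}': unknown role tag '{self.role_tag}'")
        return out


@dataclass
class WindkesselOutlet:
    """Lumped R-C-R peripheral bed attached to a terminal vessel.

    ``total_resistance`` is the PVR (R1 + R2) and ``compliance`` the PVC.
    The R1/R2 split defaults to matching R1 to the terminal vessel's
    characteristic impedance.
    """

    vessel_id: str
    total_resistance: float  # Pa s / m^3
    compliance: float  # m^3 / Pa
    proximal_resistance_fraction: float | str = CHARACTERISTIC_IMPEDANCE
    outflow_pressure: float = 0.0  # Pa

    def findings(self) -> list[str]:
        out = []
        if not self.total_resistance > 0:
            out.append(f"outlet '{self.vessel_id}': total resistance must be > 0")
        if not self.compliance > 0:
            out.append(f"outlet '{self.vessel_id}': compliance must be > 0")
        f = self.proximal_resistance_fraction
        if f != CHARACTERISTIC_IMPEDANCE and not (0.0 <= float(f) < 1.0):
            out.append(f"outlet '{self.vessel_id}': R1 fraction must be in [0, 1)")
        return out


@dataclass
class Junction:
    """Vessel ends meeting at a branching (or series) point."""

    parent_ids: list[str]
    child_ids: list[str]

    @property
    def arity(self) -> int:
        return len(self.parent_ids) + len(self.child_ids)


@dataclass
class Probe:
    name: str
    vessel_id: str
    fraction: float  # axial position in [0, 1]


@dataclass
class Network:
    vessels: dict[str, Vessel] = field(default_factory=dict)
    inlet_vessel_id: str | None = None
    outlets: dict[str, WindkesselOutlet] = field(default_factory=dict)
    probes: list[Probe] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- topology helpers -------------------------------------------------
    def children_map(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {vid: [] for vid in self.vessels}
        for v in self.vessels.values():
            if v.parent_id is not None and v.parent_id in ch:
                ch[v.parent_id].append(v.id)
        return ch

    @property
    def junctions(self) -> list[Junction]:
        return [
            Junction([pid], list(kids))
            for pid, kids in self.children_map().items()
            if kids
        ]

    def terminal_ids(self) -> list[str]:
        ch = self.children_map()
        return [vid for vid, kids in ch.items() if not kids]

    def renal_ids(self, side: str | None = None) -> list[str]:
        ids = [v.id for v in self.vessels.values() if v.role_tag.startswith("renal")]
        if side is not None:
            # renal ids end in a side token: renal_main_l, renal_seg_l3, ...
            ids = [i for i in ids if i.rsplit("_", 1)[-1].startswith(side)]
        return ids

    def probe(self, name: str) -> Probe:
        for p in self.probes:
            if p.name == name:
                return p
        raise KeyError(f"no probe named '{name}'")

    def scaled(self, *, length=None, radius=None, thickness=None,
               youngs_modulus=None, pvr=None, pvc=None) -> "Network":
        """Return a copy with per-vessel / per-outlet multiplicative factors.

        Each argument is either None, a scalar, or a mapping id -> factor.
        """
        def fac(spec, key):
            if spec is None:
                return 1.0
            if isinstance(spec, dict):
                return spec.get(key, 1.0)
            return float(spec)

        vessels = {}
        for vid, v in self.vessels.items():
            vessels[vid] = replace(
                v,
                length=v.length * fac(length, vid),
                radius_proximal=v.radius_proximal * fac(radius, vid),
                radius_distal=v.radius_distal * fac(radius, vid),
                wall_thickness=v.wall_thickness * fac(thickness, vid),
                youngs_modulus=v.youngs_modulus * fac(youngs_modulus, vid),
            )
        outlets = {}
        for oid, o in self.outlets.items():
            outlets[oid] = replace(
                o,
                total_resistance=o.total_resistance * fac(pvr, oid),
                compliance=o.compliance * fac(pvc, oid),
            )
        return Network(vessels, self.inlet_vessel_id, outlets,
                       list(self.probes), dict(self.metadata))


# -- validation ----------------------------------------------------------

def validate_network(net: Network) -> list[str]:
    """Structural validation.  Empty list iff all invariants hold."""
    findings: list[str] = []
    for v in net.vessels.values():
        findings.extend(v.findings())

    roots = [v.id for v in net.vessels.values() if v.parent_id is None]
    if len(roots) != 1:
        findings.append(f"network must have exactly one inlet vessel, found {len(roots)}: {roots}")
    if net.inlet_vessel_id is not None:
        if net.inlet_vessel_id not in net.vessels:
            findings.append(f"inlet vessel '{net.inlet_vessel_id}' does not exist")
        elif roots and net.inlet_vessel_id not in roots:
            findings.append(f"declared inlet '{net.inlet_vessel_id}' is not a root vessel")

    for v in net.vessels.values():
        if v.parent_id is not None and v.parent_id not in net.vessels:
            findings.append(f"vessel '{v.id}' references missing parent '{v.parent_id}'")

    # reachability from the inlet
    if len(roots) == 1:
        ch = net.children_map()
        seen = set()
        stack = [roots[0]]
        while stack:
            vid = stack.pop()
            if vid in seen:
                continue
            seen.add(vid)
            stack.extend(ch.get(vid, []))
        for vid in net.vessels:
            if vid not in seen:
                findings.append(f"vessel '{vid}' is not reachable from the inlet")

    ch = net.children_map()
    for vid, kids in ch.items():
        if vid not in net.vessels:
            continue
        if not kids and vid not in net.outlets:
            findings.append(f"terminal vessel '{vid}' has no outlet model")
        if kids and vid in net.outlets:
            findings.append(f"vessel '{vid}' has both children and an outlet model")
    for oid, o in net.outlets.items():
        if oid not in net.vessels:
            findings.append(f"outlet attached to missing vessel '{oid}'")
        findings.extend(o.findings())

    for p in net.probes:
        if p.vessel_id not in net.vessels:
            findings.append(f"probe '{p.name}' references missing vessel '{p.vessel_id}'")
        if not 0.0 <= p.fraction <= 1.0:
            findings.append(f"probe '{p.name}' axial fraction outside [0, 1]")

    # fixture metadata counts, when present
    meta = net.metadata
    if "n_vessels" in meta and meta["n_vessels"] != len(net.vessels):
        findings.append(
            f"metadata records {meta['n_vessels']} vessels, network has {len(net.vessels)}")
    if "n_outlets" in meta and meta["n_outlets"] != len(net.outlets):
        findings.append(
            f"metadata records {meta['n_outlets']} outlets, network has {len(net.outlets)}")
    return findings


# -- on-disk format ------------------------------------------------------

_COLUMNS = ["id", "parent_id", "length_mm", "r_prox_mm", "r_dist_mm",
            "h0_mm", "E_kPa", "nu", "role_tag", "outlet_R_total", "outlet_C",
            "outlet_R1_fraction", "outlet_Pout_mmHg"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _fmt_scaled(x: float, scale: float) -> str:
    """Serialize ``x`` as ``x/scale`` such that re-parsing times ``scale``
    reproduces ``x`` bit-for-bit (nudging one ulp when scaling rounds)."""
    c = x / scale
    up = down = c
    for _ in range(20):
        for cand in (up, down):
            if float(repr(cand)) * scale == x:
                return repr(cand)
        up = math.nextafter(up, math.inf)
        down = math.nextafter(down, -math.inf)
    return repr(c)


def _parse_float(raw, row, fieldname, positive=False):
    try:
        val = float(raw)
    except (TypeError, ValueError):
        raise NetworkFormatError(f"cannot parse '{raw}' as a number", row, fieldname)
    if positive and not val > 0:
        raise NetworkFormatError(f"value must be > 0, got {val}", row, fieldname)
    return val


def probes_path_for(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_probes.csv")


def metadata_path_for(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_meta.json")


def read_network(path) -> Network:
    """Read a network CSV (plus sibling probes/metadata files if present).

    Raises :class:`NetworkFormatError` naming the row and field for
    malformed input; structural invariants are checked after parsing.
    """
    path = Path(path)
    net = Network()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise NetworkFormatError(f"missing columns {missing}")
        for i, rec in enumerate(reader, start=2):
            vid = (rec["id"] or "").strip()
            if not vid:
                raise NetworkFormatError("empty vessel id", i, "id")
            if vid in net.vessels:
                raise NetworkFormatError(f"duplicate vessel id '{vid}'", i, "id")
            parent = (rec["parent_id"] or "").strip() or None
            if parent is not None and ";" in parent:
                raise NetworkFormatError(
                    "multiple parents are not supported by the tree format", i, "parent_id")
            v = Vessel(
                id=vid,
                parent_id=parent,
                length=_parse_float(rec["length_mm"], i, "length_mm", positive=True) * 1e-3,
                radius_proximal=_parse_float(rec["r_prox_mm"], i, "r_prox_mm", positive=True) * 1e-3,
                radius_distal=_parse_float(rec["r_dist_mm"], i, "r_dist_mm", positive=True) * 1e-3,
                wall_thickness=_parse_float(rec["h0_mm"], i, "h0_mm", positive=True) * 1e-3,
                youngs_modulus=_parse_float(rec["E_kPa"], i, "E_kPa", positive=True) * 1e3,
                poisson_ratio=_parse_float(rec["nu"], i, "nu"),
                role_tag=(rec["role_tag"] or "systemic").strip(),
            )
            bad = v.findings()
            if bad:
                raise NetworkFormatError("; ".join(bad), i)
            net.vessels[vid] = v
            r_raw = (rec["outlet_R_total"] or "").strip()
            c_raw = (rec["outlet_C"] or "").strip()
            if bool(r_raw) != bool(c_raw):
                raise NetworkFormatError(
                    "outlet needs both R and C (or neither)", i, "outlet_R_total")
            if r_raw:
                f_raw = (rec.get("outlet_R1_fraction") or "").strip()
                p_raw = (rec.get("outlet_Pout_mmHg") or "").strip()
                net.outlets[vid] = WindkesselOutlet(
                    vessel_id=vid,
                    total_resistance=_parse_float(r_raw, i, "outlet_R_total", positive=True) * PVR_SCALE,
                    compliance=_parse_float(c_raw, i, "outlet_C", positive=True) * PVC_SCALE,
                    proximal_resistance_fraction=(
                        _parse_float(f_raw, i, "outlet_R1_fraction")
                        if f_raw else CHARACTERISTIC_IMPEDANCE),
                    outflow_pressure=(
                        _parse_float(p_raw, i, "outlet_Pout_mmHg") * MMHG_PA
                        if p_raw else 0.0),
                )

    roots = [v.id for v in net.vessels.values() if v.parent_id is None]
    net.inlet_vessel_id = roots[0] if len(roots) == 1 else None

    ppath = probes_path_for(path)
    if ppath.exists():
        with open(ppath, newline="") as fh:
            for i, rec in enumerate(csv.DictReader(fh), start=2):
                net.probes.append(Probe(
                    name=rec["probe_name"].strip(),
                    vessel_id=rec["vessel_id"].strip(),
                    fraction=_parse_float(rec["axial_fraction"], i, "axial_fraction"),
                ))
    mpath = metadata_path_for(path)
    if mpath.exists():
        net.metadata = json.loads(mpath.read_text())

    findings = validate_network(net)
    if findings:
        raise NetworkFormatError("invalid network: " + "; ".join(findings))
    return net


def write_network(net: Network, path) -> None:
    """Write ``net`` (and its probes/metadata) so that a read round-trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for v in net.vessels.values():
            o = net.outlets.get(v.id)
            w.writerow([
                v.id, v.parent_id or "",
                _fmt_scaled(v.length, 1e-3), _fmt_scaled(v.radius_proximal, 1e-3),
                _fmt_scaled(v.radius_distal, 1e-3), _fmt_scaled(v.wall_thickness, 1e-3),
                _fmt_scaled(v.youngs_modulus, 1e3), _fmt(v.poisson_ratio), v.role_tag,
                _fmt_scaled(o.total_resistance, PVR_SCALE) if o else "",
                _fmt_scaled(o.compliance, PVC_SCALE) if o else "",
                ("" if o is None
                 or o.proximal_resistance_fraction == CHARACTERISTIC_IMPEDANCE
                 else _fmt(o.proximal_resistance_fraction)),
                ("" if o is None or o.outflow_pressure == 0.0
                 else _fmt_scaled(o.outflow_pressure, MMHG_PA)),
            ])
    with open(probes_path_for(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["probe_name", "vessel_id", "axial_fraction"])
        for p in net.probes:
            w.writerow([p.name, p.vessel_id, _fmt(p.fraction)])
    if net.metadata:
        metadata_path_for(path).write_text(json.dumps(net.metadata, indent=1))
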