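"""Network data model, on-disk format and the baseline fixture."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renalpulse import (Network, Probe, Vessel, WindkesselOutlet,
                        build_baseline_network, load_baseline_network,
                        read_network, validate_network, write_network)
from renalpulse.network import NetworkFormatError


TOY_CSV = """id,parent_id,length_mm,r_prox_mm,r_dist_mm,h0_mm,E_kPa,nu,role_tag,outlet_R_total,outlet_C,outlet_R1_fraction,outlet_Pout_mmHg
root,,100.0,5.0,4.0,1.0,400.0,0.5,systemic,,,,
child,root,80.0,3.0,2.5,0.8,450.0,0.5,systemic,0.5,1.0,0.2,
"""


def write_toy(tmp_path, text=TOY_CSV, name="toy.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadNetwork:
    def test_two_vessel_toy(self, tmp_path):
        net = read_network(write_toy(tmp_path))
        assert len(net.vessels) == 2
        assert len(net.junctions) == 1
        assert len(net.outlets) == 1
        # SI conversion
        assert net.vessels["root"].length == pytest.approx(0.1)
        assert net.outlets["child"].total_resistance == pytest.approx(0.5e10)
        assert net.outlets["child"].compliance == pytest.approx(1.0e-10)

    def test_zero_length_names_vessel(self, tmp_path):
        bad = TOY_CSV.replace("child,root,80.0", "child,root,0.0")
        with pytest.raises(NetworkFormatError, match="length_mm"):
            read_network(write_toy(tmp_path, bad))

    def test_duplicate_id(self, tmp_path):
        bad = TOY_CSV + "child,root,10.0,1.0,1.0,0.5,400.0,0.5,systemic,1.0,0.1\n"
        with pytest.raises(NetworkFormatError, match="duplicate"):
            read_network(write_toy(tmp_path, bad))

    def test_dangling_parent(self, tmp_path):
        bad = TOY_CSV.replace("child,root", "child,ghost")
        with pytest.raises(NetworkFormatError):
            read_network(write_toy(tmp_path, bad))

    def test_malformed_number_names_row_and_field(self, tmp_path):
        bad = TOY_CSV.replace("80.0", "eighty")
        with pytest.raises(NetworkFormatError, match="length_mm"):
            read_network(write_toy(tmp_path, bad))


class TestValidate:
    def test_orphan_vessel(self):
        net = Network()
        net.vessels["a"] = Vessel("a", 0.1, 5e-3, 5e-3, 1e-3, 4e5)
        net.vessels["b"] = Vessel("b", 0.1, 3e-3, 3e-3, 1e-3, 4e5,
                                  parent_id="a")
        net.vessels["orphan"] = Vessel("orphan", 0.1, 3e-3, 3e-3, 1e-3, 4e5,
                                       parent_id="ghost")
        net.inlet_vessel_id = "a"
        net.outlets["b"] = WindkesselOutlet("b", 1e9, 1e-10)
        net.outlets["orphan"] = WindkesselOutlet("orphan", 1e9, 1e-10)
        findings = validate_network(net)
        assert any("orphan" in f for f in findings)

    def test_two_inlets(self):
        net = Network()
        for vid in ("a", "b"):
            net.vessels[vid] = Vessel(vid, 0.1, 5e-3, 5e-3, 1e-3, 4e5)
            net.outlets[vid] = WindkesselOutlet(vid, 1e9, 1e-10)
        findings = validate_network(net)
        assert any("exactly one inlet" in f for f in findings)

    def test_distal_radius_must_not_exceed_proximal(self):
        v = Vessel("x", 0.1, 3e-3, 4e-3, 1e-3, 4e5)
        assert any("distal radius" in f for f in v.findings())


# strategy: small trees with on-grid (mm / kPa) values
_mm = st.floats(0.5, 30.0).map(lambda x: round(x, 4))
_len = st.floats(5.0, 500.0).map(lambda x: round(x, 3))


@st.composite
def small_trees(draw):
    n = draw(st.integers(1, 7))
    net = Network()
    for i in range(n):
        rp = draw(_mm)
        rd = rp * draw(st.floats(0.5, 1.0).map(lambda x: round(x, 3)))
        parent = None if i == 0 else f"v{draw(st.integers(0, i - 1))}"
        net.vessels[f"v{i}"] = Vessel(
            f"v{i}", draw(_len) * 1e-3, rp * 1e-3, max(rd, 0.25) * 1e-3,
            draw(st.floats(0.1, 3.0).map(lambda x: round(x, 3))) * 1e-3,
            draw(st.floats(100.0, 2000.0).map(lambda x: round(x, 2))) * 1e3,
            role_tag=draw(st.sampled_from(("systemic", "renal_interlobar"))),
            parent_id=parent)
    net.inlet_vessel_id = "v0"
    for tid in net.terminal_ids():
        net.outlets[tid] = WindkesselOutlet(
            tid, draw(st.floats(0.01, 20.0).map(lambda x: round(x, 6))) * 1e10,
            draw(st.floats(0.01, 3.0).map(lambda x: round(x, 6))) * 1e-10)
    if draw(st.booleans()):
        net.probes.append(Probe("probe0", "v0",
                                draw(st.floats(0, 1).map(lambda x: round(x, 3)))))
    return net


class TestRoundTrip:
    @settings(max_examples=40, deadline=None)
    @given(small_trees())
    def test_write_read_identity(self, tmp_path_factory, net):
        path = tmp_path_factory.mktemp("rt") / "net.csv"
        write_network(net, path)
        back = read_network(path)
        assert back.vessels == net.vessels
        assert back.outlets == net.outlets
        assert back.probes == net.probes
        assert back.inlet_vessel_id == net.inlet_vessel_id

    def test_baseline_round_trip(self, tmp_path, baseline_net):
        path = tmp_path / "baseline.csv"
        write_network(baseline_net, path)
        back = read_network(path)
        assert back.vessels == baseline_net.vessels
        assert back.outlets == baseline_net.outlets
        assert back.probes == baseline_net.probes


class TestBaselineFixture:
    def test_counts(self, baseline_net):
        net = baseline_net
        assert len(net.vessels) == 113
        assert len(net.renal_ids("l")) == 38
        assert len(net.renal_ids("r")) == 38
        for side in ("l", "r"):
            seg = [v for v in net.vessels.values()
                   if v.role_tag == "renal_segmental"
                   and v.id in net.renal_ids(side)]
            assert len(seg) == 5
        roots = [v for v in net.vessels.values() if v.parent_id is None]
        assert len(roots) == 1 and roots[0].id == net.inlet_vessel_id
        # metadata records the actual outlet count and is self-consistent
        assert net.metadata["n_outlets"] == len(net.outlets)
        assert net.metadata["n_vessels"] == 113

    def test_validates_clean(self, baseline_net):
        assert validate_network(baseline_net) == []

    def test_named_model_values(self, baseline_net):
        v = baseline_net.vessels
        assert v["renal_main_l"].radius_proximal == pytest.approx(2.71e-3)
        assert v["renal_main_l"].wall_thickness == pytest.approx(0.54e-3)
        assert v["aorta_asc"].radius_proximal == pytest.approx(15.95e-3)
        assert v["aorta_abd_b"].radius_proximal == pytest.approx(7.49e-3)
        assert v["carotid_common_l"].radius_proximal == pytest.approx(3.17e-3)
        assert v["carotid_common_l"].wall_thickness == pytest.approx(0.70e-3)
        assert v["radial_l"].radius_proximal == pytest.approx(1.38e-3)
        assert v["aorta_thor_a"].wall_thickness == pytest.approx(2.12e-3)
        E = [x.youngs_modulus for x in v.values()]
        assert min(E) >= 400e3 and max(E) <= 500e3

    def test_outlet_parameter_ranges(self, baseline_net):
        R = [o.total_resistance for o in baseline_net.outlets.values()]
        C = [o.compliance for o in baseline_net.outlets.values()]
        assert min(R) >= 0.11e10 and max(R) <= 17.20e10
        assert min(C) >= 0.02e-10 and max(C) <= 2.60e-10

    def test_renal_radii_decrease_by_generation(self, baseline_net):
        v = baseline_net.vessels
        chain = ["renal_main_l", "renal_seg_l1", "renal_il1_l1a",
                 "renal_il2_l1a1", "renal_il3_l1"]
        radii = [v[c].radius_proximal for c in chain]
        assert all(a > b for a, b in zip(radii, radii[1:]))
        # Murray's law at the pentafurcation: r_main^3 = 5 r_seg^3
        assert v["renal_seg_l1"].radius_proximal == pytest.approx(
            v["renal_main_l"].radius_proximal / 5 ** (1 / 3), rel=1e-3)

    def test_probes(self, baseline_net):
        names = {p.name for p in baseline_net.probes}
        assert "renal_main_l" in names and "renal_main_r" in names
        assert "brachial" in names
        assert sum(1 for n in names if n.startswith("renal_seg_")) == 10

    def test_packaged_csv_matches_programmatic_build(self, baseline_net):
        packaged = load_baseline_network()
        assert packaged.vessels == baseline_net.vessels
        assert packaged.outlets == baseline_net.outlets
        assert packaged.probes == baseline_net.probes
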