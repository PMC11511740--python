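"""Shared fixtures.

The expensive session fixtures (baseline simulation, the shared
scaled-down study) are computed once and reused by the solver oracles and
the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from renalpulse import (BloodProperties, InletWaveform, Network,
                        NumericsConfig, Probe, Vessel, WindkesselOutlet,
                        build_baseline_network, generate_inlet_waveform,
                        run_simulation)
from renalpulse.baseline import BASELINE_CO_LMIN
from renalpulse.units import lmin_to_m3s


def make_single_vessel_network(length=0.2, radius=5e-3, h=1.0e-3,
                               E=4.0e5, R_total=1.6e9, C=1.0e-10,
                               r1_fraction=None, probes=(0.5,)) -> Network:
    """One uniform vessel with an R-C-R outlet."""
    net = Network()
    net.vessels["v0"] = Vessel("v0", length, radius, radius, h, E)
    net.inlet_vessel_id = "v0"
    out = WindkesselOutlet("v0", R_total, C)
    if r1_fraction is not None:
        out.proximal_resistance_fraction = r1_fraction
    net.outlets["v0"] = out
    net.probes = [Probe(f"p{i}", "v0", f) for i, f in enumerate(probes)]
    return net


def make_bifurcation_network(child_radius=3e-3, child_radius2=None) -> Network:
    """Parent bifurcating into two children (symmetric by default)."""
    r2 = child_radius2 if child_radius2 is not None else child_radius
    net = Network()
    net.vessels["parent"] = Vessel("parent", 0.1, 5e-3, 5e-3, 1.0e-3, 4.0e5)
    net.vessels["c1"] = Vessel("c1", 0.1, child_radius, child_radius,
                               0.7e-3, 4.0e5, parent_id="parent")
    net.vessels["c2"] = Vessel("c2", 0.1, r2, r2, 0.7e-3, 4.0e5,
                               parent_id="parent")
    net.inlet_vessel_id = "parent"
    for cid in ("c1", "c2"):
        net.outlets[cid] = WindkesselOutlet(cid, 3.2e9, 1.0e-10)
    net.probes = [Probe("parent_end", "parent", 1.0),
                  Probe("c1_mid", "c1", 0.5), Probe("c2_mid", "c2", 0.5)]
    return net


def constant_inflow(q, period=0.8, n=64) -> InletWaveform:
    return InletWaveform(period, np.full(n, float(q)), float(q))


@pytest.fixture(scope="session")
def baseline_net():
    return build_baseline_network()


@pytest.fixture(scope="session")
def baseline_sim(baseline_net):
    inlet = generate_inlet_waveform(lmin_to_m3s(BASELINE_CO_LMIN), 70.0)
    return run_simulation(baseline_net, inlet)


#: population sizes of the shared scaled-down study used by the
#: acceptance tests (small enough to keep the default suite in budget)
STUDY_SIZES = {"20-29": 36, "30-39": 10, "40-49": 10,
               "50-59": 44, "60-69": 10, "70-79": 36}


@pytest.fixture(scope="session")
def shared_study():
    """One scaled-down end-to-end study shared by all acceptance tests."""
    from renalpulse.pipeline import acceptance_study

    return acceptance_study(seed=20240705, n_per_group=STUDY_SIZES,
                            stage_cap=8, roc_cap=24)
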