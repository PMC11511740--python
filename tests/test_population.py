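"""Virtual-population sampling, disease scaling and the physiology filter."""

import numpy as np
import pandas as pd
import pytest

from renalpulse.population import (AGE_GROUPS, AgeingDistributionTable,
                                   apply_disease_scaling, load_ageing_table,
                                   load_disease_scalings, physiology_filter,
                                   sample_ageing_subjects)


@pytest.fixture(scope="module")
def table():
    return load_ageing_table()


@pytest.fixture(scope="module")
def scalings():
    return load_disease_scalings()


class TestAgeingTable:
    def test_printed_values(self, table):
        assert table.mean_sd("70-79", "youngs_modulus") == (2.00, 0.45)
        assert table.mean_sd("20-29", "cardiac_output") == (1.00, 0.22)
        assert table.mean_sd("20-29", "sbp_mmhg") == (120, 11)
        assert table.mean_sd("50-59", "pvc") == (0.65, 0.18)

    def test_all_groups_present(self, table):
        for g in AGE_GROUPS:
            assert g in table.params

    def test_rejects_missing_group(self):
        with pytest.raises(ValueError, match="missing age groups"):
            AgeingDistributionTable({"20-29": {"cardiac_output": (1.0, 0.2)}})


class TestSampling:
    def test_sampled_moments_recover_table(self, baseline_net, table):
        # pooled per-vessel draws: ~18 subjects x 113 vessels > 2000 draws
        subs = sample_ageing_subjects(table, "70-79", 18, seed=3,
                                      baseline=baseline_net)
        draws = np.array([f for s in subs
                          for f in s.factors.youngs_modulus.values()])
        m, sd = table.mean_sd("70-79", "youngs_modulus")
        n = len(draws)
        assert n >= 2000
        assert abs(draws.mean() - m) < 3 * sd / np.sqrt(n)
        assert abs(draws.std() - sd) < 3 * sd / np.sqrt(2 * n)

    def test_truncation_bounds(self, baseline_net, table):
        subs = sample_ageing_subjects(table, "20-29", 10, seed=5,
                                      baseline=baseline_net)
        for s in subs:
            for param in ("length", "radius", "youngs_modulus", "thickness"):
                m, sd = table.mean_sd("20-29", param)
                vals = np.array(list(getattr(s.factors, param).values()))
                assert np.all(vals > 0) and np.all(vals <= m + 4 * sd)

    def test_determinism(self, baseline_net, table):
        a = sample_ageing_subjects(table, "40-49", 4, seed=11,
                                   baseline=baseline_net)
        b = sample_ageing_subjects(table, "40-49", 4, seed=11,
                                   baseline=baseline_net)
        for x, y in zip(a, b):
            assert x.factors == y.factors
        c = sample_ageing_subjects(table, "40-49", 4, seed=12,
                                   baseline=baseline_net)
        assert any(x.factors != y.factors for x, y in zip(a, c))

    def test_zero_sd_degenerates_to_means(self, baseline_net):
        params = {g: {p: (1.0 if p not in ("sbp_mmhg", "dbp_mmhg") else 120.0,
                          0.0)
                      for p in ("cardiac_output", "length", "radius",
                                "youngs_modulus", "thickness", "pvr", "pvc",
                                "sbp_mmhg", "dbp_mmhg")}
                  for g in AGE_GROUPS}
        degenerate = AgeingDistributionTable(params)
        subs = sample_ageing_subjects(degenerate, "20-29", 3, seed=1,
                                      baseline=baseline_net)
        for s in subs:
            assert s.factors.cardiac_output == 1.0
            assert all(v == 1.0 for v in s.factors.radius.values())
            net = s.materialize(baseline_net)
            assert net.vessels == baseline_net.vessels

    def test_invalid_age_group(self, baseline_net, table):
        with pytest.raises(ValueError, match="age group"):
            sample_ageing_subjects(table, "90-99", 2, seed=1,
                                   baseline=baseline_net)


class TestDiseaseScaling:
    def test_calibrated_point_values(self, scalings):
        ed, sd = scalings["Early.D"], scalings["Severe.D"]
        eh, sh = scalings["Early.H"], scalings["Severe.H"]
        assert (ed.viscosity, ed.cardiac_output, ed.pvr, ed.pvc) == \
            (1.10, 0.85, 1.20, 0.82)
        assert (sd.viscosity, sd.cardiac_output, sd.pvr, sd.pvc) == \
            (1.20, 0.70, 1.40, 0.80)
        assert (eh.cardiac_output, eh.pvr, eh.pvc) == (1.15, 1.15, 0.86)
        assert (sh.pvr, sh.pvc) == (1.35, 0.70)
        # named overrides
        assert eh.radius_factor("aorta_asc") == 0.95
        assert eh.radius_factor("renal_main_l") == 0.98
        assert sh.radius_factor("aorta_asc") == 0.93
        assert sh.thickness_factor("aorta_thor_a") == 1.10
        assert sh.thickness_factor("renal_main_l") == 1.05

    def test_renal_radius_scaling_example(self, baseline_net, table, scalings):
        # 2.71 mm renal artery under the early-diabetes multiplier (x0.95)
        subs = sample_ageing_subjects(table, "20-29", 1, seed=2,
                                      baseline=baseline_net)
        s = subs[0]
        s.factors.radius = {k: 1.0 for k in s.factors.radius}
        diseased = apply_disease_scaling(s, scalings["Early.D"])
        net = diseased.materialize(baseline_net)
        assert net.vessels["renal_main_l"].radius_proximal == \
            pytest.approx(2.5745e-3, rel=1e-9)

    def test_viscosity_example(self, baseline_net, table, scalings):
        subs = sample_ageing_subjects(table, "20-29", 1, seed=2,
                                      baseline=baseline_net)
        diseased = apply_disease_scaling(subs[0], scalings["Severe.D"])
        # 4.00 mPa s x 1.20 = 4.80 mPa s
        assert 4.0e-3 * diseased.factors.viscosity == pytest.approx(4.8e-3)

    def test_identity_scaling_is_noop(self, baseline_net, table):
        from renalpulse.population import DiseaseScaling
        ident = DiseaseScaling("Early.D")
        subs = sample_ageing_subjects(table, "30-39", 1, seed=9,
                                      baseline=baseline_net)
        out = apply_disease_scaling(subs[0], ident)
        for attr in ("cardiac_output", "viscosity"):
            assert getattr(out.factors, attr) == getattr(subs[0].factors, attr)
        for attr in ("radius", "youngs_modulus", "thickness", "pvr", "pvc"):
            assert getattr(out.factors, attr) == getattr(subs[0].factors, attr)

    def test_double_application_rejected(self, baseline_net, table, scalings):
        subs = sample_ageing_subjects(table, "30-39", 1, seed=9,
                                      baseline=baseline_net)
        once = apply_disease_scaling(subs[0], scalings["Early.D"])
        with pytest.raises(ValueError, match="healthy"):
            apply_disease_scaling(once, scalings["Severe.D"])

    def test_scaling_commutes_with_materialization(self, baseline_net, table,
                                                   scalings):
        subs = sample_ageing_subjects(table, "50-59", 1, seed=4,
                                      baseline=baseline_net)
        s = subs[0]
        sc = scalings["Severe.H"]
        # factors then materialize
        net_a = apply_disease_scaling(s, sc).materialize(baseline_net)
        # materialize then scale dimensional values
        net_b = s.materialize(baseline_net).scaled(
            radius={k: sc.radius_factor(k) for k in baseline_net.vessels},
            youngs_modulus={k: sc.youngs_factor(k) for k in baseline_net.vessels},
            thickness={k: sc.thickness_factor(k) for k in baseline_net.vessels},
            pvr={k: sc.pvr_factor(k) for k in baseline_net.outlets},
            pvc={k: sc.pvc_factor(k) for k in baseline_net.outlets})
        for vid in baseline_net.vessels:
            va, vb = net_a.vessels[vid], net_b.vessels[vid]
            assert va.radius_proximal == pytest.approx(vb.radius_proximal, rel=1e-12)
            assert va.youngs_modulus == pytest.approx(vb.youngs_modulus, rel=1e-12)
            assert va.wall_thickness == pytest.approx(vb.wall_thickness, rel=1e-12)


class TestPhysiologyFilter:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "age_group",
                                           "sbp_mmhg", "dbp_mmhg"])

    def test_group_means_are_kept(self, table):
        rec = self.frame([("a", "20-29", 120.0, 74.0)])
        kept, report = physiology_filter(rec, table)
        assert list(kept["subject_id"]) == ["a"]
        assert report["keep_rate"].iloc[0] == 1.0

    def test_sbp_150_removed_in_youngest_group(self, table):
        # bound: 120 + 2.575 * 11 = 148.325 < 150
        rec = self.frame([("a", "20-29", 150.0, 74.0),
                          ("b", "20-29", 148.0, 74.0)])
        kept, _ = physiology_filter(rec, table)
        assert list(kept["subject_id"]) == ["b"]

    def test_zero_sd_keeps_only_exact_means(self):
        params = {g: {"sbp_mmhg": (120.0, 0.0), "dbp_mmhg": (74.0, 0.0),
                      "cardiac_output": (1.0, 0.1)}
                  for g in AGE_GROUPS}
        tight = AgeingDistributionTable(params)
        rec = self.frame([("a", "20-29", 120.0, 74.0),
                          ("b", "20-29", 120.1, 74.0)])
        kept, _ = physiology_filter(rec, tight)
        assert list(kept["subject_id"]) == ["a"]

    def test_idempotent_and_order_independent(self, table):
        rng = np.random.default_rng(0)
        rows = [(f"s{i}", "50-59", float(rng.normal(124, 25)),
                 float(rng.normal(77, 15))) for i in range(200)]
        rec = self.frame(rows)
        kept1, _ = physiology_filter(rec, table)
        kept2, _ = physiology_filter(kept1, table)
        assert list(kept1["subject_id"]) == list(kept2["subject_id"])
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        kept3, _ = physiology_filter(shuffled, table)
        assert set(kept3["subject_id"]) == set(kept1["subject_id"])

    def test_missing_pressures_raise(self, table):
        rec = self.frame([("a", "20-29", np.nan, 74.0)])
        with pytest.raises(ValueError, match="missing pressures"):
            physiology_filter(rec, table)
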