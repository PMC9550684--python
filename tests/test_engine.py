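import dataclasses

import numpy as np
import pandas as pd
import pytest

import tumorsim as ts
from tumorsim.engine import SimulationTrajectory
from tumorsim.pkpd import Administration, Regimen


def _short_case(small_phantom, sensitivity=1.0, dose=120.0, surgery=24.0,
                n_doses=2, spacing=7.0):
    lat, pmap, rho = small_phantom
    ads = []
    for c in range(n_doses):
        ads += [Administration("docetaxel", dose, spacing * c),
                Administration("cyclophosphamide", dose * 8, spacing * c)]
    reg = Regimen(ads, surgery_day=surgery)
    return ts.CaseRecord(
        "s", 50.0, "Other", "T2", "N0", 0.0, 0.0, False, 3,
        "Invasive Ductal Carcinoma", "TNBC",
        sensitivity={d: sensitivity for d in reg.drugs()},
        lattice=lat, perfusion=pmap, density=rho.copy(), regimen=reg)


class TestRunCase:
    def test_frozen_dynamics_constant_volume(self, small_phantom, fast_sim_config):
        """No growth (mu_max ~ 0) and no kill (zero sensitivity): the volume
        trajectory is flat."""
        case = _short_case(small_phantom, sensitivity=0.0)
        cfg = dataclasses.replace(
            fast_sim_config, metabolic=ts.MetabolicParameters(mu_max=1e-12))
        traj = ts.run_case(case, cfg)
        assert np.allclose(traj.volumes_cm3, traj.v_initial)

    def test_overwhelming_drug_reaches_pcr(self, small_phantom, fast_sim_config):
        """Sustained exposure far above IC50 clears a ~1 cm³ phantom before
        surgery."""
        case = _short_case(small_phantom, sensitivity=30.0, n_doses=4,
                           spacing=7.0, surgery=42.0)
        assert case.density is not None
        traj = ts.run_case(case, fast_sim_config)
        pred = ts.classify_pcr(traj)
        assert traj.v_initial > 0.1
        assert pred.predicted_class == "pCR"
        assert traj.v_final < ts.PCR_VOLUME_CM3

    def test_doubling_dose_never_increases_final_volume(self, small_phantom,
                                                        fast_sim_config):
        base = _short_case(small_phantom, sensitivity=0.9, dose=120.0)
        double = _short_case(small_phantom, sensitivity=0.9, dose=240.0)
        v1 = ts.run_case(base, fast_sim_config).v_final
        v2 = ts.run_case(double, fast_sim_config).v_final
        assert v2 <= v1

    def test_deterministic_bit_identical(self, small_phantom, fast_sim_config):
        case = _short_case(small_phantom, sensitivity=1.1)
        t1 = ts.run_case(case, fast_sim_config)
        t2 = ts.run_case(case, fast_sim_config)
        assert np.array_equal(t1.volumes_cm3, t2.volumes_cm3)
        assert np.array_equal(t1.times_days, t2.times_days)

    def test_trajectory_extends_to_surgery_day(self, small_phantom, fast_sim_config):
        case = _short_case(small_phantom, surgery=30.0)
        traj = ts.run_case(case, fast_sim_config)
        assert traj.times_days[0] == 0.0
        assert traj.times_days[-1] == pytest.approx(30.0)
        assert np.all(np.diff(traj.times_days) > 0)

    def test_mesh_and_bookkeeping_agree_on_initial_volume(self, small_phantom):
        case = _short_case(small_phantom, sensitivity=1.0, n_doses=1, surgery=7.0)
        mesh_traj = ts.run_case(case, ts.SimConfig(mechanics_mode="mesh"))
        book_traj = ts.run_case(case, ts.SimConfig(mechanics_mode="bookkeeping"))
        assert mesh_traj.v_initial == book_traj.v_initial

    def test_kill_max_monotonicity(self, small_phantom, fast_sim_config):
        """Final volume is non-increasing in kill_max on a fixed phantom."""
        finals = []
        for scale in (0.5, 1.0, 2.0):
            lib = {k: dataclasses.replace(d, kill_max=d.kill_max * scale)
                   for k, d in ts.load_drug_library().items()}
            case = _short_case(small_phantom, sensitivity=0.9)
            finals.append(ts.run_case(case, fast_sim_config, lib).v_final)
        assert finals[0] >= finals[1] >= finals[2]

    def test_ic50_monotonicity(self, small_phantom, fast_sim_config):
        """Final volume is non-decreasing in IC50 on a fixed phantom."""
        finals = []
        for scale in (0.5, 1.0, 2.0):
            lib = {k: dataclasses.replace(d, IC50=d.IC50 * scale)
                   for k, d in ts.load_drug_library().items()}
            case = _short_case(small_phantom, sensitivity=0.9)
            finals.append(ts.run_case(case, fast_sim_config, lib).v_final)
        assert finals[0] <= finals[1] <= finals[2]

    def test_missing_inputs_rejected(self):
        case = ts.CaseRecord("x", 50.0, "Other", "T1", "N0", 0.0, 0.0, False, 2,
                             "Invasive Ductal Carcinoma", "TNBC")
        with pytest.raises(ValueError, match="must carry"):
            ts.run_case(case)


class TestClassifyPcr:
    @staticmethod
    def _traj(v0, vf):
        return SimulationTrajectory(np.array([0.0, 100.0]), np.array([v0, vf]))

    def test_absolute_volume_rule(self):
        pred = ts.classify_pcr(self._traj(10.0, 0.009))
        assert pred.predicted_class == "pCR" and pred.rule_fired == "absolute_volume"

    def test_percent_reduction_rule_despite_volume(self):
        # 99.92% reduction with Vf above the absolute threshold
        pred = ts.classify_pcr(self._traj(50.0, 0.04))
        assert pred.predicted_class == "pCR" and pred.rule_fired == "percent_reduction"

    def test_just_outside_both_thresholds(self):
        pred = ts.classify_pcr(self._traj(10.0, 0.011))  # 99.89% reduction
        assert pred.predicted_class == "residual" and pred.rule_fired == "none"

    def test_boundary_volume_exactly_at_threshold_is_residual(self):
        # Vf = 0.01 exactly: strict < fails; reduction 99.8% < 99.9 fails
        pred = ts.classify_pcr(self._traj(5.0, 0.01))
        assert pred.predicted_class == "residual"

    def test_boundary_reduction_exactly_999_is_pcr(self):
        # V0 = 100, Vf = 0.1: reduction exactly 99.9% (inclusive)
        pred = ts.classify_pcr(self._traj(100.0, 0.1))
        assert pred.predicted_class == "pCR"
        assert pred.rule_fired == "percent_reduction"
        assert pred.percent_reduction == pytest.approx(99.9)

    def test_degenerate_baseline_flagged(self):
        pred = ts.classify_pcr(self._traj(0.005, 0.005))
        assert pred.predicted_class == "pCR"
        assert "degenerate" in pred.flag


class TestCompareToFollowups:
    @staticmethod
    def _traj():
        days = np.arange(0.0, 101.0)
        vols = np.linspace(10.0, 4.0, 101)
        return SimulationTrajectory(days, vols)

    def test_exact_observations_zero_error(self):
        traj = self._traj()
        fus = [(20.0, traj.volumes_cm3[20]), (60.0, traj.volumes_cm3[60])]
        table = ts.compare_to_followups(traj, fus)
        assert np.allclose(table["error_pct_of_initial"], 0.0)

    def test_definition_arithmetic(self):
        traj = SimulationTrajectory(np.array([0.0, 60.0]), np.array([10.0, 4.0]))
        table = ts.compare_to_followups(traj, [(60.0, 5.0)])
        assert table["error_pct_of_initial"].iloc[0] == pytest.approx(10.0)

    def test_empty_followups_empty_table(self):
        table = ts.compare_to_followups(self._traj(), [])
        assert len(table) == 0

    def test_out_of_range_day_snaps_with_flag(self):
        table = ts.compare_to_followups(self._traj(), [(150.0, 4.0)])
        assert table["matched_day"].iloc[0] == 100.0
        assert table["flag"].iloc[0] == "nearest-day"

    def test_degenerate_initial_volume_rejected(self):
        traj = SimulationTrajectory(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            ts.compare_to_followups(traj, [(1.0, 0.0)])


class TestCaseRecordValidation:
    def test_subtype_must_match_receptors(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ts.CaseRecord("x", 50.0, "Other", "T1", "N0", 80.0, 0.0, False, 2,
                          "Invasive Ductal Carcinoma", "TNBC")

    def test_er_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="ER/PR"):
            ts.CaseRecord("x", 50.0, "Other", "T1", "N0", 120.0, 0.0, False, 2,
                          "Invasive Ductal Carcinoma", "HR+/HER2-")

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            SimulationTrajectory(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            SimulationTrajectory(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
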