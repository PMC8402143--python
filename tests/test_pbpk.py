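import dataclasses

import numpy as np
import pytest

from panapk import defaults as d
from panapk.nca import ConcentrationProfile, run_nca
from panapk.parameterization import (kidney_kp_model, well_stirred_clearance)
from panapk.pbpk import (DoseEvent, DoseRegimen, SolverSettings,
                         bolus_regimen, build_model, infusion_regimen,
                         simulate, steady_state_kpss)
from panapk.physiology import default_rat_physiology

from conftest import CONTROL_BW, paper_grid, zero_kidney

BALANCE_TOL = 1e-6


def dense_grid(t_end=2000.0, n=400):
    return np.unique(np.concatenate([[0.0], np.geomspace(0.01, t_end, n)]))


class TestMassBalance:
    def test_bolus(self, control_model, control_dose):
        grid = np.unique(np.concatenate([paper_grid(), [720.0, 1440.0]]))
        res = simulate(control_model, bolus_regimen(control_dose), grid)
        assert np.nanmax(np.abs(res.mass_balance_error(d.PA))) < BALANCE_TOL
        assert np.nanmax(np.abs(res.mass_balance_error(d.NAPA)[1:])) \
            < BALANCE_TOL

    def test_loading_dose_plus_infusion(self, control_model):
        rate = d.INFUSION_RATE_MG_PER_KG_H * CONTROL_BW * 1000.0 / 60.0
        reg = infusion_regimen(1.4 * CONTROL_BW * 1000.0, rate, 60.0)
        grid = np.linspace(0.0, 120.0, 61)
        res = simulate(control_model, reg, grid)
        assert np.nanmax(np.abs(res.mass_balance_error(d.PA))) < BALANCE_TOL

    def test_zero_dose_gives_zero_trajectories(self, control_model):
        reg = bolus_regimen(0.0)
        res = simulate(control_model, reg, np.linspace(0.0, 480.0, 20))
        for drug in d.DRUGS:
            assert np.all(res.amounts[drug] == 0.0)

    def test_everything_eliminated_at_long_time(self, control_model,
                                                control_dose):
        grid = np.array([0.0, 100.0, 20000.0])
        res = simulate(control_model, bolus_regimen(control_dose), grid)
        remaining = res.amounts[d.PA][-1, :14].sum()
        assert remaining < 1e-4 * control_dose
        eliminated = (res.cumulative_urine(d.PA)[-1]
                      + res.cumulative_hepatic(d.PA)[-1])
        assert eliminated == pytest.approx(control_dose, rel=1e-6)


class TestClosedFormChecks:
    def test_hepatic_only_clearance_matches_well_stirred(self, control_tables,
                                                         control_dose):
        """With all renal pathways removed, dose/AUC equals the forward
        well-stirred hepatic clearance."""
        pa, napa = control_tables
        phys = default_rat_physiology(CONTROL_BW,
                                      config={"gfr_ml_min_kg": 1e-12})
        model = build_model(phys, zero_kidney(pa), zero_kidney(napa))
        grid = dense_grid()
        res = simulate(model, bolus_regimen(control_dose), grid)
        c = np.clip(res.plasma_concentration(d.PA), 0.0, None)
        prof = ConcentrationProfile(d.PA, grid[1:], c[1:], control_dose,
                                    CONTROL_BW)
        cl_sim = run_nca(prof).cl
        cl_ws = well_stirred_clearance(phys.q_liver, pa.properties.fup,
                                       pa.hepatic.clu_int) / CONTROL_BW
        assert cl_sim == pytest.approx(cl_ws, rel=0.01)

    def test_steady_state_cell_ratio_matches_partition_relation(
            self, control_tables):
        """With secretion, reabsorption and filtration off, the kidney-cell
        to plasma concentration ratio at infusion steady state equals
        fup*PSin/(fu,kidney*PSout)."""
        pa, napa = control_tables
        phys = default_rat_physiology(CONTROL_BW,
                                      config={"gfr_ml_min_kg": 1e-12})
        tables = []
        for t in (pa, napa):
            kid = dataclasses.replace(t.kidney, clu_int_r=0.0, cl_rabs=0.0)
            tables.append(dataclasses.replace(t, kidney=kid))
        model = build_model(phys, *tables)
        rate = d.INFUSION_RATE_MG_PER_KG_H * CONTROL_BW * 1000.0 / 60.0
        reg = infusion_regimen(1.4 * CONTROL_BW * 1000.0, rate, 2000.0)
        res = simulate(model, reg, np.linspace(0.0, 2000.0, 101))
        c_cell = (res.state(d.PA, "kidney_cell")[-1]
                  / phys.kidney_subvolumes["cell"])
        c_pl = res.plasma_concentration(d.PA)[-1]
        expected = kidney_kp_model(pa.properties.fup, pa.kidney.ps_in,
                                   pa.properties.fu_kidney, pa.kidney.ps_out)
        assert c_cell / c_pl == pytest.approx(expected, rel=1e-3)

    def test_cell_ratio_invariant_to_joint_transport_scaling(
            self, control_tables):
        """Doubling PSin and PSout together leaves the steady-state cell
        ratio unchanged (the partition relation depends on their ratio)."""
        pa, napa = control_tables
        phys = default_rat_physiology(CONTROL_BW,
                                      config={"gfr_ml_min_kg": 1e-12})
        ratios = []
        for factor in (1.0, 2.0):
            tables = []
            for t in (pa, napa):
                kid = dataclasses.replace(
                    t.kidney, ps_in=t.kidney.ps_in * factor,
                    ps_pas=t.kidney.ps_pas * factor, clu_int_r=0.0,
                    cl_rabs=0.0)
                tables.append(dataclasses.replace(t, kidney=kid))
            model = build_model(phys, *tables)
            rate = d.INFUSION_RATE_MG_PER_KG_H * CONTROL_BW * 1000.0 / 60.0
            reg = infusion_regimen(1.4 * CONTROL_BW * 1000.0, rate, 2000.0)
            res = simulate(model, reg, np.linspace(0.0, 2000.0, 51))
            c_cell = (res.state(d.PA, "kidney_cell")[-1]
                      / phys.kidney_subvolumes["cell"])
            ratios.append(c_cell / res.plasma_concentration(d.PA)[-1])
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-3)

    def test_no_elimination_distributes_to_total_volume(self, physio):
        """All Kp = 1 and no elimination: plasma concentration approaches
        dose over the accessible distribution volume."""
        from panapk.parameterization import (DrugProperties, HepaticParams,
                                             KidneyTransportParams,
                                             ParameterTable, TissueKpSet)
        tissues = ("adipose", "bone", "brain", "gut", "heart", "kidney",
                   "liver", "lung", "muscle", "skin", "spleen")
        tables = {}
        for drug in d.DRUGS:
            props = DrugProperties(name=drug, molecular_weight=235.33,
                                   pka=9.0, logp=0.8, fup=1.0, fu_kidney=1.0)
            kp = TissueKpSet({t: 1.0 for t in tissues},
                             {"kidney": "model_based",
                              "liver": "retrograde"})
            tables[drug] = ParameterTable(
                drug=drug, arm=d.CONTROL, properties=props, kp=kp,
                hepatic=HepaticParams(0.0, 0.0, 0.0),
                kidney=KidneyTransportParams(ps_in=1.0, ps_pas=1.0,
                                             clu_int_r=0.0, cl_rabs=0.0))
        phys = default_rat_physiology(CONTROL_BW,
                                      config={"gfr_ml_min_kg": 1e-12})
        model = build_model(phys, tables[d.PA], tables[d.NAPA])
        dose = 1000.0
        res = simulate(model, bolus_regimen(dose), np.array([0.0, 5e4]))
        vols = phys.tissue_volumes
        accessible = (sum(vols[t] for t in tissues if t != "kidney")
                      + vols["blood"] + phys.kidney_subvolumes["vascular"]
                      + phys.kidney_subvolumes["cell"])
        assert res.plasma_concentration(d.PA)[-1] == pytest.approx(
            dose / accessible, rel=1e-3)

    def test_tolerance_halving_leaves_auc_unchanged(self, physio,
                                                    control_tables,
                                                    control_dose):
        pa, napa = control_tables
        aucs = []
        for rtol in (1e-8, 5e-9):
            model = build_model(physio, pa, napa,
                                solver=SolverSettings(rtol=rtol))
            grid = dense_grid(1440.0, 200)
            res = simulate(model, bolus_regimen(control_dose), grid)
            aucs.append(np.trapezoid(res.plasma_concentration(d.PA), grid))
        assert abs(aucs[1] / aucs[0] - 1.0) < 1e-4


class TestTrajectories:
    def test_states_nonnegative_and_urine_monotone(self, control_model,
                                                   control_dose):
        grid = dense_grid(1440.0, 200)
        res = simulate(control_model, bolus_regimen(control_dose), grid)
        for drug in d.DRUGS:
            assert res.amounts[drug].min() > -1e-6
            urine = res.cumulative_urine(drug)
            assert np.all(np.diff(urine) >= -1e-9)
            assert urine[-1] <= control_dose

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(d.PA, "iv_infusion", 100.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            DoseRegimen((DoseEvent(d.PA, "iv_bolus", 1.0, 10.0),
                         DoseEvent(d.PA, "iv_bolus", 1.0, 0.0)))

    def test_grid_must_cover_events(self, control_model):
        reg = bolus_regimen(100.0, start=500.0)
        with pytest.raises(ValueError, match="outside grid"):
            simulate(control_model, reg, np.linspace(0.0, 480.0, 10))


class TestSteadyStateKpss:
    def test_non_eliminating_tissue_recovers_input_kp(self, control_model,
                                                      control_tables):
        rate = d.INFUSION_RATE_MG_PER_KG_H * CONTROL_BW * 1000.0 / 60.0
        reg = infusion_regimen(1.4 * CONTROL_BW * 1000.0, rate, 600.0)
        kpss = steady_state_kpss(control_model, reg, 600.0, d.PA)
        pa, _ = control_tables
        for tissue in ("brain", "heart", "spleen", "lung"):
            assert kpss[tissue] == pytest.approx(pa.kp[tissue], rel=0.01)

    def test_eliminating_tissue_kpss_depressed_below_kp(self, control_model,
                                                        control_tables):
        rate = d.INFUSION_RATE_MG_PER_KG_H * CONTROL_BW * 1000.0 / 60.0
        reg = infusion_regimen(1.4 * CONTROL_BW * 1000.0, rate, 600.0)
        kpss = steady_state_kpss(control_model, reg, 600.0, d.PA)
        pa, _ = control_tables
        assert kpss["kidney"] < pa.kp["kidney"]
        assert kpss["liver"] < pa.kp["liver"]

    def test_premature_sampling_warns(self, control_model):
        rate = d.INFUSION_RATE_MG_PER_KG_H * CONTROL_BW * 1000.0 / 60.0
        reg = infusion_regimen(0.0, rate, 10.0)
        with pytest.warns(UserWarning, match="steady state not reached"):
            steady_state_kpss(control_model, reg, 10.0, d.PA)

    def test_sampling_at_time_zero_rejected(self, control_model):
        reg = bolus_regimen(100.0)
        with pytest.raises(ValueError):
            steady_state_kpss(control_model, reg, 0.0, d.PA)
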