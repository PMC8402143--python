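"""Virtual-rat study generator.

Emulates the two in vivo study designs the analysis pipeline consumes:

* a two-arm IV bolus study (10 mg/kg PA HCl; plasma sampled over 480 min,
  urine collected over five intervals to 24 h);
* a loading-dose + constant-infusion tissue-distribution study (sacrifice
  at 60 min, six tissues sampled) yielding observed Kp,ss values.

Between-animal variability is lognormal on clearance-type and Kp-type
parameters (default CV 20%, chosen to approximate the dispersion of the
reported per-animal NCA parameters); observation noise follows the
additive+proportional variance model of the fitting module, applied on the
concentration scale and truncated at zero.  Everything is reproducible from
the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import defaults as d
from .fitting import ObservationSet, ObservedDataset, VarianceModel
from .nca import ConcentrationProfile, UrineCollection
from .parameterization import (HepaticParams, KidneyTransportParams,
                               ParameterTable, TissueKpSet,
                               control_parameter_table,
                               treatment_parameter_table)
from .pbpk import (ModelSpec, bolus_regimen, build_model, infusion_regimen,
                   simulate, steady_state_kpss)
from .physiology import default_rat_physiology

__all__ = ["StudyDesign", "BolusStudy", "generate_bolus_study",
           "generate_infusion_study", "mean_observation_set",
           "arm_tables"]

_CL_PARAMS = ("clu_int", "clu_int_r", "ps_act", "ps_pas", "cl_rabs")
_KPSS_TISSUES = ("brain", "heart", "kidney", "liver", "lung", "spleen")


@dataclass(frozen=True)
class StudyDesign:
    """Design of one virtual study arm."""

    n_animals: int = d.N_ANIMALS
    body_weight_mean: float = d.BODY_WEIGHT_KG[d.CONTROL]  # kg
    body_weight_sd: float = 0.019
    dose_mg_per_kg: float = d.DOSE_MG_PER_KG
    sampling_times: tuple[float, ...] = d.SAMPLING_TIMES_MIN
    urine_intervals: tuple[tuple[float, float], ...] = d.URINE_INTERVALS_H
    variance: VarianceModel = VarianceModel()
    between_animal_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.between_animal_cv < 0:
            raise ValueError("between-animal CV must be >= 0")
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise ValueError("sampling times must be sorted")


@dataclass(frozen=True)
class BolusStudy:
    """Generated bolus study: per-animal profiles and urine collections."""

    arm: str
    profiles: Mapping[str, tuple[ConcentrationProfile, ...]]
    urine: Mapping[str, tuple[UrineCollection, ...]]
    truth: dict = field(default_factory=dict)


def arm_tables(arm: str, r_act: float = d.RACT_FITTED
               ) -> tuple[ParameterTable, ParameterTable]:
    """(PA, NAPA) parameter tables for a study arm."""
    if arm == d.CONTROL:
        return (control_parameter_table(d.PA),
                control_parameter_table(d.NAPA))
    if arm == d.TREATED:
        return (treatment_parameter_table(d.PA, r_act=r_act),
                treatment_parameter_table(d.NAPA, r_act=r_act))
    raise ValueError(f"unknown arm {arm!r}")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))


def _perturb_table(table: ParameterTable, rng: np.random.Generator,
                   cv: float) -> ParameterTable:
    """Lognormally perturb clearance-type and Kp-type parameters."""
    if cv == 0:
        return table
    f = {name: _lognormal_factor(rng, cv) for name in _CL_PARAMS}
    kid = table.kidney
    ps_act = kid.ps_act * f["ps_act"]
    ps_pas = kid.ps_pas * f["ps_pas"]
    kidney = KidneyTransportParams(
        ps_in=ps_act + ps_pas, ps_pas=ps_pas,
        clu_int_r=kid.clu_int_r * f["clu_int_r"],
        cl_rabs=kid.cl_rabs * f["cl_rabs"],
        extraction_ratio=kid.extraction_ratio)
    hepatic = HepaticParams(
        clu_int=table.hepatic.clu_int * f["clu_int"],
        f_napa=table.hepatic.f_napa,
        extraction_ratio=table.hepatic.extraction_ratio)
    kp = {t: v * _lognormal_factor(rng, cv) for t, v in table.kp.kp.items()}
    return replace(table, kidney=kidney, hepatic=hepatic,
                   kp=TissueKpSet(kp, dict(table.kp.provenance)))


def _add_noise(rng: np.random.Generator, values: np.ndarray,
               vm: VarianceModel) -> np.ndarray:
    sd = vm.sigma1 + vm.sigma2 * values
    noisy = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    return np.clip(noisy, 0.0, None)


def generate_bolus_study(arm: str, design: StudyDesign,
                         r_act: float = d.RACT_FITTED,
                         noise: bool = True) -> BolusStudy:
    """Simulate one arm of the IV-bolus plasma + urine study.

    Each animal gets a body weight drawn from the design distribution,
    lognormally perturbed parameters, a noiseless PBPK-simulated truth, and
    observation noise on both plasma concentrations and interval urine
    amounts (unless ``noise=False``).  Urinary amounts are reported on the
    observation scale, i.e. multiplied by the per-drug calibration factor.
    """
    rng = np.random.default_rng(design.seed)
    base_pa, base_napa = arm_tables(arm, r_act=r_act)
    vm = design.variance
    profiles: dict[str, list[ConcentrationProfile]] = {d.PA: [], d.NAPA: []}
    urine: dict[str, list[UrineCollection]] = {d.PA: [], d.NAPA: []}
    truth: dict = {"arm": arm, "r_act": r_act, "seed": design.seed,
                   "animals": []}

    t_plasma = np.asarray(design.sampling_times, dtype=float)
    t_urine_min = np.array([end * 60.0 for _, end in design.urine_intervals])
    t_grid = np.unique(np.concatenate([[0.0], t_plasma, t_urine_min]))

    for i in range(design.n_animals):
        bw = rng.normal(design.body_weight_mean, design.body_weight_sd)
        bw = float(np.clip(bw, 0.1, 1.0))
        physio = default_rat_physiology(bw)
        pa = _perturb_table(base_pa, rng, design.between_animal_cv)
        napa = _perturb_table(base_napa, rng, design.between_animal_cv)
        model = build_model(physio, pa, napa,
                            urinary_calibration=d.URINARY_CALIBRATION)
        dose = design.dose_mg_per_kg * bw * 1000.0  # ug
        res = simulate(model, bolus_regimen(dose, d.PA), t_grid)
        animal_truth = {"body_weight": bw, "dose_ug": dose}
        for drug in (d.PA, d.NAPA):
            c_true = np.interp(t_plasma, t_grid,
                               res.plasma_concentration(drug))
            c_obs = _add_noise(rng, c_true, vm) if noise else c_true
            profiles[drug].append(ConcentrationProfile(
                drug=drug, times=t_plasma, concentrations=c_obs, dose=dose,
                body_weight=bw))
            cum_true = np.interp(t_urine_min, t_grid,
                                 res.cumulative_urine(drug, calibrated=True))
            interval_true = np.diff(np.concatenate([[0.0], cum_true]))
            interval_obs = (_add_noise(rng, interval_true, vm)
                            if noise else interval_true)
            urine[drug].append(UrineCollection(
                drug=drug, intervals=design.urine_intervals,
                amounts=interval_obs, dose=dose))
            animal_truth[drug] = {
                "plasma_true": c_true.tolist(),
                "urine_cumulative_true": cum_true.tolist()}
        truth["animals"].append(animal_truth)

    return BolusStudy(
        arm=arm,
        profiles={k: tuple(v) for k, v in profiles.items()},
        urine={k: tuple(v) for k, v in urine.items()},
        truth=truth)


def mean_observation_set(study: BolusStudy) -> ObservationSet:
    """Arm-mean observation set for naive-pooled fitting.

    Plasma concentrations are averaged across animals at each sampling
    time; urinary amounts are averaged as cumulative series at interval
    ends.  Dose and body weight are the arm means.
    """
    any_profile = study.profiles[d.PA][0]
    doses = [p.dose for p in study.profiles[d.PA]]
    bws = [p.body_weight for p in study.profiles[d.PA]]
    datasets = []
    for drug in (d.PA, d.NAPA):
        profs = study.profiles[drug]
        c_mean = np.mean([p.concentrations for p in profs], axis=0)
        datasets.append(ObservedDataset("plasma", drug, any_profile.times,
                                        c_mean))
        cols = study.urine[drug]
        cum = np.mean([np.cumsum(u.amounts) for u in cols], axis=0)
        ends_min = np.array([e * 60.0 for _, e in cols[0].intervals])
        datasets.append(ObservedDataset("urine_cumulative", drug, ends_min,
                                        cum))
    return ObservationSet(arm=study.arm, dose=float(np.mean(doses)),
                          body_weight=float(np.mean(bws)),
                          datasets=tuple(datasets))


def generate_infusion_study(arm: str, design: StudyDesign,
                            r_act: float = d.RACT_FITTED,
                            sample_time: float = 60.0,
                            noise: bool = True) -> pd.DataFrame:
    """Simulate the loading-dose + constant-infusion Kp,ss study.

    Returns a tidy table (animal, drug, tissue, c_tissue, c_plasma, kp_ss)
    at the sacrifice time, with multiplicative lognormal measurement noise
    on tissue and plasma concentrations (CV = the design's proportional
    sigma).  Plasma concentrations at the serial sampling times are included
    as rows with tissue = "plasma".
    """
    rng = np.random.default_rng(design.seed + 1)
    base_pa, base_napa = arm_tables(arm, r_act=r_act)
    rows = []
    noise_cv = design.variance.sigma2 if noise else 0.0
    for i in range(design.n_animals):
        bw = float(np.clip(rng.normal(design.body_weight_mean,
                                      design.body_weight_sd), 0.1, 1.0))
        physio = default_rat_physiology(bw)
        pa = _perturb_table(base_pa, rng, design.between_animal_cv)
        napa = _perturb_table(base_napa, rng, design.between_animal_cv)
        model = build_model(physio, pa, napa,
                            urinary_calibration=d.URINARY_CALIBRATION)
        loading = d.INFUSION_LOADING_MG_PER_KG[arm] * bw * 1000.0
        rate = d.INFUSION_RATE_MG_PER_KG_H * bw * 1000.0 / 60.0  # ug/min
        regimen = infusion_regimen(loading, rate, sample_time, d.PA)
        grid = np.unique(np.concatenate(
            [[0.0], np.asarray(d.INFUSION_SAMPLING_TIMES_MIN),
             [sample_time]]))
        res = simulate(model, regimen, grid)
        for drug in (d.PA, d.NAPA):
            c_pl = res.plasma_concentration(drug)
            c_end = float(c_pl[-1]) * _lognormal_factor(rng, noise_cv)
            for t_s, c_s in zip(grid[1:], c_pl[1:]):
                rows.append({"animal": i, "drug": drug, "tissue": "plasma",
                             "time_min": float(t_s),
                             "concentration": float(c_s)
                             * _lognormal_factor(rng, noise_cv)})
            if c_end <= 0:
                continue
            for tissue in _KPSS_TISSUES:
                c_t = float(res.tissue_concentration(drug, tissue)[-1])
                c_t *= _lognormal_factor(rng, noise_cv)
                rows.append({"animal": i, "drug": drug, "tissue": tissue,
                             "time_min": sample_time, "c_tissue": c_t,
                             "c_plasma": c_end, "kp_ss": c_t / c_end})
    return pd.DataFrame(rows)
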