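"""Parameter derivations for the PA/NAPA disposition model.

Implements the retrograde calculations that turn observed quantities into
model parameters, and the treatment-effect scaling that maps the control-arm
parameter table onto the 1,25(OH)2D3-treated arm:

* retrograde tissue partitioning, ``Kp = Kp,ss / (1 - ER)`` — the steady-state
  partition coefficient of an eliminating tissue is depressed by extraction,
  so the true coefficient is recovered by dividing by the fraction escaping;
* the kidney-cell partition relation ``Kp,KI = fup*PSin / (fu,kidney*PSout)``
  (steady-state balance of basolateral uptake and efflux);
* the well-stirred liver in retrograde form,
  ``CLu,int = QLI*CLNR / (fup*(QLI - CLNR))``, and its forward inverse;
* the active-uptake fold change, ``PSin' = (PSin - PSpas)*Ract + PSpas``, and
  the rMATE1 secretory fold, ``CLu,int,r' = CLu,int,r * RMATE``;
* hepatic uptake scaling through the saturable (transporter-mediated)
  fraction, and qPCR expression folds ``2**(-ddCt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd

from . import defaults as d

__all__ = [
    "DrugProperties", "TissueKpSet", "HepaticParams", "KidneyTransportParams",
    "TreatmentScalars", "ParameterTable",
    "retrograde_kp", "kidney_kp_model", "well_stirred_retrograde",
    "well_stirred_clearance", "extraction_ratio", "apply_ract", "apply_rmate",
    "scale_hepatic_uptake", "expression_fold", "active_fraction",
    "build_parameter_table", "control_parameter_table",
    "treatment_parameter_table", "parameter_table_to_frame",
    "parameter_table_from_frame",
]


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 < value <= 1.0):
        raise ValueError(f"{name} must be in (0, 1], got {value}")


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical and binding properties of one drug."""

    name: str
    molecular_weight: float  # g/mol
    pka: float
    logp: float
    fup: float               # plasma unbound fraction
    blood_plasma_ratio: float = 1.0
    fu_kidney: float = 1.0   # kidney-cell unbound fraction
    fu_inc: float = 1.0      # incubation unbound fraction

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be > 0")
        for nm in ("fup", "fu_kidney", "fu_inc"):
            _check_fraction(nm, getattr(self, nm))


@dataclass(frozen=True)
class TissueKpSet:
    """Tissue-to-plasma partition coefficients with per-tissue provenance.

    Provenance is one of ``observed_kpss`` (non-eliminating tissue, measured
    at infusion steady state), ``retrograde`` (eliminating tissue, corrected
    for extraction), ``model_based`` (kidney relation) or ``in_silico``.
    """

    kp: Mapping[str, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    _ELIMINATING = ("kidney", "liver")

    def __post_init__(self) -> None:
        for tissue, value in self.kp.items():
            if value <= 0:
                raise ValueError(f"Kp[{tissue}] must be > 0, got {value}")
        for tissue in self._ELIMINATING:
            if tissue in self.kp:
                prov = self.provenance.get(tissue)
                if prov not in ("retrograde", "model_based"):
                    raise ValueError(
                        f"{tissue} is an eliminating tissue; its Kp must be "
                        f"retrograde or model_based, got {prov!r}")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]


@dataclass(frozen=True)
class HepaticParams:
    clu_int: float           # unbound hepatic intrinsic clearance, mL/min
    f_napa: float            # fraction of hepatic elimination forming NAPA
    extraction_ratio: float  # CLNR / QLI

    def __post_init__(self) -> None:
        if self.clu_int < 0:
            raise ValueError("clu_int must be >= 0")
        if not (0.0 <= self.f_napa <= 1.0):
            raise ValueError("f_napa must be in [0, 1]")
        if not (0.0 <= self.extraction_ratio < 1.0):
            raise ValueError("hepatic extraction ratio must be in [0, 1)")


@dataclass(frozen=True)
class KidneyTransportParams:
    ps_in: float       # total basolateral uptake clearance, mL/min
    ps_pas: float      # passive bidirectional clearance (= PSout), mL/min
    clu_int_r: float   # apical secretory intrinsic clearance, mL/min
    cl_rabs: float     # luminal reabsorption clearance, mL/min
    extraction_ratio: float = 0.0  # CLsec / QKI

    def __post_init__(self) -> None:
        for nm in ("ps_in", "ps_pas", "clu_int_r", "cl_rabs"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if self.ps_in < self.ps_pas:
            raise ValueError("ps_in must be >= ps_pas (active component >= 0)")

    @property
    def ps_act(self) -> float:
        """Active (transporter-mediated) component of basolateral uptake."""
        return self.ps_in - self.ps_pas

    @property
    def ps_out(self) -> float:
        """Basolateral efflux clearance; passive, so equals ``ps_pas``."""
        return self.ps_pas


@dataclass(frozen=True)
class TreatmentScalars:
    """Fold changes applied to the control table to obtain the treated arm."""

    r_act: float = 1.0                 # renal active-uptake fold (fitted)
    r_mate: float = 1.0                # rMATE1 protein fold
    oct1_liver_fold: float = 1.0       # hepatic rOCT1 protein fold
    saturable_hepatic_fraction: float = 1.0
    urinary_calibration: Mapping[str, float] = field(
        default_factory=lambda: {d.PA: 1.0, d.NAPA: 1.0})

    def __post_init__(self) -> None:
        for nm in ("r_act", "r_mate", "oct1_liver_fold"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if not (0.0 <= self.saturable_hepatic_fraction <= 1.0):
            raise ValueError("saturable_hepatic_fraction must be in [0, 1]")
        for drug, v in self.urinary_calibration.items():
            if v <= 0:
                raise ValueError(f"urinary calibration for {drug} must be > 0")


@dataclass(frozen=True)
class ParameterTable:
    """Complete parameterization for one drug in one study arm."""

    drug: str
    arm: str
    properties: DrugProperties
    kp: TissueKpSet
    hepatic: HepaticParams
    kidney: KidneyTransportParams


# ---------------------------------------------------------------------------
# Elementary derivations
# ---------------------------------------------------------------------------

def retrograde_kp(kp_ss: float, er: float) -> float:
    """True tissue partition coefficient from its steady-state apparent value.

    ``Kp = Kp,ss / (1 - ER)``: elimination within the tissue lowers the
    apparent steady-state tissue/plasma ratio by the fraction extracted.
    """
    if kp_ss <= 0:
        raise ValueError(f"kp_ss must be > 0, got {kp_ss}")
    if not (0.0 <= er < 1.0):
        raise ValueError(f"extraction ratio must be in [0, 1), got {er}")
    return kp_ss / (1.0 - er)


def kidney_kp_model(fup: float, ps_in: float, fu_kidney: float,
                    ps_out: float) -> float:
    """Model-based kidney cell-to-plasma coefficient.

    At steady state, unbound uptake (``fup*PSin``) balances unbound efflux
    (``fu,kidney*PSout``), giving ``Kp,KI = fup*PSin / (fu,kidney*PSout)``.
    """
    for nm, v in (("fup", fup), ("ps_in", ps_in), ("fu_kidney", fu_kidney),
                  ("ps_out", ps_out)):
        if v <= 0:
            raise ValueError(f"{nm} must be > 0, got {v}")
    return (fup * ps_in) / (fu_kidney * ps_out)


def well_stirred_retrograde(q_li: float, cl_nr: float, fup: float) -> float:
    """Unbound hepatic intrinsic clearance from observed non-renal clearance.

    Inverts the well-stirred liver model:
    ``CLu,int = QLI*CLNR / (fup*(QLI - CLNR))``.
    """
    _check_fraction("fup", fup)
    if cl_nr < 0 or q_li <= 0:
        raise ValueError("flows and clearances must be non-negative, q_li > 0")
    if cl_nr >= q_li:
        raise ValueError(
            f"CLNR ({cl_nr}) must be below hepatic flow QLI ({q_li}): an organ "
            "cannot clear more than it receives")
    return q_li * cl_nr / (fup * (q_li - cl_nr))


def well_stirred_clearance(q_li: float, fup: float, clu_int: float) -> float:
    """Forward well-stirred model: ``CL = QLI*fup*CLu,int/(QLI + fup*CLu,int)``."""
    _check_fraction("fup", fup)
    if q_li <= 0 or clu_int < 0:
        raise ValueError("q_li must be > 0 and clu_int >= 0")
    return q_li * fup * clu_int / (q_li + fup * clu_int)


def extraction_ratio(cl: float, q: float) -> float:
    """Organ extraction ratio CL/Q for organ plasma flow Q."""
    if q <= 0:
        raise ValueError("organ flow must be > 0")
    if not (0.0 <= cl < q):
        raise ValueError(f"clearance {cl} must lie in [0, organ flow {q})")
    return cl / q


def apply_ract(ps_in: float, ps_pas: float, r_act: float) -> float:
    """Scale the active component of basolateral uptake by the fold ``Ract``.

    ``PSin' = PSact*Ract + PSpas`` with ``PSact = PSin - PSpas``.
    """
    if r_act <= 0:
        raise ValueError("r_act must be > 0")
    if ps_pas < 0 or ps_in < ps_pas:
        raise ValueError("need ps_in >= ps_pas >= 0 (active component >= 0)")
    return (ps_in - ps_pas) * r_act + ps_pas


def apply_rmate(clu_int_r: float, r_mate: float) -> float:
    """Scale apical secretory intrinsic clearance by the rMATE1 protein fold."""
    if clu_int_r < 0 or r_mate < 0:
        raise ValueError("inputs must be >= 0")
    return clu_int_r * r_mate


def scale_hepatic_uptake(saturable_fraction: float, protein_fold: float) -> float:
    """Percent decrease in hepatic uptake when only the saturable
    (transporter-mediated) component follows the protein fold change.

    New total fold = ``saturable*fold + (1 - saturable)``; returns
    ``(1 - new fold) * 100``.
    """
    if not (0.0 <= saturable_fraction <= 1.0):
        raise ValueError("saturable_fraction must be in [0, 1]")
    if protein_fold <= 0:
        raise ValueError("protein_fold must be > 0")
    new_fold = saturable_fraction * protein_fold + (1.0 - saturable_fraction)
    return (1.0 - new_fold) * 100.0


def expression_fold(delta_delta_ct: float) -> float:
    """qPCR relative expression fold, ``2**(-ddCt)``."""
    if not math.isfinite(delta_delta_ct):
        raise ValueError("delta-delta-Ct must be finite")
    return 2.0 ** (-delta_delta_ct)


def active_fraction(ps_in: float, ps_pas: float) -> float:
    """Active share of basolateral uptake, ``PSact/PSin``, as a fraction."""
    if ps_in <= 0 or not (0.0 <= ps_pas <= ps_in):
        raise ValueError("need ps_in > 0 and 0 <= ps_pas <= ps_in")
    return (ps_in - ps_pas) / ps_in


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def build_parameter_table(control: ParameterTable,
                          scalars: TreatmentScalars,
                          overrides: Mapping[str, float] | None = None,
                          ) -> ParameterTable:
    """Derive the treated-arm parameter table from the control arm.

    Renal basolateral uptake is scaled through ``Ract`` (active component
    only), apical secretion through the rMATE1 protein fold, and the kidney
    Kp is re-derived from the scaled clearances.  All other parameters carry
    over unless given in ``overrides`` (recognised keys: ``kp_liver``,
    ``clu_int``, ``f_napa``, ``hepatic_extraction_ratio``,
    ``renal_extraction_ratio``), which is how observed treated-arm values
    replace the carried-over control values.
    """
    overrides = dict(overrides or {})
    kid = control.kidney
    # unit folds leave values bit-identical (idempotence for unit scalars)
    ps_in_new = (kid.ps_in if scalars.r_act == 1.0
                 else apply_ract(kid.ps_in, kid.ps_pas, scalars.r_act))
    clu_int_r_new = (kid.clu_int_r if scalars.r_mate == 1.0
                     else apply_rmate(kid.clu_int_r, scalars.r_mate))
    kidney_new = KidneyTransportParams(
        ps_in=ps_in_new,
        ps_pas=kid.ps_pas,
        clu_int_r=clu_int_r_new,
        cl_rabs=kid.cl_rabs,
        extraction_ratio=overrides.pop("renal_extraction_ratio",
                                       kid.extraction_ratio),
    )
    kp = dict(control.kp.kp)
    prov = dict(control.kp.provenance)
    if scalars.r_act != 1.0:
        # the scaled uptake changes the steady-state cell partitioning;
        # the control value (retrograde from observed Kp,ss) is replaced by
        # the model-based relation evaluated at the new PSin
        kp["kidney"] = kidney_kp_model(control.properties.fup, ps_in_new,
                                       control.properties.fu_kidney,
                                       kid.ps_out)
        prov["kidney"] = "model_based"
    if "kp_liver" in overrides:
        kp["liver"] = overrides.pop("kp_liver")
        prov["liver"] = "retrograde"
    hepatic_new = HepaticParams(
        clu_int=overrides.pop("clu_int", control.hepatic.clu_int),
        f_napa=overrides.pop("f_napa", control.hepatic.f_napa),
        extraction_ratio=overrides.pop("hepatic_extraction_ratio",
                                       control.hepatic.extraction_ratio),
    )
    if overrides:
        raise ValueError(f"unrecognised overrides: {sorted(overrides)}")
    return replace(control, arm=d.TREATED, kp=TissueKpSet(kp, prov),
                   hepatic=hepatic_new, kidney=kidney_new)


def _drug_properties(drug: str) -> DrugProperties:
    return DrugProperties(
        name=drug,
        molecular_weight=d.MOLECULAR_WEIGHT[drug],
        pka=d.PKA[drug],
        logp=d.LOGP[drug],
        fup=d.FUP[drug],
        blood_plasma_ratio=d.BLOOD_PLASMA_RATIO[drug],
        fu_kidney=d.FU_KIDNEY[drug],
        fu_inc=d.FU_INC if drug == d.PA else 1.0,
    )


def control_parameter_table(drug: str) -> ParameterTable:
    """Control-arm parameter table assembled from the published study inputs.

    Kp for liver and kidney are derived retrogradely from the observed
    Kp,ss and extraction ratios; remaining sampled tissues use Kp,ss
    directly and unsampled tissues use the in-silico predictions.
    """
    props = _drug_properties(drug)
    kpss = d.KP_SS[d.CONTROL][drug]
    kp: dict[str, float] = {}
    prov: dict[str, str] = {}
    for tissue, value in kpss.items():
        if tissue == "kidney":
            kp[tissue] = retrograde_kp(value, d.ER_RENAL[d.CONTROL][drug])
            prov[tissue] = "retrograde"
        elif tissue == "liver":
            kp[tissue] = retrograde_kp(value, d.ER_HEPATIC[d.CONTROL][drug])
            prov[tissue] = "retrograde"
        else:
            kp[tissue] = value
            prov[tissue] = "observed_kpss"
    for tissue, value in d.KP_PREDICTED[drug].items():
        kp[tissue] = value
        prov[tissue] = "in_silico"
    hepatic = HepaticParams(
        clu_int=d.CLU_INT[d.CONTROL][drug],
        f_napa=d.F_NAPA[d.CONTROL] if drug == d.PA else 0.0,
        extraction_ratio=d.ER_HEPATIC[d.CONTROL][drug],
    )
    kidney = KidneyTransportParams(
        ps_in=d.PS_IN[d.CONTROL][drug],
        ps_pas=d.PS_OUT[drug],
        clu_int_r=d.CLU_INT_R[d.CONTROL][drug],
        cl_rabs=d.CL_RABS[drug],
        extraction_ratio=d.ER_RENAL[d.CONTROL][drug],
    )
    return ParameterTable(drug=drug, arm=d.CONTROL, properties=props,
                          kp=TissueKpSet(kp, prov), hepatic=hepatic,
                          kidney=kidney)


def treatment_parameter_table(drug: str,
                              r_act: float = d.RACT_FITTED,
                              r_mate: float = d.RMATE) -> ParameterTable:
    """Treated-arm table: control table scaled by Ract/RMATE with the
    observed treated-arm hepatic values overriding the carried-over ones."""
    control = control_parameter_table(drug)
    scalars = TreatmentScalars(
        r_act=r_act, r_mate=r_mate,
        oct1_liver_fold=d.OCT1_LIVER_PROTEIN_FOLD,
        saturable_hepatic_fraction=d.SATURABLE_HEPATIC_FRACTION,
        urinary_calibration=d.URINARY_CALIBRATION,
    )
    overrides = {
        "kp_liver": retrograde_kp(d.KP_SS[d.TREATED][drug]["liver"],
                                  d.ER_HEPATIC[d.TREATED][drug]),
        "clu_int": d.CLU_INT[d.TREATED][drug],
        "hepatic_extraction_ratio": d.ER_HEPATIC[d.TREATED][drug],
        "renal_extraction_ratio": d.ER_RENAL[d.TREATED][drug],
    }
    if drug == d.PA:
        overrides["f_napa"] = d.F_NAPA[d.TREATED]
    return build_parameter_table(control, scalars, overrides)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["block", "parameter", "drug", "arm", "value", "units",
                "provenance"]


def parameter_table_to_frame(table: ParameterTable) -> pd.DataFrame:
    """Flatten a :class:`ParameterTable` into the tidy CSV layout
    (block, parameter, drug, arm, value, units, provenance)."""
    rows: list[dict] = []

    def add(block: str, parameter: str, value: float, units: str = "",
            provenance: str = "") -> None:
        rows.append({"block": block, "parameter": parameter,
                     "drug": table.drug, "arm": table.arm, "value": value,
                     "units": units, "provenance": provenance})

    p = table.properties
    add("physchem", "molecular_weight", p.molecular_weight, "g/mol")
    add("physchem", "pka", p.pka)
    add("physchem", "logp", p.logp)
    add("physchem", "fup", p.fup)
    add("physchem", "blood_plasma_ratio", p.blood_plasma_ratio)
    add("physchem", "fu_kidney", p.fu_kidney)
    add("physchem", "fu_inc", p.fu_inc)
    for tissue in sorted(table.kp.kp):
        add("distribution", f"kp_{tissue}", table.kp[tissue], "",
            table.kp.provenance.get(tissue, ""))
    h = table.hepatic
    add("hepatic", "clu_int", h.clu_int, "mL/min")
    add("hepatic", "f_napa", h.f_napa)
    add("hepatic", "extraction_ratio", h.extraction_ratio)
    k = table.kidney
    add("kidney", "ps_in", k.ps_in, "mL/min")
    add("kidney", "ps_pas", k.ps_pas, "mL/min")
    add("kidney", "clu_int_r", k.clu_int_r, "mL/min")
    add("kidney", "cl_rabs", k.cl_rabs, "mL/min")
    add("kidney", "extraction_ratio", k.extraction_ratio)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def parameter_table_from_frame(frame: pd.DataFrame) -> ParameterTable:
    """Rebuild a :class:`ParameterTable` from its tidy CSV layout."""
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"parameter CSV missing columns: {sorted(missing)}")
    drugs = frame["drug"].unique()
    arms = frame["arm"].unique()
    if len(drugs) != 1 or len(arms) != 1:
        raise ValueError("parameter CSV must contain one drug and one arm")

    def block(name: str) -> dict[str, float]:
        sel = frame[frame["block"] == name]
        return dict(zip(sel["parameter"], sel["value"].astype(float)))

    phys = block("physchem")
    props = DrugProperties(
        name=str(drugs[0]), molecular_weight=phys["molecular_weight"],
        pka=phys["pka"], logp=phys["logp"], fup=phys["fup"],
        blood_plasma_ratio=phys["blood_plasma_ratio"],
        fu_kidney=phys["fu_kidney"], fu_inc=phys["fu_inc"])
    dist = frame[frame["block"] == "distribution"]
    kp = {row.parameter.removeprefix("kp_"): float(row.value)
          for row in dist.itertuples()}
    prov = {row.parameter.removeprefix("kp_"): str(row.provenance)
            for row in dist.itertuples()}
    hep = block("hepatic")
    kid = block("kidney")
    return ParameterTable(
        drug=str(drugs[0]), arm=str(arms[0]), properties=props,
        kp=TissueKpSet(kp, prov),
        hepatic=HepaticParams(clu_int=hep["clu_int"], f_napa=hep["f_napa"],
                              extraction_ratio=hep["extraction_ratio"]),
        kidney=KidneyTransportParams(
            ps_in=kid["ps_in"], ps_pas=kid["ps_pas"],
            clu_int_r=kid["clu_int_r"], cl_rabs=kid["cl_rabs"],
            extraction_ratio=kid["extraction_ratio"]),
    )
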