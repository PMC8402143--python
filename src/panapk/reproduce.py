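"""Recomputation of the published derived quantities from their inputs.

Each check recomputes one printed value through the package's own
functions, starting from the published input tables, and compares it with
the printed value at the printed precision (3 significant figures).  The
check ids double as the keys of the machine-readable report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import defaults as d
from .invitro import ivive_scale, ivive_scaling_factor
from .nca import percent_change
from .parameterization import (active_fraction, apply_ract, apply_rmate,
                               kidney_kp_model, retrograde_kp,
                               scale_hepatic_uptake)

__all__ = ["Check", "round_sig", "run_checks", "report_lines"]


def round_sig(x: float, n: int = 3) -> float:
    """Round to ``n`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, n - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class Check:
    id: str
    description: str
    computed: float   # rounded to the printed precision
    expected: float   # the printed value
    raw: float        # unrounded computed value

    @property
    def passed(self) -> bool:
        return self.computed == self.expected


def run_checks() -> list[Check]:
    """The 12-check derivation report."""
    checks: list[Check] = []

    def add(cid: str, description: str, raw: float, expected: float) -> None:
        checks.append(Check(cid, description, round_sig(raw, 3), expected,
                            raw))

    add("t1", "control PA kidney Kp, retrograde Kp,ss/(1-ER)",
        retrograde_kp(d.KP_SS[d.CONTROL][d.PA]["kidney"],
                      d.ER_RENAL[d.CONTROL][d.PA]), 11.4)
    add("t2", "control NAPA kidney Kp, retrograde Kp,ss/(1-ER)",
        retrograde_kp(d.KP_SS[d.CONTROL][d.NAPA]["kidney"],
                      d.ER_RENAL[d.CONTROL][d.NAPA]), 14.7)
    add("t3", "treated PA liver Kp, retrograde Kp,ss/(1-ER)",
        retrograde_kp(d.KP_SS[d.TREATED][d.PA]["liver"],
                      d.ER_HEPATIC[d.TREATED][d.PA]), 0.649)
    add("t4", "treated PA renal uptake PSin' = PSact*Ract + PSpas (mL/min)",
        apply_ract(d.PS_IN[d.CONTROL][d.PA], d.PS_OUT[d.PA], d.RACT_FITTED),
        17.4)
    add("t5", "treated NAPA renal uptake PSin' = PSact*Ract + PSpas (mL/min)",
        apply_ract(d.PS_IN[d.CONTROL][d.NAPA], d.PS_OUT[d.NAPA],
                   d.RACT_FITTED), 8.95)
    add("t6", "treated PA apical secretion CLu,int,r * RMATE (mL/min)",
        apply_rmate(d.CLU_INT_R[d.CONTROL][d.PA], d.RMATE), 1.46)
    add("t8", "IVIVE whole-liver unbound formation clearance (mL/min)",
        ivive_scale(d.S9_FORMATION_CL_UL_MIN_MG, d.S9_YIELD_MG_PER_G_LIVER,
                    d.LIVER_MASS_G, d.FU_INC), 4.64)
    add("t11", "hepatic PSin percent decrease via saturable-fraction scaling",
        scale_hepatic_uptake(d.SATURABLE_HEPATIC_FRACTION,
                             d.OCT1_LIVER_PROTEIN_FOLD), 38.5)
    add("active_fraction",
        "active share of PA renal basolateral uptake, PSact/PSin (%)",
        active_fraction(d.PS_IN[d.CONTROL][d.PA], d.PS_OUT[d.PA]) * 100.0,
        65.6)
    ivive_cl = round_sig(
        ivive_scale(d.S9_FORMATION_CL_UL_MIN_MG, d.S9_YIELD_MG_PER_G_LIVER,
                    d.LIVER_MASS_G, d.FU_INC), 3)
    add("ivive_factor",
        "empirical IVIVE scaling factor, CLu,int*FNAPA / scaled S9 clearance",
        ivive_scaling_factor(d.CLU_INT_FNAPA, ivive_cl), 5.80)
    add("pa_clnr_decrease", "percent decrease in PA non-renal clearance",
        percent_change(d.NCA_SUMMARY[d.CONTROL][d.PA]["cl_nr"],
                       d.NCA_SUMMARY[d.TREATED][d.PA]["cl_nr"]), 22.5)
    add("napa_clr_decrease", "percent decrease in NAPA renal clearance",
        percent_change(d.NCA_SUMMARY[d.CONTROL][d.NAPA]["cl_r"],
                       d.NCA_SUMMARY[d.TREATED][d.NAPA]["cl_r"]), 29.2)
    return checks


def kidney_kp_consistency() -> dict:
    """Side-by-side of the two treated-arm kidney Kp values.

    The published model-based treated kidney Kp differs from a direct
    evaluation of the steady-state relation with the scaled PSin; both are
    reported, neither is adjusted.
    """
    out = {}
    for drug in d.DRUGS:
        ps_in_treated = apply_ract(d.PS_IN[d.CONTROL][drug], d.PS_OUT[drug],
                                   d.RACT_FITTED)
        direct = kidney_kp_model(d.FUP[drug], ps_in_treated,
                                 d.FU_KIDNEY[drug], d.PS_OUT[drug])
        out[drug] = {"direct_evaluation": round_sig(direct, 3),
                     "published": d.KP_KIDNEY_TREATED_PRINTED[drug]}
    return out


def report_lines(checks: list[Check]) -> list[str]:
    lines = [f"{'id':<18} {'computed':>10} {'published':>10}  status",
             "-" * 52]
    for c in checks:
        status = "pass" if c.passed else "FAIL"
        lines.append(f"{c.id:<18} {c.computed:>10g} {c.expected:>10g}  "
                     f"{status}")
    n_pass = sum(c.passed for c in checks)
    lines.append(f"{n_pass}/{len(checks)} checks passed")
    return lines
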