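"""Ultrafiltration binding arithmetic, S9 formation kinetics and IVIVE.

Ultrafiltration of plasma or an S9 incubation through a centrifugal filter
gives the free (unbound) drug fraction once two corrections are applied:
non-specific binding of drug to the device (measured in protein-free
buffer) and mass recovery (drug accounted for in filtrate plus retentate
relative to the loaded reservoir).

The S9 metabolite-formation assay yields a per-mg-protein formation
clearance (rate of metabolite appearance divided by substrate
concentration), which IVIVE scales to a whole-liver unbound intrinsic
clearance via the S9 protein yield per gram of liver, the liver mass, and
the unbound fraction in the incubation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UltrafiltrationMeasurement", "S9Assay",
    "nsb_percent", "free_fraction_percent", "recovery_percent",
    "formation_clearance", "ivive_scale", "ivive_scaling_factor",
    "ultrafiltration_report",
]


@dataclass(frozen=True)
class UltrafiltrationMeasurement:
    """One ultrafiltration run.

    ``c1`` is the matrix standard before incubation, ``c2`` the reservoir
    sample loaded into the filter, ``c3`` the retentate after spinning,
    ``cf`` the filtrate; ``c_before``/``c_after`` are the buffer-only device
    controls.  ``filtrate_weight`` is the filtrate mass in g, treated as mL
    at unit density.
    """

    c1: float
    c2: float
    c3: float
    cf: float
    filtrate_weight: float
    c_before: float
    c_after: float
    reservoir_volume: float = 0.4  # mL remaining in the loaded device

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "cf", "c_before", "c_after"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.filtrate_weight <= self.reservoir_volume):
            raise ValueError("filtrate weight must be in (0, reservoir volume]")


@dataclass(frozen=True)
class S9Assay:
    """Metabolite-formation time course in a liver S9 incubation."""

    protein_conc: float       # mg/mL
    substrate_conc: float     # uM
    times: tuple[float, ...]  # min
    amounts: tuple[float, ...]  # pmol metabolite / mg protein

    def __post_init__(self) -> None:
        if self.protein_conc <= 0 or self.substrate_conc <= 0:
            raise ValueError("protein and substrate concentrations must be > 0")
        if len(self.times) != len(self.amounts) or len(self.times) < 2:
            raise ValueError("need matching times/amounts, at least 2 points")
        if 0.0 not in self.times:
            raise ValueError("the time course must include t = 0")
        if any(a < 0 for a in self.amounts):
            raise ValueError("metabolite amounts must be >= 0")


def nsb_percent(c_before: float, c_after: float) -> float:
    """Non-specific binding to the device, ``(Cbefore - Cafter)/Cbefore*100``."""
    if c_before <= 0:
        raise ZeroDivisionError("c_before must be > 0")
    return (c_before - c_after) / c_before * 100.0


def free_fraction_percent(cf: float, c2: float, nsb: float) -> float:
    """Unbound fraction (%) with the NSB correction applied to the filtrate.

    The corrected filtrate concentration is ``Crf = Cf*100/(100 - NSB)``;
    the free fraction is ``Crf/C2 * 100``.
    """
    if c2 <= 0:
        raise ZeroDivisionError("c2 must be > 0")
    if not (0.0 <= nsb < 100.0):
        raise ValueError("NSB percent must be in [0, 100)")
    crf = cf * 100.0 / (100.0 - nsb)
    return crf / c2 * 100.0


def recovery_percent(cf: float, c3: float, c2: float, filtrate_weight: float,
                     reservoir_volume: float = 0.4) -> float:
    """Mass recovery (%): drug in filtrate plus retentate over drug loaded.

    ``[Cf*w + C3*(V - w)] / (C2*V) * 100`` with ``V`` the residual reservoir
    volume of the device and ``w`` the filtrate volume.
    """
    if c2 <= 0:
        raise ZeroDivisionError("c2 must be > 0")
    if not (0.0 <= filtrate_weight <= reservoir_volume):
        raise ValueError("filtrate weight must be in [0, reservoir volume]")
    mass_found = cf * filtrate_weight + c3 * (reservoir_volume - filtrate_weight)
    return mass_found / (c2 * reservoir_volume) * 100.0


def ultrafiltration_report(m: UltrafiltrationMeasurement) -> dict:
    """NSB, free fraction and recovery for one measurement."""
    nsb = nsb_percent(m.c_before, m.c_after)
    return {
        "nsb_percent": nsb,
        "free_fraction_percent": free_fraction_percent(m.cf, m.c2, nsb),
        "recovery_percent": recovery_percent(m.cf, m.c3, m.c2,
                                             m.filtrate_weight,
                                             m.reservoir_volume),
    }


def formation_clearance(assay: S9Assay, through_origin: bool = False
                        ) -> float:
    """Formation clearance in uL/min/mg protein.

    The formation rate (pmol/min/mg) is the least-squares slope of the
    metabolite time course (ordinary regression with intercept by default,
    since the assay samples a t=0 point); dividing by the substrate
    concentration (uM = pmol/uL) gives a clearance per mg protein.  A
    negative slope is clipped to zero.
    """
    t = np.asarray(assay.times, dtype=float)
    a = np.asarray(assay.amounts, dtype=float)
    if through_origin:
        slope = float(t @ a / (t @ t))
    else:
        slope = float(np.polyfit(t, a, 1)[0])
    if slope < 0:
        import warnings
        warnings.warn("negative formation rate; clearance clipped to 0",
                      stacklevel=2)
        return 0.0
    return slope / assay.substrate_conc


def ivive_scale(cl_per_mg: float, s9_yield: float, liver_mass: float,
                fu_inc: float) -> float:
    """Scale a per-mg-protein clearance (uL/min/mg) to whole-liver unbound
    intrinsic clearance (mL/min).

    ``CLu,int = cl_per_mg * s9_yield * liver_mass / fu_inc / 1000``.
    """
    for name, v in (("cl_per_mg", cl_per_mg), ("s9_yield", s9_yield),
                    ("liver_mass", liver_mass), ("fu_inc", fu_inc)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if fu_inc > 1.0:
        raise ValueError("fu_inc must be <= 1")
    return cl_per_mg * s9_yield * liver_mass / fu_inc / 1000.0


def ivive_scaling_factor(in_vivo_cl: float, in_vitro_cl: float) -> float:
    """Empirical fold by which the scaled in vitro clearance must be
    multiplied to match the in vivo estimate."""
    if in_vitro_cl <= 0:
        raise ZeroDivisionError("in_vitro_cl must be > 0")
    return in_vivo_cl / in_vitro_cl
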