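"""Rat physiological constants with body-weight scaling.

Tissue volumes and regional plasma flows follow standard rat reference
compendia (Brown et al.-style tables), expressed per kg body weight and
scaled linearly to the animal's weight.  Because the drugs modelled here
have a blood:plasma ratio of 1, blood and plasma flows are interchangeable
and the model works throughout in plasma concentrations.

Every reference value can be overridden from a TOML config (see
:func:`default_rat_physiology`), which is how a user supplies the hepatic or
renal flow implied by their own clearance data when it differs from the
compendium.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "PhysiologySet",
    "REFERENCE_PHYSIOLOGY",
    "default_rat_physiology",
    "load_reference_config",
]

TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "lung", "muscle", "skin", "spleen", "blood",
)

#: Reference values per kg body weight.  Volumes in mL/kg; cardiac output,
#: GFR and urine flow in mL/min/kg; regional flows as fractions of cardiac
#: output.  The muscle fraction also carries the residual carcass flow so
#: that the organ arterial fractions sum exactly to 1.
REFERENCE_PHYSIOLOGY: dict = {
    "volumes_ml_per_kg": {
        "adipose": 76.0, "bone": 41.7, "brain": 5.7, "gut": 27.0,
        "heart": 3.3, "kidney": 7.3, "liver": 36.6, "lung": 5.0,
        "muscle": 404.0, "skin": 190.4, "spleen": 2.0, "blood": 74.0,
    },
    "cardiac_output_ml_min_kg": 296.0,
    "flow_fractions": {
        # fraction of cardiac output delivered arterially to each tissue;
        # liver arterial supply is the hepatic artery only -- portal inflow
        # arrives via gut and spleen.  Lung is in series and takes the full
        # cardiac output.
        "adipose": 0.070, "bone": 0.122, "brain": 0.020, "gut": 0.131,
        "heart": 0.049, "kidney": 0.141, "hepatic_artery": 0.021,
        "muscle": 0.378, "skin": 0.058, "spleen": 0.010,
    },
    "gfr_ml_min_kg": 5.2,
    "urine_flow_ml_min_kg": 0.05,
    "kidney_subvolume_fractions": {"vascular": 0.15, "cell": 0.75,
                                   "lumen": 0.10},
}

_FLOW_BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class PhysiologySet:
    """Internally consistent set of volumes (mL) and plasma flows (mL/min).

    ``tissue_flows`` holds arterial inflows per tissue plus the derived
    entries ``hepatic_artery``, ``liver`` (total hepatic = artery + gut +
    spleen outflow), ``lung`` (= cardiac output) and ``cardiac_output``.
    """

    body_weight: float  # kg
    tissue_volumes: Mapping[str, float] = field(repr=False)
    kidney_subvolumes: Mapping[str, float] = field(repr=False)
    tissue_flows: Mapping[str, float] = field(repr=False)
    gfr: float = 0.0
    urine_flow: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, v in {**self.tissue_volumes, **self.kidney_subvolumes,
                        **self.tissue_flows,
                        "GFR": self.gfr, "urine_flow": self.urine_flow}.items():
            if not (v > 0.0) or not math.isfinite(v):
                raise ValueError(f"physiology value {name!r} must be > 0, got {v}")
        missing = set(TISSUES) - set(self.tissue_volumes)
        if missing:
            raise ValueError(f"missing tissue volumes: {sorted(missing)}")
        co = self.tissue_flows["cardiac_output"]
        arterial = sum(
            self.tissue_flows[t]
            for t in ("adipose", "bone", "brain", "gut", "heart", "kidney",
                      "hepatic_artery", "muscle", "skin", "spleen")
        )
        if abs(arterial - co) > _FLOW_BALANCE_TOL * co:
            raise ValueError(
                f"organ arterial flows ({arterial:.6g}) do not sum to cardiac "
                f"output ({co:.6g})")
        q_li = (self.tissue_flows["hepatic_artery"] + self.tissue_flows["gut"]
                + self.tissue_flows["spleen"])
        if abs(self.tissue_flows["liver"] - q_li) > _FLOW_BALANCE_TOL * q_li:
            raise ValueError("liver flow must equal hepatic artery + gut + spleen")
        ksum = sum(self.kidney_subvolumes.values())
        vki = self.tissue_volumes["kidney"]
        if abs(ksum - vki) > _FLOW_BALANCE_TOL * vki:
            raise ValueError("kidney subvolumes must sum to the kidney volume")

    @property
    def q_liver(self) -> float:
        """Total hepatic plasma flow Q_LI (mL/min)."""
        return self.tissue_flows["liver"]

    @property
    def q_kidney(self) -> float:
        """Renal plasma flow Q_KI (mL/min)."""
        return self.tissue_flows["kidney"]

    @property
    def cardiac_output(self) -> float:
        return self.tissue_flows["cardiac_output"]


def load_reference_config(path: str | Path) -> dict:
    """Read a TOML physiology config, merged over the built-in reference."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _merge(REFERENCE_PHYSIOLOGY, user)


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(val, Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def default_rat_physiology(body_weight: float,
                           config: Mapping | str | Path | None = None,
                           ) -> PhysiologySet:
    """Build a :class:`PhysiologySet` for a rat of the given weight (kg).

    Parameters
    ----------
    body_weight:
        Body weight in kg; must lie in [0.1, 1.0], the range over which
        linear per-kg scaling of rat organ volumes and flows is defensible.
    config:
        Optional overrides: a mapping with the structure of
        :data:`REFERENCE_PHYSIOLOGY`, or a path to a TOML file with the same
        keys.  Partial overrides are merged over the reference values.
    """
    if not (0.1 <= body_weight <= 1.0):
        raise ValueError(f"body weight {body_weight} kg outside [0.1, 1.0]")
    if config is None:
        ref = REFERENCE_PHYSIOLOGY
    elif isinstance(config, (str, Path)):
        ref = load_reference_config(config)
    else:
        ref = _merge(REFERENCE_PHYSIOLOGY, config)

    fractions = ref["flow_fractions"]
    fsum = sum(fractions.values())
    if abs(fsum - 1.0) > 1e-9:
        raise ValueError(f"flow fractions must sum to 1, got {fsum:.6g}")

    volumes = {t: ref["volumes_ml_per_kg"][t] * body_weight for t in TISSUES}
    co = ref["cardiac_output_ml_min_kg"] * body_weight
    flows = {name: frac * co for name, frac in fractions.items()}
    flows["liver"] = flows["hepatic_artery"] + flows["gut"] + flows["spleen"]
    flows["lung"] = co
    flows["cardiac_output"] = co
    kf = ref["kidney_subvolume_fractions"]
    if abs(sum(kf.values()) - 1.0) > 1e-9:
        raise ValueError("kidney subvolume fractions must sum to 1")
    ksub = {name: frac * volumes["kidney"] for name, frac in kf.items()}

    return PhysiologySet(
        body_weight=body_weight,
        tissue_volumes=volumes,
        kidney_subvolumes=ksub,
        tissue_flows=flows,
        gfr=ref["gfr_ml_min_kg"] * body_weight,
        urine_flow=ref["urine_flow_ml_min_kg"] * body_weight,
    )
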