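"""Non-compartmental analysis of plasma and urine data.

Conventions (declared, since software packages differ):

* terminal slope by log-linear regression over the last 3..6 positive
  concentrations, picking the window with the best adjusted R^2;
* AUC by the linear-up / log-down trapezoidal rule, extrapolated to infinity
  with ``C_last/lambda_z`` (AUMC tail ``C_last*t_last/lambda_z +
  C_last/lambda_z**2``);
* clearances reported per kg body weight, mirroring the usual rat NCA
  reporting style;
* per-animal NCA first, then arithmetic mean +/- SD across animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConcentrationProfile", "UrineCollection", "NCAResult",
    "terminal_slope", "auc_moments", "clearance_partition", "percent_change",
    "cumulative_recovery", "kp_ss_observed", "run_nca", "summarize_nca",
    "secretion_clearance",
]


@dataclass(frozen=True)
class ConcentrationProfile:
    """One animal's plasma concentration-time profile after a single dose."""

    drug: str
    times: np.ndarray            # min
    concentrations: np.ndarray   # ug/mL
    dose: float                  # ug
    body_weight: float           # kg
    route: str = "iv_bolus"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.count_nonzero(c > 0) < 3:
            raise ValueError("need at least 3 positive concentrations")


@dataclass(frozen=True)
class UrineCollection:
    """Interval urine amounts for one animal."""

    drug: str
    intervals: Sequence[tuple[float, float]]  # (start h, end h)
    amounts: np.ndarray                       # ug per interval
    dose: float                               # ug

    def __post_init__(self) -> None:
        a = np.asarray(self.amounts, dtype=float)
        object.__setattr__(self, "amounts", a)
        ivals = [(float(s), float(e)) for s, e in self.intervals]
        object.__setattr__(self, "intervals", tuple(ivals))
        if len(ivals) != len(a):
            raise ValueError("one amount per interval required")
        for (s0, e0), (s1, _) in zip(ivals[:-1], ivals[1:]):
            if not math.isclose(e0, s1):
                raise ValueError("urine intervals must be contiguous")
        if any(e <= s for s, e in ivals):
            raise ValueError("urine intervals must have positive width")
        if np.any(a < 0):
            raise ValueError("urine amounts must be >= 0")

    @property
    def total_amount(self) -> float:
        return float(self.amounts.sum())


@dataclass(frozen=True)
class NCAResult:
    drug: str
    auc_inf: float        # ug*min/mL
    aumc_inf: float       # ug*min^2/mL
    lambda_z: float       # 1/min
    t_half_beta: float    # min
    mrt: float            # min
    vss: float            # mL/kg
    cl: float             # mL/min/kg
    cmax: float           # ug/mL
    tmax: float           # min
    cl_r: float = float("nan")   # mL/min/kg
    cl_nr: float = float("nan")  # mL/min/kg
    n_terminal: int = 0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def terminal_slope(profile: ConcentrationProfile,
                   n_terminal: int | None = None) -> tuple[float, float]:
    """Terminal elimination rate constant and half-life.

    Log-linear least squares over the last ``n_terminal`` positive points;
    if ``n_terminal`` is None the window (3..6 points) with the highest
    adjusted R^2 is used.
    """
    t = profile.times
    c = profile.concentrations
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < 3:
        raise ValueError("need at least 3 positive points for the terminal fit")
    logc = np.log(c)

    def fit(n: int) -> tuple[float, float]:
        tt, yy = t[-n:], logc[-n:]
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        if ss_tot == 0:
            r2adj = -np.inf
        else:
            r2 = 1.0 - ss_res / ss_tot
            r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        return slope, r2adj

    if n_terminal is not None:
        if not (3 <= n_terminal <= len(t)):
            raise ValueError("n_terminal out of range")
        slope, _ = fit(n_terminal)
        n_used = n_terminal
    else:
        best = None
        for n in range(3, min(6, len(t)) + 1):
            slope, r2adj = fit(n)
            if best is None or r2adj > best[1] + 1e-12:
                best = (slope, r2adj, n)
        slope, _, n_used = best
    if slope >= 0:
        raise ValueError("terminal phase is not declining; cannot estimate "
                         "the elimination rate constant")
    lambda_z = -slope
    return lambda_z, math.log(2.0) / lambda_z


def _auc_aumc_interval(t1: float, t2: float, c1: float, c2: float
                       ) -> tuple[float, float]:
    """Linear-up/log-down AUC and AUMC over one sampling interval."""
    dt = t2 - t1
    if c2 < c1 and c1 > 0 and c2 > 0:
        lam = math.log(c1 / c2) / dt
        auc = (c1 - c2) / lam
        aumc = (t1 * c1 - t2 * c2) / lam + (c1 - c2) / lam ** 2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def auc_moments(profile: ConcentrationProfile, lambda_z: float,
                n_terminal: int = 0) -> NCAResult:
    """AUC/AUMC to infinity and the derived NCA parameters.

    For an IV bolus profile whose first sample is after dosing, the segment
    from t=0 to the first sample is included by back-extrapolating the
    initial concentration from the first two samples (log-linear when
    declining).
    """
    t = profile.times
    c = profile.concentrations
    if lambda_z <= 0:
        raise ValueError("lambda_z must be > 0")
    auc = aumc = 0.0
    if t[0] > 0 and profile.route == "iv_bolus":
        # back-extrapolate C(0) from the first two positive samples
        if c[0] > 0 and len(c) > 1 and 0 < c[1] < c[0]:
            k0 = math.log(c[0] / c[1]) / (t[1] - t[0])
            c0 = c[0] * math.exp(k0 * t[0])
        else:
            c0 = c[0]
        a, m = _auc_aumc_interval(0.0, t[0], c0, c[0])
        auc += a
        aumc += m
    for i in range(len(t) - 1):
        a, m = _auc_aumc_interval(t[i], t[i + 1], c[i], c[i + 1])
        auc += a
        aumc += m
    c_last = c[c > 0][-1]
    t_last = t[c > 0][-1]
    auc_inf = auc + c_last / lambda_z
    aumc_inf = aumc + c_last * t_last / lambda_z + c_last / lambda_z ** 2
    if auc_inf <= 0:
        raise ZeroDivisionError("zero AUC; clearance undefined")
    if profile.dose <= 0:
        raise ZeroDivisionError("zero dose; clearance undefined")
    mrt = aumc_inf / auc_inf
    cl = profile.dose / auc_inf / profile.body_weight  # mL/min/kg
    vss = cl * mrt
    imax = int(np.argmax(c))
    return NCAResult(
        drug=profile.drug, auc_inf=auc_inf, aumc_inf=aumc_inf,
        lambda_z=lambda_z, t_half_beta=math.log(2.0) / lambda_z, mrt=mrt,
        vss=vss, cl=cl, cmax=float(c[imax]), tmax=float(t[imax]),
        n_terminal=n_terminal)


def clearance_partition(dose: float, auc_inf: float, ae_urine: float,
                        body_weight: float) -> tuple[float, float, float]:
    """Split total clearance into renal and non-renal parts (mL/min/kg).

    ``CLR = Ae/AUCinf`` per kg; ``CLNR = CL - CLR``.
    """
    if auc_inf <= 0:
        raise ValueError("auc_inf must be > 0")
    if not (0.0 <= ae_urine <= dose):
        raise ValueError("urinary amount must lie in [0, dose]")
    cl = dose / auc_inf / body_weight
    cl_r = ae_urine / auc_inf / body_weight
    return cl, cl_r, cl - cl_r


def percent_change(control: float, treated: float) -> float:
    """Percent decrease from control to treated, ``(c - t)/c * 100``."""
    if control == 0:
        raise ZeroDivisionError("control value must be nonzero")
    return (control - treated) / control * 100.0


def cumulative_recovery(urine: UrineCollection) -> np.ndarray:
    """Cumulative urinary recovery (% of dose) at each interval end."""
    if urine.dose <= 0:
        raise ValueError("dose must be > 0")
    rec = np.cumsum(urine.amounts) / urine.dose * 100.0
    if rec.size and rec[-1] > 100.0 + 1e-9:
        raise ValueError("recovered more than the administered dose")
    return rec


def kp_ss_observed(c_tissue: float, c_plasma: float,
                   dilution_factor: float = 1.0) -> float:
    """Observed steady-state tissue/plasma ratio, unit tissue density assumed.

    ``dilution_factor`` undoes homogenate dilution: a tissue homogenised in
    a two-fold volume of buffer is measured at 1/3 of the tissue
    concentration, so pass ``dilution_factor=3``.
    """
    if c_plasma <= 0:
        raise ZeroDivisionError("plasma concentration must be > 0")
    if c_tissue < 0 or dilution_factor <= 0:
        raise ValueError("tissue concentration >= 0, dilution factor > 0")
    return c_tissue * dilution_factor / c_plasma


def secretion_clearance(cl_r: float, fup: float, gfr: float,
                        subtract_filtration: bool = True) -> float:
    """Net renal secretion clearance (mL/min).

    By default the filtration contribution ``fup*GFR`` is subtracted from
    total renal clearance; pass ``subtract_filtration=False`` to treat the
    whole renal clearance as secretory (both conventions appear in the
    literature for the ratio CLsec/QKI).
    """
    cl_sec = cl_r - fup * gfr if subtract_filtration else cl_r
    return max(cl_sec, 0.0)


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------

def run_nca(profile: ConcentrationProfile,
            urine: UrineCollection | None = None,
            n_terminal: int | None = None) -> NCAResult:
    """Full per-animal NCA: terminal fit, moments, clearance partition."""
    lambda_z, _ = terminal_slope(profile, n_terminal)
    n_used = n_terminal or 0
    result = auc_moments(profile, lambda_z, n_terminal=n_used)
    if urine is not None:
        cl, cl_r, cl_nr = clearance_partition(
            profile.dose, result.auc_inf, urine.total_amount,
            profile.body_weight)
        result = NCAResult(**{**result.__dict__, "cl_r": cl_r,
                              "cl_nr": cl_nr})
    return result


def summarize_nca(results: Sequence[NCAResult]) -> dict:
    """Arithmetic mean +/- SD across animals, plus the ratio-of-means CL.

    ``cl_mean`` is the mean of individual clearances (the usual reporting
    style); ``cl_from_mean_auc`` is dose/mean-AUC, which differs whenever
    AUC varies across animals -- both are reported so the distinction is
    explicit.
    """
    if not results:
        raise ValueError("no NCA results to summarize")
    fields = ("auc_inf", "lambda_z", "t_half_beta", "mrt", "vss", "cl",
              "cl_r", "cl_nr", "cmax", "tmax")
    out: dict = {"n": len(results), "drug": results[0].drug}
    for f in fields:
        vals = np.array([getattr(r, f) for r in results], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[f"{f}_mean"] = float(vals.mean())
            out[f"{f}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    aucs = np.array([r.auc_inf for r in results])
    cls = np.array([r.cl for r in results])
    out["cl_mean"] = float(cls.mean())
    # dose/BW per animal = cl*auc; ratio of means uses mean dose intensity
    out["cl_from_mean_auc"] = float((cls * aucs).mean() / aucs.mean())
    return out
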