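# Methods

## Scope and model overview

`panapk` implements a parent–metabolite whole-body PBPK model for
procainamide (PA) and N-acetylprocainamide (NAPA) in rat, together with
the parameter-derivation arithmetic, non-compartmental analysis (NCA),
in vitro binding/metabolism arithmetic, maximum-likelihood fitting, and a
virtual-study generator that exercises the whole pipeline.  Both drugs are
small organic cations (monoprotic bases, pKa 9.04) with a blood:plasma
ratio of 1, so the model works in plasma concentrations throughout.
Canonical internal units are mL, min, µg and kg body weight; per-kg
clearances are converted at the boundary using the arm-specific mean final
body weight (0.2976 kg control, 0.2823 kg treated).

## Physiology

Tissue volumes and regional flows follow standard rat compendium values
(Brown et al.-style reference tables), expressed per kg and scaled
linearly with body weight over 0.1–1.0 kg.  Cardiac output is
296 mL/min/kg; organ arterial flow fractions sum exactly to 1, with the
residual carcass flow folded into the muscle fraction so the flow-balance
invariant (`Σ organ arterial flows = cardiac output`;
`Q_liver = Q_hepatic artery + Q_gut + Q_spleen`) holds to machine
precision.  GFR defaults to 5.2 mL/min/kg and urine flow to
0.05 mL/min/kg.  Kidney subvolumes default to fixed fractions of kidney
volume (vascular 0.15, cell 0.75, lumen 0.10).  Every value is overridable
from a TOML config; this matters because the hepatic flow implied by the
observed non-renal clearance and hepatic extraction ratio of PA
(≈23 mL/min for a 0.3 kg rat) exceeds compendium values (≈14 mL/min), and
the package deliberately does not reconcile the two — the user chooses.

## Parameter derivations

* **Retrograde Kp.** For an eliminating tissue the steady-state
  tissue/plasma ratio is depressed by extraction; the model coefficient is
  `Kp = Kp,ss / (1 − ER)`.  Applied to kidney and liver with the
  NCA-derived extraction ratios (`ER_hepatic = CLNR/Q_LI`,
  `ER_renal = CLsec/Q_KI`).
* **Kidney partition relation.** At steady state unbound uptake balances
  unbound efflux across the basolateral membrane, giving
  `Kp,KI = fup·PSin / (fu,kidney·PSout)`.
* **Well-stirred liver.** Forward
  `CL_hep = Q·fup·CLu,int / (Q + fup·CLu,int)`; the retrograde inverse
  `CLu,int = Q·CLNR / (fup·(Q − CLNR))` converts an observed non-renal
  clearance into an intrinsic clearance.  The two forms are exact inverses
  over `0 < CLNR < Q`, which is property-tested.
* **Treatment scaling.** Basolateral uptake splits into active and passive
  components (`PSin = PSact + PSpas`, with `PSpas = PSout`); treatment
  scales only the active part: `PSin' = PSact·Ract + PSpas`.  Apical
  secretion scales directly with the rMATE1 protein fold:
  `CLu,int,r' = CLu,int,r·RMATE` (RMATE = 0.312 from densitometry).
  Hepatic uptake scales through its saturable fraction (55.7% for PA):
  `new fold = f_sat·protein fold + (1 − f_sat)`.
* **Expression folds.** Relative qPCR expression is `2^(−ΔΔCt)`.

`build_parameter_table` maps a control table to the treated arm.  Unit
folds leave the table bit-identical (idempotence).  When `Ract ≠ 1`, the
kidney Kp is re-derived from the scaled PSin via the partition relation.
Direct evaluation of that relation with the scaled PSin gives 8.92 (PA)
and 13.8 (NAPA), whereas the published model-based treated-arm values are
10.7 and 14.5; the source does not explain the difference, so the package
computes and reports both (`panapk reproduce` prints the comparison) and
adjusts neither.

Two further published rows are carried but not computed with: the
`CLint,m` row (its column assignment and definition are ambiguous) and
`FNAPA`, which is treated as a direct input (0.562 control, 0.845
treated) because its derivation from NCA is not fully specified.  The
administered dose is interpreted as the salt (PA HCl); an optional
free-base correction (235.33/271.8) exists but is off by default, matching
the nominal-dose convention of the NCA.

## PBPK structure

Venous and arterial plasma are pooled into one central compartment (with
B/P = 1 the distinction carries no information at this resolution); the
lung sits in series carrying full cardiac output, and its outflow is the
arterial concentration feeding all tissues.  Perfusion-limited tissues
follow `dA_T/dt = Q_T(C_art − A_T/(V_T·Kp_T))`.  Gut and spleen drain into
the liver; hepatic elimination is `CLu,int·fup·C_liver,out`, of which a
fraction `FNAPA` enters NAPA's liver compartment, mass-corrected by the
molecular-weight ratio 277.36/235.33 (toggleable).

The kidney has vascular, cell and lumen subcompartments:

* vascular ⇄ cell: `fup·PSin` (uptake) and `fu,kidney·PSout` (efflux);
* vascular → lumen: glomerular filtration `fup·GFR`;
* cell → lumen: active secretion `fu,kidney·CLu,int,r`;
* lumen → cell: reabsorption `CLrabs`;
* lumen → urine: a configurable outflow clearance.

The source text for the original model's differential equations was not
available; this wiring is reconstructed from the narrative description and
the roles of the published parameters, and each flux term is named after
its published symbol.  The lumen outflow clearance defaults to **GFR**
(tubular fluid transit): using the literal urine flow (~0.013 mL/min)
would let `CLrabs` (0.415 mL/min) reabsorb >95% of filtered plus secreted
drug, which is inconsistent with the observed ~20% urinary recovery of
PA.  The choice is exposed (`lumen_outflow = "gfr" | "urine_flow" |
<value>`).

Cumulative urine and cumulative hepatic elimination (split into
NAPA-formation and miscellaneous for PA) are carried as states, so total
mass is a linear invariant of the ODE system and is conserved by the
integrator to near machine precision; the acceptance property asserts
≤ 1e−6 relative error per time point.

Empirical urinary calibration factors (1.29 for PA, 0.836 for NAPA,
attributed to the four-day vehicle treatment) are applied as
multiplicative observation-scale factors on simulated urinary amounts,
never as kinetic parameters — raw urine states keep mass balance exact.

### Numerics

`scipy.integrate.solve_ivp` with LSODA, rtol 1e−8, atol 1e−10 by default
(the reference computation used fixed-step RK4; we match results, not the
integrator — halving the tolerance changes the plasma AUC by < 0.01%).
Dosing discontinuities (boluses, infusion starts/ends) split the
integration into segments; boluses are state jumps at segment starts, and
a grid point at a bolus time records the post-bolus state.

## NCA conventions

λz is fitted by log-linear regression over the last 3–6 positive points,
selecting the window with the best adjusted R² (the rule used by common
NCA software is not published; this one is declared).  AUC uses
linear-up/log-down trapezoids with a `C_last/λz` tail; AUMC accordingly.
For IV-bolus profiles whose first sample is after dosing, C(0) is
back-extrapolated log-linearly from the first two samples.  `CL = dose /
AUCinf / BW`, `Vss = CL·MRT`, `CLR = Ae/AUCinf/BW`, `CLNR = CL − CLR`
(exact by construction).  Per-animal NCA is computed first and then
averaged arithmetically; `summarize_nca` reports both the mean of
individual clearances and dose/mean-AUC, which differ whenever AUC varies
across animals.  Net secretion clearance is `CLR − fup·GFR` by default,
with the "total CLR" convention available, since the published ratio
`CLsec/Q_KI` does not state which was used.  Urine dilution factors
(100-fold for 0–8 h, 50-fold for 8–24 h collections) belong to the I/O
layer, not the NCA.

## In vitro arithmetic

Non-specific device binding `NSB% = (C_before − C_after)/C_before·100`;
corrected filtrate concentration `Crf = Cf·100/(100 − NSB)`; free fraction
`Crf/C2·100`; recovery `[Cf·w + C3·(V − w)]/(C2·V)·100`.  The constant
0.4 in the recovery expression is interpreted as the 0.4 mL residual
reservoir volume of the filtration device and promoted to a parameter;
filtrate weight is treated as volume at unit density.  S9 formation
clearance is the least-squares slope of the metabolite time course
(ordinary regression with intercept, since the assay samples t = 0;
through-origin optional) divided by substrate concentration; IVIVE scales
it by 135 mg S9 protein/g liver × 9 g liver / fu,inc (0.380) / 1000 to
mL/min.  Whether the published per-mg clearance was derived exactly this
way is not stated; the linear example series in the tests is constructed
to be consistent with it and labelled as such.

## Fitting

`Ract` is the only estimated parameter; RMATE is fixed.  The objective is
the ML criterion `Σ_datasets Σ_i [(y_i − Y_i)²/V_i + ln V_i]` with
`V_i = (σ₁ + σ₂·Y_i)²` evaluated at model predictions.  σ₁ = 0.01
(observation units) and σ₂ = 0.1 are user-set defaults; the source does
not report estimated variance parameters.  Fitting is naive-pooled on
arm-mean profiles (four datasets: plasma and cumulative urine for PA and
NAPA).  The search is bounded scalar minimization on log(Ract) over
(1e−3, 10); CV% comes from a central finite-difference
observed-information approximation at the optimum, an approximation to
the reference software's output.

One property of this criterion worth knowing: because `V` depends on the
prediction, the `ln V` term rewards smaller predictions, so even on
noise-free data the optimum sits a few tenths of a percent away from the
generating value under the default σ₂.  With constant weights (σ₂ = 0)
noise-free recovery is exact; the tests exercise both.

Published AAFE values against the in vivo observations cannot be
recomputed here (the observed profiles exist only as figures); model
adequacy is instead verified by the synthetic recovery study below.

## Synthetic studies

The generator reproduces the study designs: IV bolus 10 mg/kg PA HCl with
sampling at 1, 5, 15, 30, 60, 120, 180, 240, 360, 480 min and urine
intervals 0–2, 2–4, 4–6, 6–8, 8–24 h (n = 9 per arm); and a loading dose
(1.4/1.5 mg/kg) plus 2.5 mg/kg/h infusion with sacrifice at 60 min for
Kp,ss.  Between-animal variability is lognormal with CV 20% on
clearance-type and Kp-type parameters — the dispersion of the reported
per-animal NCA parameters is of this order — and observation noise follows
the σ₁/σ₂ variance model on the concentration scale, truncated at zero.
Body weights are normal (SD 0.019 kg, the reported control SD).

What this does and does not show: passing the recovery study demonstrates
that the pipeline (generation → NCA → parameterization → ML fitting) is
self-consistent and that `Ract` is identifiable under the stated design
and noise; it does not validate the model against real rat data, because
the generator shares the model's structural assumptions (no model
misspecification, no BLQ censoring, no chromatographic error structure,
no dropout).

## Problem sizes used in the automated checks

The acceptance targets themselves are closed-form arithmetic on published
inputs (instantaneous).  The PBPK property checks integrate the 34-state
system over 1440–2000 min grids; the Monte-Carlo recovery study uses 20
replicate virtual studies of 9 rats each, fitted on arm means — about 800
ODE solves in total, chosen to give a stable median while keeping the
whole suite around a minute of compute.

## Known limitations

* No oral absorption, biliary/fecal routes, enterohepatic circulation or
  saturable (Michaelis–Menten) transport — all transport is linear, as in
  the published parameter table; the fecal route of NAPA (~1.6% of dose)
  is ignored by design.
* The rOCT1 vs rOCT2 contributions to `PSact` are not separable without
  per-transporter turnover information; only their combined fold is
  estimated.
* Kidney subvolume fractions and the lumen outflow convention are
  modelling choices exposed as configuration, not measured quantities.
* The in-silico Kp values for unsampled tissues are taken as fixed inputs;
  the tissue-composition prediction method itself is not reimplemented.
* No statistical hypothesis testing (group t-tests are out of scope); no
  plotting.
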