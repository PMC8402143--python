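"""Published study inputs for procainamide (PA) and N-acetylprocainamide (NAPA).

This module collects the drug-specific and study-specific input values used
throughout the package: physicochemical properties, observed steady-state
tissue partition coefficients, the parameter table of the control and
1,25(OH)2D3-treated arms, the non-compartmental summary statistics of both
arms, and the in vitro binding / S9 metabolism constants.  These numbers are
*inputs* in the same sense a dosing record is an input: the package derives
everything else from them.

Units follow the package-wide convention: mL, min, ug, kg body weight.
"""

from __future__ import annotations

PA = "PA"
NAPA = "NAPA"
DRUGS = (PA, NAPA)

CONTROL = "control"
TREATED = "treated"
ARMS = (CONTROL, TREATED)

# ---------------------------------------------------------------------------
# Physicochemistry and blood binding
# ---------------------------------------------------------------------------
MOLECULAR_WEIGHT = {PA: 235.33, NAPA: 277.36}  # g/mol, free base
MW_PA_HCL = 271.80  # g/mol, the administered salt
PKA = {PA: 9.04, NAPA: 9.04}  # monoprotic bases
LOGP = {PA: 0.83, NAPA: 0.93}
FUP = {PA: 0.87, NAPA: 0.688}           # plasma unbound fraction
BLOOD_PLASMA_RATIO = {PA: 1.0, NAPA: 1.0}
FU_KIDNEY = {PA: 0.223, NAPA: 0.0588}   # kidney-cell unbound fraction
FU_INC = 0.380                          # S9 incubation unbound fraction (PA)

# ---------------------------------------------------------------------------
# Observed steady-state tissue-to-plasma partition coefficients (Kp,ss)
# ---------------------------------------------------------------------------
KP_SS = {
    CONTROL: {
        PA: {"brain": 0.3904, "heart": 2.362, "kidney": 8.484,
             "liver": 0.4561, "lung": 0.9077, "spleen": 2.027},
        NAPA: {"brain": 0.1268, "heart": 2.670, "kidney": 11.86,
               "liver": 8.410, "lung": 5.448, "spleen": 6.432},
    },
    TREATED: {
        PA: {"brain": 0.2861, "heart": 1.658, "kidney": 8.775,
             "liver": 0.3059, "lung": 0.9282, "spleen": 1.507},
        NAPA: {"brain": 0.2458, "heart": 2.290, "kidney": 13.93,
               "liver": 6.338, "lung": 4.191, "spleen": 5.186},
    },
}

# In-silico predicted Kp for tissues not sampled in the infusion study
# (tissue-composition method of the original model; taken as fixed inputs).
KP_PREDICTED = {
    PA: {"adipose": 0.721, "bone": 1.96, "gut": 4.87,
         "muscle": 3.93, "skin": 2.96},
    NAPA: {"adipose": 0.967, "bone": 2.20, "gut": 6.23,
           "muscle": 4.61, "skin": 3.64},
}

# ---------------------------------------------------------------------------
# Hepatic (non-renal) elimination block
# ---------------------------------------------------------------------------
CLU_INT = {  # unbound hepatic intrinsic clearance, mL/min
    CONTROL: {PA: 47.9, NAPA: 4.04},
    TREATED: {PA: 25.0, NAPA: 4.04},
}
ER_HEPATIC = {  # hepatic extraction ratio, CLNR/QLI
    CONTROL: {PA: 0.682, NAPA: 0.125},
    TREATED: {PA: 0.529, NAPA: 0.125},
}
F_NAPA = {CONTROL: 0.562, TREATED: 0.845}  # fraction of hepatic PA loss -> NAPA
CLU_INT_FNAPA = 26.9  # mL/min, unbound intrinsic NAPA-formation clearance

# ---------------------------------------------------------------------------
# Semi-mechanistic kidney block
# ---------------------------------------------------------------------------
CLU_INT_R = {CONTROL: {PA: 4.67, NAPA: 9.16}}  # apical secretory CL, mL/min
PS_OUT = {PA: 7.61, NAPA: 7.61}                # passive basolateral CL (=PSpas)
PS_IN = {CONTROL: {PA: 22.1, NAPA: 9.59}}      # total basolateral uptake CL
CL_RABS = {PA: 0.415, NAPA: 0.415}             # tubular reabsorption CL
ER_RENAL = {  # renal extraction ratio, CLsec/QKI
    CONTROL: {PA: 0.253, NAPA: 0.195},
    TREATED: {PA: 0.0892, NAPA: 0.116},
}

# ---------------------------------------------------------------------------
# Treatment-effect scalars
# ---------------------------------------------------------------------------
RACT_FITTED = 0.675       # fitted fold change in renal active uptake
RACT_CV_PERCENT = 61.6
RMATE = 0.312             # renal rMATE1 protein fold (treated/control)
OCT1_LIVER_PROTEIN_FOLD = 0.309
SATURABLE_HEPATIC_FRACTION = 0.557
URINARY_CALIBRATION = {PA: 1.29, NAPA: 0.836}

# Published model-based treated-arm kidney Kp (footnote-b values); direct
# Eq-A12 evaluation with the footnote-d PSin gives 8.92 / 13.8 instead.
KP_KIDNEY_TREATED_PRINTED = {PA: 10.7, NAPA: 14.5}

# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------
BODY_WEIGHT_KG = {CONTROL: 0.2976, TREATED: 0.2823}  # final weights
DOSE_MG_PER_KG = 10.0  # PA HCl, IV bolus
SAMPLING_TIMES_MIN = (1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0,
                      360.0, 480.0)
URINE_INTERVALS_H = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0),
                     (8.0, 24.0))
N_ANIMALS = 9
INFUSION_LOADING_MG_PER_KG = {CONTROL: 1.4, TREATED: 1.5}
INFUSION_RATE_MG_PER_KG_H = 2.5
INFUSION_SAMPLING_TIMES_MIN = (1.0, 5.0, 15.0, 30.0, 45.0, 60.0)

# ---------------------------------------------------------------------------
# Non-compartmental summary of the two arms (arithmetic means)
# ---------------------------------------------------------------------------
NCA_SUMMARY = {
    CONTROL: {
        PA: {"auc_inf": 146.6, "t_half_beta": 52.01, "mrt": 31.62,
             "vss": 2153.0, "cl": 69.24, "cl_r": 16.29, "cl_nr": 52.95},
        NAPA: {"auc_inf": 196.7, "t_half_beta": 132.3, "cmax": 0.9958,
               "tmax": 23.33, "cl_r": 12.67},
    },
    TREATED: {
        PA: {"auc_inf": 208.5, "t_half_beta": 68.09, "mrt": 33.05,
             "vss": 1616.0, "cl": 49.72, "cl_r": 8.696, "cl_nr": 41.02},
        NAPA: {"auc_inf": 402.5, "t_half_beta": 151.6, "cmax": 1.740,
               "tmax": 16.67, "cl_r": 8.971},
    },
}
AUC_RATIO = {CONTROL: 1.328, TREATED: 1.853}

# ---------------------------------------------------------------------------
# In vitro: ultrafiltration binding and S9 formation kinetics
# ---------------------------------------------------------------------------
NSB_PERCENT_OBSERVED = 7.52
FREE_FRACTION_PLASMA = {CONTROL: 87.1, TREATED: 87.4}   # percent
FREE_FRACTION_S9 = {CONTROL: 38.3, TREATED: 38.0}       # percent
S9_FORMATION_CL_UL_MIN_MG = 1.45  # at 50 uM PA, control
S9_YIELD_MG_PER_G_LIVER = 135.0
LIVER_MASS_G = 9.0
IVIVE_SCALING_FACTOR = 5.80
S9_PROTEIN_MG_PER_ML = 2.0
S9_SUBSTRATE_UM = (50.0, 500.0, 5000.0)
S9_SAMPLE_TIMES_MIN = (0.0, 15.0, 30.0)
ULTRAFILTRATION_RESERVOIR_ML = 0.4
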