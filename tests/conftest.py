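import dataclasses

import numpy as np
import pytest

from panapk import defaults as d
from panapk.parameterization import KidneyTransportParams
from panapk.pbpk import build_model
from panapk.physiology import default_rat_physiology
from panapk.synthetic import arm_tables

CONTROL_BW = d.BODY_WEIGHT_KG[d.CONTROL]


@pytest.fixture(scope="session")
def physio():
    return default_rat_physiology(CONTROL_BW)


@pytest.fixture(scope="session")
def control_tables():
    return arm_tables(d.CONTROL)


@pytest.fixture(scope="session")
def control_model(physio, control_tables):
    pa, napa = control_tables
    return build_model(physio, pa, napa,
                       urinary_calibration=d.URINARY_CALIBRATION)


@pytest.fixture(scope="session")
def control_dose():
    """10 mg/kg PA HCl for the control-arm mean final body weight, ug."""
    return d.DOSE_MG_PER_KG * CONTROL_BW * 1000.0


def zero_kidney(table):
    """Variant of a drug table with all renal transport clearances removed."""
    return dataclasses.replace(
        table, kidney=KidneyTransportParams(ps_in=0.0, ps_pas=0.0,
                                            clu_int_r=0.0, cl_rabs=0.0,
                                            extraction_ratio=0.0))


def paper_grid():
    """The in vivo sampling grid (min) including t=0."""
    return np.concatenate([[0.0], np.asarray(d.SAMPLING_TIMES_MIN)])
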