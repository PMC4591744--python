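import math

import numpy as np
import pytest

from gfrmodels.cohort import Cohort, PatientRecord
from gfrmodels.equations import SplineEquationModel


def make_record(i=0, sex="male", age=60.0, scr=0.9, **kw):
    return PatientRecord(id=f"p{i}", sex=sex, age=age, scr=scr, **kw)


@pytest.fixture
def small_cohort():
    """Six hand-written records with full covariates and sGFR."""
    recs = [
        make_record(0, "male", 60, 0.9, bmi=24.0, hba1c=7.5, uacr=20.0, sgfr=90.0),
        make_record(1, "female", 55, 0.7, bmi=22.5, hba1c=8.2, uacr=35.0, sgfr=95.0),
        make_record(2, "male", 70, 1.4, bmi=27.0, hba1c=9.0, uacr=150.0, sgfr=55.0),
        make_record(3, "female", 48, 0.6, bmi=21.0, hba1c=6.5, uacr=10.0, sgfr=105.0),
        make_record(4, "male", 65, 2.1, bmi=26.0, hba1c=8.8, uacr=400.0, sgfr=35.0),
        make_record(5, "female", 72, 1.1, bmi=25.5, hba1c=7.1, uacr=80.0, sgfr=60.0),
    ]
    return Cohort(records=recs)


@pytest.fixture
def truth_model():
    """A known generating spline equation with all three covariates."""
    return SplineEquationModel(
        intercept=4.81,
        slope_below=-0.35,
        slope_above=-1.2,
        age_coef=math.log(0.993),
        female_coef=math.log(1.018),
        covariate_coefs={"bmi": -0.004, "hba1c": 0.01, "uacr": -0.0002},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
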