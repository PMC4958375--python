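import numpy as np
import pytest

from bcv.choice import SubjectParams, model_spec
from bcv.synthetic import generate_exp1_schedule, generate_exp2_schedule, simulate_choices


@pytest.fixture(scope="session")
def exp1_schedule():
    return generate_exp1_schedule(seed=101)


@pytest.fixture(scope="session")
def exp2_schedule():
    return generate_exp2_schedule(seed=202)


@pytest.fixture(scope="session")
def exp1_session(exp1_schedule):
    """One simulated variance-task session from a value-sensitive subject."""
    params = SubjectParams(alpha=1.5, rho=0.3, tau=0.5)
    return simulate_choices(
        exp1_schedule, params, model_spec("full", "exp1"), seed=7, subject_id="s000"
    )


@pytest.fixture(scope="session")
def exp2_session(exp2_schedule):
    """One simulated deck-task session with positive context weights."""
    params = SubjectParams(alpha=1.2, rho=-0.2, tau_lo=0.4, tau_hi=0.3)
    return simulate_choices(
        exp2_schedule, params, model_spec("full", "exp2"), seed=8, subject_id="s000"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
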