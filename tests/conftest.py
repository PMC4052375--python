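import pytest

from kvinact import DEFAULT_ACTIVATION, FitConstraints, GatingProtocol

# Reported per-construct gate rates (k_on, k_off) in s^-1: four free
# inactivation gates (homotetramer), one gate (wild-type concatemer),
# one gate with all four cavity sites mutated to valine.
REPORTED_RATES = {
    "homotetramer": (430.0, 21.0),
    "wt_concatemer": (108.0, 40.0),
    "concatemer_4v": (90.0, 163.0),
}


@pytest.fixture
def protocol():
    return GatingProtocol(duration=60.0)


@pytest.fixture
def short_protocol():
    # small grid to keep optimiser-heavy tests quick
    return GatingProtocol(duration=30.0, pre_step_baseline=2.0)


@pytest.fixture
def constraints():
    return FitConstraints(fixed_activation=DEFAULT_ACTIVATION)
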