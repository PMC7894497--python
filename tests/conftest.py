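import numpy as np
import pytest

import coformkin as ck
from coformkin import datasets


@pytest.fixture(scope="session")
def ppp_apps():
    """Packaged PPP composition table keyed by (trial, substance)."""
    return datasets.application_rates()


@pytest.fixture(scope="session")
def day0_table():
    """Packaged measured day-0 residues with printed normalized values."""
    return datasets.load_day0_residues()


@pytest.fixture(scope="session")
def scaled_table():
    return ck.load_scaled_day0_table()


@pytest.fixture
def sfo_scenario():
    """Noise-free SFO scenario: c0 10 mg/kg, DT50 2 d, default schedule."""
    return ck.TrialScenario(
        truth_params=ck.SfoParams(c0=10.0, k=float(np.log(2.0) / 2.0)),
        cv_pct=0.0,
        seed=1,
    )


def make_series(days, means, loq=0.001, crop="crop", substance="sub"):
    """Series with one replicate per day at the given mean concentrations."""
    ms = tuple(
        ck.Measurement(day=d, replicate_values=(v,), loq=loq) for d, v in zip(days, means)
    )
    return ck.ResidueTimeSeries(crop=crop, substance=substance, measurements=ms)
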