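import numpy as np
import pytest

from vertmech import CurveModelParams, generate_curve

# Group means of the reference rat cohort: (stiffness N/mm, yield N,
# maximum N, failure N) for sham-operated and ovariectomized animals.
SHAM_MEANS = {"stiffness": 174.2, "yield_load": 134.6,
              "max_load": 154.2, "failure_load": 143.8}
OVX_MEANS = {"stiffness": 133.2, "yield_load": 125.8,
             "max_load": 133.5, "failure_load": 123.4}


def make_params(means, **overrides):
    kwargs = dict(elastic_slope=means["stiffness"],
                  yield_load=means["yield_load"],
                  max_load=means["max_load"],
                  failure_load=means["failure_load"])
    kwargs.update(overrides)
    return CurveModelParams(**kwargs)


def random_params(rng, **overrides):
    """Physically plausible random specimen parameters."""
    max_load = rng.uniform(90.0, 200.0)
    kwargs = dict(
        elastic_slope=max_load * rng.uniform(1.0, 1.4),
        yield_load=max_load * rng.uniform(0.78, 0.96),
        max_load=max_load,
        failure_load=max_load * rng.uniform(0.65, 0.93))
    kwargs.update(overrides)
    return CurveModelParams(**kwargs)


@pytest.fixture(scope="session")
def sham_curve():
    return generate_curve(make_params(SHAM_MEANS))


@pytest.fixture(scope="session")
def ovx_curve():
    return generate_curve(make_params(OVX_MEANS))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
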