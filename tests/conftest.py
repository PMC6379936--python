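import numpy as np
import pytest

from oggkit import BurstParams, TimeCourse
from oggkit.synthetic import DEFAULT_TIMES, default_variants, gen_time_course


@pytest.fixture(scope="session")
def variants():
    return default_variants()


@pytest.fixture(scope="session")
def wt_spec(variants):
    return variants["Wild-type"]


@pytest.fixture
def wt_noiseless_tc(wt_spec):
    """Exact burst-model curve for the wild-type parameters."""
    return gen_time_course(wt_spec, noise_sd=0.0, n_reps=1)[0]


def make_tc(times, products, substrate_total=20.0, variant="x", condition="std",
            replicate="r1"):
    t = np.asarray(times, dtype=float)
    return TimeCourse(
        variant=variant,
        condition=condition,
        substrate_total=substrate_total,
        time=t,
        product=np.asarray(products, dtype=float),
        replicate=np.array([replicate] * t.size),
    )


@pytest.fixture
def line_tc():
    """Burstless data: a pure steady-state line P = 0.14 t."""
    t = np.array(DEFAULT_TIMES)
    return make_tc(t, 0.14 * t)
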