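import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lomaxg import NLWParams, datasets

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


# Published point estimates (alpha, lam, theta, beta, c) for the four
# packaged datasets, used for fixed-parameter evaluation.
REFERENCE_FITS = {
    "failure_times": NLWParams(alpha=0.0636, lam=0.6008, theta=1.4638,
                               beta=1.5414, c=2.0284),
    "gauge_lengths": NLWParams(alpha=5.4361, lam=-1.8154, theta=3.1189,
                               beta=4.3767, c=0.4850),
    "strength": NLWParams(alpha=2.0395, lam=1.5950, theta=3.4368,
                          beta=3.9508, c=3.0019),
    "student_grades": NLWParams(alpha=0.2493, lam=-3.8664, theta=7.1817,
                                beta=1.7261, c=0.6840),
}


@pytest.fixture(scope="session")
def reference_fits():
    return REFERENCE_FITS


@pytest.fixture(scope="session")
def failure_times():
    return datasets.load_dataset("failure_times")


@pytest.fixture(scope="session")
def gauge_lengths():
    return datasets.load_dataset("gauge_lengths")


@pytest.fixture(scope="session")
def set2_params():
    """A moderately skewed NLW truth used across simulation-flavoured tests."""
    return NLWParams(alpha=1.9, beta=1.2, lam=0.07, theta=2.5, c=1.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_admissible_params(rng, n):
    """n random parameter vectors inside well-conditioned ranges."""
    out = []
    for _ in range(n):
        out.append(NLWParams(
            alpha=float(rng.uniform(0.3, 4.0)),
            beta=float(rng.uniform(0.4, 3.0)),
            lam=float(rng.uniform(-2.0, 3.0)),
            theta=float(rng.uniform(0.3, 4.0)),
            c=float(rng.uniform(0.4, 3.0)),
        ))
    return out
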