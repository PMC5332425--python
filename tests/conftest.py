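import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Printed per-group summary moments of the prosociality evaluation."""
    from latentchange.datasets import prosociality_summary
    return prosociality_summary()


@pytest.fixture(scope="session")
def model2_fit(table1):
    """Model 2 fitted once to the printed summary statistics."""
    from latentchange import fit_ml_summary
    from latentchange.sequence import build_step_model
    return fit_ml_summary(build_step_model("M2"), table1)


def random_psd(rng, p, scale=1.0):
    a = rng.normal(size=(p, p))
    return scale * (a @ a.T / p + 0.1 * np.eye(p))
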