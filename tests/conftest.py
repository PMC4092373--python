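import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fine_grid():
    """Dense potential grid for numeric oracles (V)."""
    return np.linspace(-0.6, 0.4, 200001)


@pytest.fixture(scope="session")
def analyzed_fixtures():
    """Noise-free registry fixtures run once through the full pipeline."""
    from flavodpv import pipeline, synth

    out = {}
    for name in synth.fixture_names():
        v = synth.make_dpv_fixture(name, noise_sd=0.0, seed=0)
        result, report = pipeline.analyze(v)
        out[name] = (v, result, report)
    return out
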