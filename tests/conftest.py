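import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_922)


@pytest.fixture(scope="session")
def tiny_library_text():
    return "\n".join(
        [
            "nif (nitrogen fixation): K02586+K02591+K02588",
            "dnra (DNRA): K00362+K00363 | K03385+K15876",
            "twostep (two independent steps): K00001; K00002",
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by read-only tests."""
    from trenchomics import default_config, generate_cohort

    return generate_cohort(default_config(seed=11, genes_per_sample=600))
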