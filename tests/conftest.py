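import warnings

import pytest

from mammotriage.cascade import CascadeConfig
from mammotriage.synthetic import CohortSpec, generate_patients


@pytest.fixture(scope="session")
def cascade_config() -> CascadeConfig:
    """The packaged demo cascade (rule bases + encoding), loaded once."""
    return CascadeConfig.default()


@pytest.fixture(scope="session")
def demo_cohort():
    """A 130-patient labeled synthetic cohort (reference-cohort geometry)."""
    return generate_patients(CohortSpec(seed=7))


@pytest.fixture(autouse=True)
def _silence_heywood_warnings():
    """Heywood warnings are expected on cascade-derived tables; keep logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Heywood case", category=RuntimeWarning)
        yield
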