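import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from dyadkin.demography import IndividualRecord, ParentageRecord  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_record(
    id,
    sex="male",
    birth=dt.date(1990, 1, 1),
    natality="natal",
    residency_start=None,
    residency_end=None,
    genotyped=True,
    **kwargs,
):
    """Terse builder for one-interval residency records."""
    start = residency_start or birth
    return IndividualRecord(
        id=id,
        sex=sex,
        birth_date=birth,
        natality=natality,
        residency=[(start, residency_end)],
        in_genetic_dataset=genotyped,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated community with genotypes, reused across tests."""
    from dyadkin.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(seed=11, years=30, n_founders=30, n_sites=3000, panel_size=50)
    return simulate_dataset(cfg)
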