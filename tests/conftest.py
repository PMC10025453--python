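import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """One strongly planted module plus decoys; shared across tests."""
    from pcmkit import PlantedModule, SyntheticCohortSpec, generate

    spec = SyntheticCohortSpec(
        n_samples=120,
        n_genes=400,
        planted=[PlantedModule(size=30, activation_fraction=0.4,
                               shift=2.5, log_hr=1.2, motif="TGACGTCA")],
        n_decoys=8,
        seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    from pcmkit import score_cohort
    from pcmkit.io import standardize

    z = standardize(small_cohort.expression)
    return score_cohort(small_cohort.catalog, z, Ne=10, n_rand=200, seed=5)


@pytest.fixture()
def toy_outcomes():
    rng = np.random.default_rng(11)
    n = 80
    return pd.DataFrame(
        {"time": rng.exponential(20, n), "event": rng.random(n) < 0.7},
        index=[f"p{i:03d}" for i in range(n)],
    )
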