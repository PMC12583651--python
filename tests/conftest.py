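import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from copulanet import (
    CohortTable,
    default_config,
    generate_cohort,
    merged_dictionary,
    split_dictionary,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 110-participant cohort from the study-like generator."""
    cfg = default_config(
        seed=42,
        structure="random",
        stage_effects=True,
        group_sizes={"CN": 40, "EMCI": 30, "LMCI": 20, "AD": 20},
    )
    cohort, model = generate_cohort(cfg)
    return cohort, model


@pytest.fixture()
def split_table():
    """A tiny valid split-mode (31-variable) cohort built by hand."""
    rng = np.random.default_rng(7)
    d = split_dictionary()
    n = 12
    cols = {}
    for spec in d:
        if spec.name == "age":
            cols[spec.name] = rng.uniform(60, 90, n)
        elif spec.name == "edu":
            cols[spec.name] = rng.integers(8, 21, n)
        elif spec.levels is not None:
            cols[spec.name] = rng.choice(spec.levels, n)
        elif spec.role == "cognitive":
            cols[spec.name] = rng.uniform(-2.5, 2.5, n)
        else:
            cols[spec.name] = rng.uniform(0.5, 2.0, n)
    values = pd.DataFrame(cols, columns=d.names)
    diagnosis = pd.Series(rng.choice(["CN", "EMCI", "LMCI", "AD"], n))
    return CohortTable(values=values, diagnosis=diagnosis, dictionary=d)


@pytest.fixture(scope="session")
def gaussian_latent_p3():
    """n=60 standardized draws from a known 3-variable Gaussian graphical model."""
    rng = np.random.default_rng(5)
    K = np.array([[1.0, 0.5, 0.0], [0.5, 1.3, -0.4], [0.0, -0.4, 1.1]])
    Z = rng.multivariate_normal(np.zeros(3), np.linalg.inv(K), size=60)
    return (Z - Z.mean(0)) / Z.std(0)
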