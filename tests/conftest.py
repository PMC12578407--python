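import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hepnet import (
    ExpressionMatrix,
    ModuleSpec,
    SyntheticStudySpec,
    generate_multi_cohort,
)


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared by read-only tests: 2 modules of 10
    genes, 30 background genes, 3 cohorts of 40 samples."""
    spec = SyntheticStudySpec(
        n_cohorts=3,
        samples_per_cohort=40,
        modules=(ModuleSpec("M1", 10, 0.6), ModuleSpec("M2", 10, 0.6)),
        n_background_genes=30,
        seed=11,
    )
    matrices, truth = generate_multi_cohort(spec)
    return spec, matrices, truth


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.normal(8.0, 1.0, (6, 8)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{j}" for j in range(8)],
    )
    return ExpressionMatrix(df, "toy")
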