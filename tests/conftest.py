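import numpy as np
import pandas as pd
import pytest

import immunecycle as ic


@pytest.fixture(scope="session")
def panels():
    return ic.builtin_panel_set()


@pytest.fixture(scope="session")
def signatures():
    return ic.builtin_signatures()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=99, planted three-subgroup pattern)."""
    return ic.generate(ic.SyntheticCohortConfig(seed=1))


@pytest.fixture(scope="session")
def fitted_results(default_cohort):
    model = ic.ImmuneSubgroupModel(default_cohort.expression, k=3)
    return model.fit(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_raw_matrix(rng, n_genes=20, n_samples=8, prefix="G"):
    values = pd.DataFrame(
        rng.uniform(0, 100, size=(n_genes, n_samples)),
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"S{j:03d}" for j in range(n_samples)])
    return ic.ExpressionMatrix(values=values, state="raw")
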