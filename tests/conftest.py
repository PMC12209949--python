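import numpy as np
import pandas as pd
import pytest

from tiernet.cohort import CohortTable, VariableSpec


@pytest.fixture
def small_truth():
    from tiernet.synthetic_cohort import nesda_like_truth

    return nesda_like_truth(1, n_biomarkers=6)


@pytest.fixture
def gauss_table_factory():
    """Equicorrelated Gaussian biomarker tables for imputation/outlier tests."""

    def make(n: int, p: int, seed: int, r: float = 0.5) -> CohortTable:
        rng = np.random.default_rng(seed)
        cov = np.full((p, p), r)
        np.fill_diagonal(cov, 1.0)
        X = rng.multivariate_normal(np.zeros(p), cov, size=n)
        specs = [VariableSpec(f"v{i}", "continuous", 1, "biomarker") for i in range(p)]
        return CohortTable(pd.DataFrame(X, columns=[s.name for s in specs]), specs)

    return make


@pytest.fixture
def mediation_table_factory():
    """Exposure -> mediator -> outcome tables with known path coefficients."""

    def make(n: int, seed: int, a: float = 0.5, b: float = 0.4, c: float = 0.3, binary_outcome: bool = True):
        rng = np.random.default_rng(seed)
        d = (rng.random(n) < 0.5).astype(float)
        m = a * d + rng.normal(size=n)
        if binary_outcome:
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-2.0 + c * d + b * m)))).astype(float)
            okind = "binary"
        else:
            y = c * d + b * m + rng.normal(size=n)
            okind = "continuous"
        specs = [
            VariableSpec("D", "binary", 0, "exposure"),
            VariableSpec("M", "continuous", 1, "biomarker"),
            VariableSpec("Y", okind, 2, "outcome"),
        ]
        return CohortTable(pd.DataFrame({"D": d, "M": m, "Y": y}), specs)

    return make
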