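import numpy as np
import pandas as pd
import pytest

from nactrisk import CohortSpec, MutationMatrix, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """56-sample cohort with 6 planted resistance genes among 120."""
    spec = CohortSpec(
        n_nonresponder=30, n_responder=26, n_genes=120,
        causal_genes=[(f"G{i:04d}", 0.45, 0.04) for i in range(1, 7)],
        background_rate=0.03, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_matrix():
    """Hand-built 6-sample, 4-gene matrix with one perfect predictor."""
    data = pd.DataFrame(
        {"GA": [1, 1, 1, 0, 0, 0],   # perfectly tracks non-response
         "GB": [1, 0, 1, 0, 1, 0],
         "GC": [0, 1, 0, 0, 0, 1],
         "GD": [1, 1, 0, 1, 0, 0]},
        index=[f"S{i}" for i in range(6)],
    )
    labels = pd.Series(["non_responder"] * 3 + ["responder"] * 3,
                       index=data.index)
    return MutationMatrix(data, labels)
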