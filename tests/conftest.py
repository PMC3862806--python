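import numpy as np
import pandas as pd
import pytest

from samflow import ExpressionMatrix, SimConfig, generate_cohort


def make_matrix(values, sample_groups=None, prefix="g"):
    """ExpressionMatrix from a 2-D array; columns annotated by group labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    cols = [f"s{j}" for j in range(n_samples)]
    df = pd.DataFrame(
        values,
        index=pd.Index([f"{prefix}{i}" for i in range(n_genes)], name="probeset_id"),
        columns=cols,
    )
    if sample_groups is None:
        samples = None
    else:
        samples = pd.DataFrame(
            {"phenotype": list(sample_groups), "condition": "S"},
            index=df.columns,
        )
    return ExpressionMatrix(df, samples)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact study-design cohort with planted DE and its truth table."""
    cfg = SimConfig(n_genes=1200, n_de=120, seed=7)
    return (*generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Same design with nothing planted and no array effects."""
    cfg = SimConfig(n_genes=1200, n_de=0, array_effect_sd=0.0, seed=11)
    return (*generate_cohort(cfg), cfg)
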