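import numpy as np
import pandas as pd
import pytest

from progmir import synthetic
from progmir.study import ExpressionStudy


def make_study(values, groups, dataset_id="test", feature_prefix="f",
               sample_prefix="s"):
    """Small helper: wrap a 2-D array into an ExpressionStudy."""
    values = np.asarray(values, dtype=float)
    fids = [f"{feature_prefix}{i}" for i in range(values.shape[0])]
    sids = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=fids, columns=sids)
    ann = pd.DataFrame({"group": list(groups), "dataset_id": dataset_id,
                        "compartment": "tissue"}, index=sids)
    return ExpressionStudy(values=vals, annotations=ann, dataset_id=dataset_id)


@pytest.fixture(scope="session")
def small_cohort():
    """One small planted cohort shared by read-only tests."""
    cfg = synthetic.SimConfig(seed=11, n_genes=400, n_mirnas=150,
                              targets_per_mirna=20)
    studies, interactions, truth = synthetic.generate_cohort(cfg)
    return cfg, studies, interactions, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
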