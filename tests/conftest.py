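import logging

import numpy as np
import pandas as pd
import pytest

logging.getLogger("simpomr").setLevel(logging.ERROR)


@pytest.fixture
def worked_example():
    """One gene: body betas [0.6, 0.8], promoter betas [0.2, 0.4]."""
    beta = pd.DataFrame(
        {"s1": [0.6, 0.8, 0.2, 0.4]}, index=pd.Index(["b1", "b2", "p1", "p2"], name="probe_id")
    )
    annot = pd.DataFrame(
        {
            "probe_id": ["b1", "b2", "p1", "p2"],
            "gene": ["G"] * 4,
            "region": ["body", "body", "promoter", "promoter"],
        }
    )
    return beta, annot


@pytest.fixture
def two_snp_pairs():
    """The hand-checkable two-instrument set: ratios 0.5 and 0.4, equal weights."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2"],
            "beta_exp": [0.1, 0.2],
            "se_exp": [0.01, 0.01],
            "beta_out": [0.05, 0.08],
            "se_out": [0.01, 0.02],
        }
    )


def random_pairs(rng, n=10):
    """Random harmonized instrument pairs for oracle comparisons."""
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(n)],
            "beta_exp": rng.normal(0.15, 0.07, n),
            "se_exp": rng.uniform(0.005, 0.02, n),
            "beta_out": rng.normal(0.05, 0.05, n),
            "se_out": rng.uniform(0.005, 0.02, n),
        }
    )


@pytest.fixture
def pairs_factory():
    return random_pairs
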