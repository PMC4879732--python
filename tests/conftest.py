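import warnings

import numpy as np
import pandas as pd
import pytest

import cagpipe as cp
from cagpipe.synthetic import GeneratorConfig, default_blocks, default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def cohort(design):
    """A strong-signal 60-genus cohort over the full 371-sample design.

    Session-scoped: generated once and reused by CAG, subject-clustering
    and pipeline tests.
    """
    gids = [f"g{i:03d}" for i in range(1, 61)]
    blocks = default_blocks(gids, n_blocks=9, rho_within=0.9, effect_size=2.5)
    config = GeneratorConfig(n_genera=60, blocks=blocks, seed=11)
    metadata = cp.sample_metadata(design, seed=11)
    counts = cp.sample_genus_counts(config, metadata)
    return {
        "config": config,
        "blocks": blocks,
        "metadata": metadata,
        "counts": counts,
        "relative": cp.to_relative(counts),
    }


@pytest.fixture(scope="session")
def cohort_corr(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cp.kendall_matrix(cohort["relative"])


@pytest.fixture(scope="session")
def cohort_zscores(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cp.zscore_table(cohort["relative"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_table():
    df = pd.DataFrame(
        [[10, 30, 0], [5, 5, 10], [1, 0, 3]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB", "gC"],
    )
    return cp.GenusAbundanceTable(df, "counts")
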