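"""Shared fixtures: small synthetic datasets and a fitted classifier."""

import numpy as np
import pandas as pd
import pytest

from oostage import classifier as C
from oostage import expression as E
from oostage.simulate import SimConfig, simulate_counts, simulate_methylomes


def make_count_matrix(counts: dict, stages: dict) -> E.CountMatrix:
    """Tiny CountMatrix from {sample: [counts...]} plus {sample: stage}."""
    df = pd.DataFrame(counts)
    df.index = [f"t{i}" for i in range(len(df))]
    meta = pd.DataFrame({"stage": pd.Series(stages)})
    return E.CountMatrix(df, meta)


@pytest.fixture(scope="session")
def ref_sim():
    """Reference cohort (9 NSN / 16 SN) with the planted SN signature."""
    cfg = SimConfig(seed=11)
    matrix, truth = simulate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def de_table(ref_sim):
    _, matrix, _ = ref_sim
    return E.differential_expression(matrix)


@pytest.fixture(scope="session")
def fitted_model(ref_sim, de_table):
    _, matrix, truth = ref_sim
    ref_degs = truth.degraded_ids + truth.missing_ids + truth.upregulated_ids
    model = C.build_classifier(de_table, ref_degs)
    return C.fit_reference(model, matrix)


SMALL_METH_GRAMMAR = {
    "unmethylated": (0.30, 30_000),
    "intermediate": (0.49, 25_000),
    "methylated": (0.21, 30_000),
}


def small_meth_config(seed: int = 5, **overrides) -> SimConfig:
    base = dict(
        seed=seed,
        genome_spec=(("chr1", 3_000_000), ("chr2", 3_000_000)),
        domain_grammar=dict(SMALL_METH_GRAMMAR),
        min_domain_length=10_000,
        n_planted_dmrs=5,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def meth_small():
    cfg = small_meth_config()
    cells, domains, truth = simulate_methylomes(cfg)
    return cfg, cells, domains, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
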