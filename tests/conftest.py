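"""Shared fixtures: one session-scoped synthetic cohort run end to end."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncnet.data_model import CountMatrix
from lncnet.pipeline import run_all
from lncnet.simulate import SimConfig, simulate, simulate_reference_de


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions, seed 0."""
    return simulate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline run on the default synthetic cohort."""
    ref, counts3 = simulate_reference_de(default_sim.truth, seed=0)
    report = run_all(
        default_sim.counts,
        default_sim.annotation,
        default_sim.gene_sets,
        reference_log2fc=ref,
        reference_counts=counts3,
        disease_set_ids=list(default_sim.truth.pathways),
        seed=0,
    )
    return default_sim, report


def make_count_matrix(values, groups=("healthy", "healthy", "healthy", "tumour", "tumour", "tumour")):
    """Small raw CountMatrix from a 2-d array."""
    values = np.asarray(values)
    samples = [f"S{i + 1}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"g{i + 1}" for i in range(values.shape[0])], columns=samples)
    return CountMatrix(df, pd.Series(list(groups), index=samples), "raw")
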