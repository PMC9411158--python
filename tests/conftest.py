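"""Shared fixtures: the default synthetic world (seed 1) and small builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from comorbnet import PipelineConfig, WorldParams, generate_world, run_pipeline
from comorbnet.moa import MOAProfile

#: Small world used by tests that only need structure, not statistical power.
SMALL_PARAMS = WorldParams(
    n_drugs=60,
    n_proteins=200,
    n_diseases=10,
    module_size=10,
    targets_from_module=8,
    background_targets=2,
    n_planted_pairs=2,
    n_tissues=4,
    tissues_per_disease=2,
    n_decoy_pathways=5,
)


@pytest.fixture(scope="session")
def default_world():
    """The reference study conditions at seed 1."""
    return generate_world(WorldParams(), seed=1)


@pytest.fixture(scope="session")
def default_pipeline(default_world):
    profiles, edges = run_pipeline(default_world.inputs)
    return profiles, edges


@pytest.fixture(scope="session")
def small_world():
    return generate_world(SMALL_PARAMS, seed=1)


def make_profile(disease: str, pmap: dict, eff=()) -> MOAProfile:
    """Profile with a prescribed protein -> p map (all proteins in the MOA set)."""
    table = pd.DataFrame(
        {
            "protein": list(pmap),
            "n1t": 1,
            "n2t": 0,
            "rr": np.inf,
            "p": list(pmap.values()),
            "q": list(pmap.values()),
            "passed_tissue_filter": 1,
        }
    )
    return MOAProfile(disease, frozenset(pmap), table, frozenset(eff))


def make_edges(rows) -> pd.DataFrame:
    """Edge frame from (a, b, ns, j, p, q, significant) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "disease_a",
            "disease_b",
            "n_shared",
            "j_score",
            "p_value",
            "q_value",
            "significant",
        ],
    )


@pytest.fixture
def default_config():
    return PipelineConfig()
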