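import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mycorrnet as mn
from mycorrnet.preprocess import filter_genes, log2_cpm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_sim_config(seed: int = 0, **overrides) -> mn.SimConfig:
    """Reduced synthetic config for fast unit tests: 45 samples,
    300 genes per organism with two planted 60-gene modules."""
    base = dict(
        host_n_genes=300,
        sym_n_genes=300,
        host_module_sizes=(60, 60),
        sym_module_sizes=(60, 60),
        host_module_classes=("interaction", "interaction"),
        sym_module_classes=("isolate_conserved", "cultivar_only"),
        cross_links=((1, 1, +1, 0.9), (2, 2, -1, 0.9)),
        trait_loadings=(
            ("host_M1", "colonization", 1.0),
            ("host_M2", "plant_dry_weight", 0.8),
        ),
        seed=seed,
    )
    base.update(overrides)
    return mn.SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return mn.simulate_dataset(small_sim_config(seed=11))


@pytest.fixture(scope="session")
def small_expr(small_sim):
    """log2-CPM host and symbiont expression of the small dataset."""
    host = log2_cpm(
        filter_genes(small_sim.host_counts, 1.0, 3, design=small_sim.design)
    )
    sym = log2_cpm(
        filter_genes(small_sim.sym_counts, 1.0, 3, design=small_sim.design)
    )
    return {"host": host, "symbiont": sym}


@pytest.fixture(scope="session")
def design_45():
    return mn.generate_design(5, 3, 3, 3, seed=1)


def zero_noise_expression(design: pd.DataFrame, patterns: dict) -> mn.ExpressionMatrix:
    """Noise-free expression built directly from per-sample patterns.

    ``patterns`` maps gene id -> per-sample value array; the result is
    the deterministic limit of the generative model where the only
    variation is the planted design response.
    """
    mat = pd.DataFrame(
        {g: np.asarray(v, dtype=float) for g, v in patterns.items()},
        index=design.index,
    ).T
    return mn.ExpressionMatrix(mat, organism="host")


def map_detected_to_planted(detected: np.ndarray, truth: np.ndarray) -> dict:
    """Best-overlap map detected module id -> planted module id."""
    out = {}
    for k in sorted(set(detected[detected > 0])):
        members = truth[detected == k]
        members = members[members > 0]
        if len(members):
            vals, counts = np.unique(members, return_counts=True)
            out[k] = int(vals[np.argmax(counts)])
    return out
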