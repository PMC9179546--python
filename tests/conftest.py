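"""Shared fixtures: small hand-made datasets and one session-scoped
trained model on the default synthetic cohort (grid 20 for speed)."""

from __future__ import annotations

import numpy as np
import pytest

import combisom as cs
from combisom import Modality

COHORT_SEED = 7
SOM_SEED = 11
GRID = 20


def make_matrix(modality, values, genes=None, samples=None, **flags):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return cs.OmicsMatrix(modality, tuple(genes), tuple(samples), values, **flags)


def make_dataset(rng, n_genes=12, n_samples=6):
    """Small random dataset with matching indices across modalities."""
    mats = [
        make_matrix(m, rng.normal(size=(n_genes, n_samples)) * scale)
        for m, scale in zip((Modality.GEX, Modality.DME, Modality.CNV), (2.0, 0.5, 1.0))
    ]
    return cs.MultiOmicsDataset(*mats)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)


@pytest.fixture(scope="session")
def cohort():
    return cs.default_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def harmonized(cohort):
    dataset, _ = cohort
    return cs.harmonize(cs.centralize_dataset(dataset))


@pytest.fixture(scope="session")
def profiles(harmonized):
    return cs.combine(harmonized, cs.weight_preset("balanced"))


@pytest.fixture(scope="session")
def model(profiles):
    return cs.train_som(profiles, grid_side=GRID, seed=SOM_SEED)


@pytest.fixture(scope="session")
def decomposed(model):
    return cs.decompose(model)


@pytest.fixture(scope="session")
def groups(cohort):
    dataset, _ = cohort
    return dataset.groups()


@pytest.fixture(scope="session")
def cohort_group_portraits(model, decomposed, groups):
    out = []
    for m in cs.MODALITIES:
        out.extend(cs.group_portraits(model, decomposed, groups, m).values())
    return out


@pytest.fixture(scope="session")
def summary_spots(cohort_group_portraits, model):
    label_grid, spots = cs.spot_summary_map(cohort_group_portraits, model, 0.9)
    return label_grid, spots
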