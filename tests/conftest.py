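"""Shared fixtures: fixtures are generated programmatically, never stored.

The "tiny" chain (dataset -> curation -> features -> matrix -> model) is
session-scoped because several interpretation tests reuse the same fitted
forest; it is small enough to fit in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from slc5pcm import (
    SyntheticSpec,
    assemble,
    curate,
    generate_dataset,
    morgan_features,
    sandberg_zscales,
    slc5_residue_table,
    stratified_split,
    train,
    variable_positions,
)

TINY_RF = {"n_estimators": 80, "max_features": 0.3}


@pytest.fixture(scope="session")
def ztable():
    return sandberg_zscales()


@pytest.fixture(scope="session")
def table2_profiles():
    return slc5_residue_table()


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(n_scaffolds=8, series_size=10, seed=11, noise_sd=0.2)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_curated(tiny_spec, tiny_dataset):
    records, _ = tiny_dataset
    return curate(records, profiles=tiny_spec.targets)


@pytest.fixture(scope="session")
def tiny_block(tiny_curated):
    mols = tiny_curated.molecules
    return morgan_features(
        mols["standardized_smiles"].tolist(), mols["inchikey"].tolist()
    )


@pytest.fixture(scope="session")
def tiny_matrix(tiny_spec, tiny_curated, tiny_block, ztable):
    positions = variable_positions(tiny_spec.targets)
    return assemble(
        tiny_curated.datapoints, tiny_block, tiny_spec.targets, positions, ztable
    )


@pytest.fixture(scope="session")
def tiny_split(tiny_matrix):
    return stratified_split(tiny_matrix, 0.7, seed=1)


@pytest.fixture(scope="session")
def tiny_rf(tiny_matrix, tiny_split):
    return train(
        tiny_matrix, tiny_split, "rf", hyperparameters=TINY_RF, seed=1,
        compute_cv=False,
    )
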