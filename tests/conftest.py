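"""Shared fixtures: a seed-fixed toy study library and a trained splitter.

The study conditions — dictionary sizes, junction-type mix, library size and
seeds — are fixed here once and shared across tests so expensive steps
(library generation, pipeline training) run once per session.
"""

from __future__ import annotations

import pytest

import protacut as pc

STUDY_SPEC = pc.ToyDictionarySpec(n_warheads=32, n_linkers=48, n_e3=32, seed=7)
LIBRARY_SEED = 42
TRAIN_SIZE = 2000
TEST_SIZE = 500


@pytest.fixture(scope="session")
def toy_dicts():
    return pc.make_toy_dictionaries(STUDY_SPEC)


@pytest.fixture(scope="session")
def connection_p():
    return pc.toy_connection_distribution()


@pytest.fixture(scope="session")
def study_library(toy_dicts, connection_p):
    d_wh, d_link, d_e3 = toy_dicts
    return pc.sample_and_assemble(
        d_wh, d_link, d_e3, connection_p, TRAIN_SIZE + TEST_SIZE, seed=LIBRARY_SEED
    )


@pytest.fixture(scope="session")
def train_library(study_library):
    return study_library[:TRAIN_SIZE]


@pytest.fixture(scope="session")
def heldout_library(study_library):
    return study_library[TRAIN_SIZE:]


@pytest.fixture(scope="session")
def train_records(train_library):
    config = pc.SplitterConfig(seed=LIBRARY_SEED)
    return pc.records_from_annotations(train_library, config)


@pytest.fixture(scope="session")
def trained_splitter(train_records, train_library):
    config = pc.SplitterConfig(seed=LIBRARY_SEED)
    model = pc.train_pipeline(train_records, config)
    e3_ref = pc.build_e3_reference([a.e3 for a in train_library], seed=LIBRARY_SEED)
    return model, e3_ref
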