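"""Shared fixtures.

The reference study (synthetic corpora + trained models) is expensive, so
it is built once per session and shared by the pipeline-level and
acceptance tests.
"""

from __future__ import annotations

import random

import pytest

import binomen.workflows as workflows
from binomen.synthetic import SynthSpec, gen_corpus
from binomen.trainset import train_pipeline


@pytest.fixture(scope="session")
def study_data():
    return workflows.reference_data(workflows.REFERENCE_SEED)


def _build(data, classifier="nb", cspan=1, use_stoplist=True):
    config = workflows.reference_config(classifier, cspan, use_stoplist, data.seed_names)
    model = train_pipeline(
        data.seed_names, data.negative_doc, [data.bootstrap_doc], config)
    return model, config


@pytest.fixture(scope="session")
def nb_reference(study_data):
    """Naive Bayes model under the reference conditions (cspan 1, stop-list)."""
    return _build(study_data, "nb")


@pytest.fixture(scope="session")
def maxent_reference(study_data):
    """MaxEnt (GIS) model under the reference conditions."""
    return _build(study_data, "maxent")


@pytest.fixture(scope="session")
def nb_cspan0(study_data):
    return _build(study_data, "nb", cspan=0)


@pytest.fixture(scope="session")
def nb_no_stoplist(study_data):
    return _build(study_data, "nb", use_stoplist=False)


@pytest.fixture(scope="session")
def ocr_test_corpus(study_data):
    """The held-out corpus regenerated with 2% character corruption."""
    seed = workflows.REFERENCE_SEED * 4 + 4
    return gen_corpus(SynthSpec(
        n_sentences=workflows.N_TEST_SENTENCES,
        name_density=workflows.NAME_DENSITY,
        distractor_rate=0.5, seed=seed, ocr_rate=0.02))


@pytest.fixture()
def rng():
    return random.Random(20240917)
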