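"""Standard end-to-end study setups on bundled synthetic data.

These define the package's reference conditions: a 2,000-sentence training
corpus and a 500-sentence held-out corpus at name density 0.3, an
800-sentence names-free negative corpus, an initial seed set of 5,000
names, context span 1, and the bundled stop-list.  All randomness derives from a single integer
seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from binomen.config import Config, load_default_stoplist
from binomen.evaluate import EvalResult, match_names
from binomen.recognize import find_names
from binomen.synthetic import SynthSpec, gen_corpus, gen_name
from binomen.textio import Document, GoldAnnotation
from binomen.trainset import train_pipeline

REFERENCE_SEED = 42

N_TRAIN_SENTENCES = 2000
N_TEST_SENTENCES = 500
N_NEGATIVE_SENTENCES = 800
N_SEED_NAMES = 5000
NAME_DENSITY = 0.3


@dataclass
class StudyData:
    seed_names: list[str]
    negative_doc: Document
    bootstrap_doc: Document
    bootstrap_gold: GoldAnnotation
    test_doc: Document
    test_gold: GoldAnnotation


def make_seed_names(seed: int, n: int = N_SEED_NAMES) -> list[str]:
    """A deterministic list of verified-name stand-ins (mostly binomials)."""
    rng = random.Random(seed)
    names = []
    for _ in range(n):
        x = rng.random()
        rank = "binomial" if x < 0.6 else ("uninominal" if x < 0.85 else "trinomial")
        names.append(gen_name(rng, rank))
    return names


def reference_data(seed: int = REFERENCE_SEED, ocr_rate: float = 0.0) -> StudyData:
    """Generate the reference corpora; sub-seeds are derived from ``seed``
    so distinct corpora are independent but jointly reproducible."""
    seed_names = make_seed_names(seed * 4 + 1)
    negative_doc, _ = gen_corpus(SynthSpec(
        n_sentences=N_NEGATIVE_SENTENCES, name_density=0.0,
        distractor_rate=0.5, seed=seed * 4 + 2))
    bootstrap_doc, bootstrap_gold = gen_corpus(SynthSpec(
        n_sentences=N_TRAIN_SENTENCES, name_density=NAME_DENSITY,
        distractor_rate=0.5, seed=seed * 4 + 3))
    test_doc, test_gold = gen_corpus(SynthSpec(
        n_sentences=N_TEST_SENTENCES, name_density=NAME_DENSITY,
        distractor_rate=0.5, seed=seed * 4 + 4, ocr_rate=ocr_rate))
    return StudyData(
        seed_names=seed_names,
        negative_doc=negative_doc,
        bootstrap_doc=bootstrap_doc,
        bootstrap_gold=bootstrap_gold,
        test_doc=test_doc,
        test_gold=test_gold,
    )


def reference_config(classifier: str = "nb", cspan: int = 1,
                     use_stoplist: bool = True,
                     seed_names: list[str] | None = None) -> Config:
    stoplist = frozenset(load_default_stoplist()) if use_stoplist else frozenset()
    dictionary = frozenset(
        word.lower() for name in (seed_names or []) for word in name.split())
    return Config(cspan=cspan, stoplist=stoplist, dictionary=dictionary,
                  classifier=classifier)


def train_reference_model(classifier: str = "nb", cspan: int = 1,
                          use_stoplist: bool = True,
                          data: StudyData | None = None,
                          seed: int = REFERENCE_SEED):
    """Train a model under the reference conditions; returns
    (model, config, data)."""
    if data is None:
        data = reference_data(seed)
    config = reference_config(classifier, cspan, use_stoplist, data.seed_names)
    model = train_pipeline(
        data.seed_names, data.negative_doc, [data.bootstrap_doc], config)
    return model, config, data


def evaluate_on(model, config: Config, doc: Document, gold: GoldAnnotation,
                mode: str = "unique_name") -> EvalResult:
    mentions = find_names(doc, model, config)
    return match_names(gold, mentions, mode=mode)
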