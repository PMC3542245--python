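"""Training-set construction.

Negatives are every word unigram/bigram/trigram of a text known to contain
no scientific names (a synthetic "geography book" by default).  Positives
come from two sides: a seed list of verified names featurized without
sentence context, and high-confidence names harvested by running an
initial structural-features-only classifier over an unlabeled corpus
(bootstrapping), featurized with their sentence contexts.  Abbreviated
variants of harvested names are added as positives too.
"""

from __future__ import annotations

import logging

from binomen.candidates import RANK_OF_SIZE, Candidate, generate_candidates
from binomen.classify import LabeledExample, train
from binomen.config import Config
from binomen.features import extract_features
from binomen.textio import Document
from binomen.tokenize import Sentence, Token, split_sentences

logger = logging.getLogger(__name__)


def _window_candidate(tokens, i, size, sentence_index) -> Candidate:
    window = tokens[i:i + size]
    return Candidate(
        tokens=tuple(window),
        rank=RANK_OF_SIZE[size],
        span=(window[0].start, window[-1].end),
        sentence_index=sentence_index,
    )


def build_negatives(document: Document, config: Config) -> list[LabeledExample]:
    """All 1/2/3-token windows of every sentence, labeled "no".

    Windows are taken over the raw token sequence without any rule
    filtering; per sentence of n tokens that is n + (n-1) + (n-2) windows
    (clamped at 0).
    """
    out: list[LabeledExample] = []
    for s_idx, sentence in enumerate(split_sentences(document)):
        toks = list(sentence.tokens)
        for size in (1, 2, 3):
            for i in range(len(toks) - size + 1):
                cand = _window_candidate(toks, i, size, s_idx)
                fv = extract_features(cand, sentence, config)
                out.append(LabeledExample(features=fv, label="no"))
    return out


def _abbreviated_variant(cand: Candidate) -> Candidate | None:
    """Replace a full genus first token with its initial + '.' (annotation
    of how abbreviated mentions of the same name look)."""
    if cand.rank == "uninominal":
        return None
    first = cand.tokens[0]
    if first.surface.endswith("."):
        return None
    abbrev = Token(first.surface[0] + ".", first.start, first.end)
    return Candidate(
        tokens=(abbrev,) + cand.tokens[1:],
        rank=cand.rank,
        span=cand.span,
        sentence_index=cand.sentence_index,
    )


def bootstrap_positives(initial_model, documents: list[Document], threshold: float,
                        config: Config) -> list[LabeledExample]:
    """Harvest high-confidence positives with their sentence contexts.

    The initial model must be structural-only (cspan 0); candidates whose
    structural "yes" posterior reaches ``threshold`` become positive
    examples featurized under the full configuration (``config.cspan``),
    together with their abbreviated variants.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"bootstrap threshold must be in (0.5, 1], got {threshold}")
    structural_config = config.with_cspan(0)
    out: list[LabeledExample] = []
    for document in documents:
        for s_idx, sentence in enumerate(split_sentences(document)):
            for cand in generate_candidates(
                sentence, config.stoplist, sentence_index=s_idx,
                min_uninomial_len=config.min_uninomial_len,
            ):
                structural_fv = extract_features(cand, sentence, structural_config)
                if initial_model.posterior(structural_fv)["yes"] >= threshold:
                    out.append(LabeledExample(
                        features=extract_features(cand, sentence, config), label="yes"))
                    variant = _abbreviated_variant(cand)
                    if variant is not None:
                        out.append(LabeledExample(
                            features=extract_features(variant, sentence, config), label="yes"))
    return out


def _name_sentence(name: str) -> tuple[Sentence, Candidate]:
    """A pseudo-sentence holding just the name, so context slots pad out."""
    tokens = []
    pos = 0
    for word in name.split():
        tokens.append(Token(word, pos, pos + len(word)))
        pos += len(word) + 1
    sentence = Sentence(tokens=tuple(tokens), start=0, end=pos - 1 if tokens else 0)
    cand = Candidate(
        tokens=tuple(tokens),
        rank=RANK_OF_SIZE[len(tokens)],
        span=(0, tokens[-1].end),
        sentence_index=0,
    )
    return sentence, cand


def seed_examples(seed_names: list[str], config: Config) -> list[LabeledExample]:
    """Featurize verified names without sentence context (context slots are
    all padding under the configured cspan)."""
    out = []
    for name in seed_names:
        n_tokens = len(name.split())
        if n_tokens not in RANK_OF_SIZE:
            raise ValueError(f"seed name {name!r} must have 1-3 tokens")
        sentence, cand = _name_sentence(name)
        out.append(LabeledExample(features=extract_features(cand, sentence, config), label="yes"))
    return out


def assemble_training_set(seed_names: list[str], context_positives: list[LabeledExample],
                          negatives: list[LabeledExample], config: Config) -> list[LabeledExample]:
    """Seed positives + bootstrapped context positives + negatives, in a
    deterministic canonical order.  Duplicates are retained: frequency
    matters to both estimators."""
    positives = seed_examples(seed_names, config) + list(context_positives)
    if not positives or not negatives:
        raise ValueError("training set needs at least one positive and one negative example")
    examples = positives + list(negatives)
    examples.sort(key=lambda e: (e.label, sorted(e.features.items())))
    n_yes = len(positives)
    logger.info("assembled training set: %d yes (%.1f%%), %d no (%.1f%%)",
                n_yes, 100 * n_yes / len(examples),
                len(negatives), 100 * len(negatives) / len(examples))
    return examples


def train_pipeline(seed_names: list[str], negative_doc: Document,
                   bootstrap_docs: list[Document], config: Config,
                   initial_classifier: str = "nb",
                   balance_context_positives: bool = True):
    """The full training recipe.

    1. train an initial classifier on structural features only (seed
       positives vs. negative-corpus windows);
    2. bootstrap high-confidence positives with contexts from the
       unlabeled corpus;
    3. train the final classifier (``config.classifier``) on seed +
       bootstrapped positives + negatives under the full configuration.

    With ``balance_context_positives`` the bootstrapped examples are
    replicated so contextual and no-context positives enter the final set
    in roughly equal numbers (duplicated frequency is meaningful to both
    estimators); without it small bootstrap harvests leave the context
    tables dominated by padding.
    """
    structural_config = config.with_cspan(0).replace(classifier=initial_classifier)
    negatives_structural = build_negatives(negative_doc, structural_config)
    initial_set = assemble_training_set(seed_names, [], negatives_structural, structural_config)
    initial_model = train(initial_set, structural_config)

    context_positives = bootstrap_positives(
        initial_model, bootstrap_docs, config.bootstrap_threshold, config)
    logger.info("bootstrap harvested %d context positives", len(context_positives))
    if balance_context_positives and context_positives:
        reps = max(1, round(len(seed_names) / len(context_positives)))
        context_positives = context_positives * reps

    negatives = build_negatives(negative_doc, config)
    final_set = assemble_training_set(seed_names, context_positives, negatives, config)
    return train(final_set, config)
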