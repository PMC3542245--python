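"""End-to-end recognition: text -> sentences -> candidates -> features ->
classifier -> abbreviation resolution -> name mentions with offsets and
posterior scores."""

from __future__ import annotations

from dataclasses import dataclass, replace

from binomen.candidates import ROLE_ABBREV_GENUS, ROLE_GENUS, generate_candidates, token_matches_role
from binomen.classify import label_of
from binomen.config import Config
from binomen.features import extract_features
from binomen.textio import Document
from binomen.tokenize import split_sentences


class ConfigMismatchError(ValueError):
    """The model was trained under a different feature configuration."""


@dataclass(frozen=True)
class NameMention:
    surface: str
    start: int
    end: int
    rank: str
    score: float
    expansion: str = ""
    doc_id: str = "doc"


def find_names(document: Document, model, config: Config) -> list[NameMention]:
    """Recognize scientific names in a document.

    Every candidate whose argmax label is "yes" becomes a mention carrying
    the "yes" posterior as its score; abbreviated genus mentions are then
    resolved against earlier mentions.  Deterministic given document,
    model and configuration.
    """
    fp = config.feature_fingerprint()
    if model.fingerprint and model.fingerprint != fp:
        raise ConfigMismatchError(
            f"model feature configuration {model.fingerprint} does not match "
            f"run configuration {fp}"
        )
    mentions: list[NameMention] = []
    for s_idx, sentence in enumerate(split_sentences(document)):
        for cand in generate_candidates(
            sentence, config.stoplist, sentence_index=s_idx,
            min_uninomial_len=config.min_uninomial_len,
        ):
            fv = extract_features(cand, sentence, config)
            if label_of(model, fv) == "yes":
                start, end = cand.span
                mentions.append(
                    NameMention(
                        surface=document.text[start:end],
                        start=start,
                        end=end,
                        rank=cand.rank,
                        score=model.posterior(fv)["yes"],
                        doc_id=document.id,
                    )
                )
    return resolve_abbreviations(mentions, document)


def _abbrev_letters(token: str) -> str | None:
    return token[:-1] if token_matches_role(token, ROLE_ABBREV_GENUS) else None


def resolve_abbreviations(mentions: list[NameMention], document: Document) -> list[NameMention]:
    """Fill the ``expansion`` slot of abbreviated-genus mentions.

    An abbreviation matches the most recent previously seen genus whose
    name starts with its letter(s); the genus history is fed by full
    binomial/trinomial mentions, uninominal genus mentions, and by
    expansions themselves (so "G. second-species" chains after an earlier
    expanded mention of the same genus).  With no antecedent the mention is
    kept with an empty expansion.  Spans are never altered.
    """
    history: list[str] = []  # genus names, most recent last
    out: list[NameMention] = []
    for mention in sorted(mentions, key=lambda m: (m.start, m.end)):
        tokens = mention.surface.split()
        first = tokens[0]
        letters = _abbrev_letters(first)
        if letters is not None:
            antecedent = None
            for genus in reversed(history):
                if genus[0] == letters[0] and genus[:len(letters)].lower() == letters.lower():
                    antecedent = genus
                    break
            if antecedent is not None:
                expansion = " ".join([antecedent] + tokens[1:])
                mention = replace(mention, expansion=expansion)
                history.append(antecedent)
        elif token_matches_role(first, ROLE_GENUS):
            history.append(first)
        out.append(mention)
    return out
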