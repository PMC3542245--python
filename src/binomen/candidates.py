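"""Candidate name generation: the capitalization/abbreviation rule filter
and the trigram -> bigram -> unigram cascade.

A candidate is a run of one to three consecutive tokens inside a single
sentence whose first token looks like a genus (or an abbreviated genus) and
whose remaining tokens look like lowercase epithets.  At each scan position
the longest admissible rank wins (trinomial, then binomial, then
uninominal); a token whose lowercase form is on the stop-list disqualifies
every rank containing it.  Emitted candidates never share tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

from binomen.tokenize import Sentence, Token

RANKS = ("uninominal", "binomial", "trinomial")
RANK_OF_SIZE = {1: "uninominal", 2: "binomial", 3: "trinomial"}

ROLE_GENUS = "genus"
ROLE_ABBREV_GENUS = "abbrev_genus"
ROLE_EPITHET = "epithet"


@dataclass(frozen=True)
class Candidate:
    tokens: tuple[Token, ...]
    rank: str
    span: tuple[int, int]
    sentence_index: int

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.tokens)


def _lower_word(s: str) -> bool:
    """All-lowercase alphabetic, single hyphens allowed internally."""
    if not s:
        return False
    parts = s.split("-")
    if any(not p for p in parts):
        return False
    return all(ch.isalpha() and ch.islower() for p in parts for ch in p)


def token_matches_role(surface: str, role: str) -> bool:
    """Does a token surface satisfy the genus / abbreviated-genus / epithet
    shape rule?  All roles reject digits and empty strings."""
    if any(ch.isdigit() for ch in surface):
        return False
    if role == ROLE_GENUS:
        if len(surface) < 3:
            return False
        head, rest = surface[0], surface[1:]
        if not (head.isalpha() and head.isupper()):
            return False
        return _lower_word(rest) and sum(ch.isalpha() for ch in rest) >= 2
    if role == ROLE_ABBREV_GENUS:
        if not surface.endswith(".") or not (2 <= len(surface) <= 3):
            return False
        letters = surface[:-1]
        return all(ch.isalpha() and ch.isupper() for ch in letters)
    if role == ROLE_EPITHET:
        return _lower_word(surface) and sum(ch.isalpha() for ch in surface) >= 2
    raise ValueError(f"unknown token role {role!r}")


def _window_ok(tokens: list[Token], stoplist: frozenset[str] | set[str],
               min_uninomial_len: int) -> bool:
    if any(t.surface.lower() in stoplist for t in tokens):
        return False
    first = tokens[0].surface
    if token_matches_role(first, ROLE_ABBREV_GENUS):
        pass
    elif token_matches_role(first, ROLE_GENUS):
        if len(tokens) == 1 and len(first) < min_uninomial_len:
            return False
    else:
        return False
    return all(token_matches_role(t.surface, ROLE_EPITHET) for t in tokens[1:])


def generate_candidates(sentence: Sentence, stoplist: frozenset[str] | set[str] = frozenset(),
                        *, sentence_index: int = 0,
                        min_uninomial_len: int = 4) -> list[Candidate]:
    """Greedy left-to-right scan over one sentence.

    At position i try the three-token window, then two, then one; on
    emission advance past the emitted tokens, otherwise advance one token.
    Candidates never cross the sentence boundary and never overlap.
    """
    toks = list(sentence.tokens)
    out: list[Candidate] = []
    i = 0
    n = len(toks)
    while i < n:
        emitted = None
        for size in (3, 2, 1):
            if i + size <= n:
                window = toks[i:i + size]
                if _window_ok(window, stoplist, min_uninomial_len):
                    emitted = Candidate(
                        tokens=tuple(window),
                        rank=RANK_OF_SIZE[size],
                        span=(window[0].start, window[-1].end),
                        sentence_index=sentence_index,
                    )
                    break
        if emitted is not None:
            out.append(emitted)
            i += len(emitted.tokens)
        else:
            i += 1
    return out
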