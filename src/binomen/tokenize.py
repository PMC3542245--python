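"""Sentence segmentation and Treebank-style word tokenization with exact
character offsets.

Two deliberate deviations from strict Penn Treebank behaviour, both driven
by how abbreviated genus names appear in taxonomic prose:

* a period directly after one (or two) capital letters stays attached, so
  "S. ysbryda" tokenizes as ``["S.", "ysbryda"]`` and the sentence splitter
  never breaks after "E." in "E. coli";
* hyphenated words are kept whole, because species epithets may contain
  internal hyphens.

Letters outside ASCII count as letters (OCR'd text carries accents).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from binomen.textio import Document


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]
    start: int
    end: int


# Order matters: the abbreviation branch must win over the bare-word branch
# so "S." is one token, while "Selenochlamys" falls through to the word
# branch untouched.
_TOKEN_RE = re.compile(
    r"[A-Z]{1,2}\."  # abbreviated genus ("G.", "Ch" is lowercase -> word)
    r"|[^\W\d_]+(?:[-'’][^\W\d_]+)*"  # word, internal hyphen/apostrophe
    r"|\d+(?:[.,]\d+)*"  # number
    r"|\S"  # any other visible character
)

_TERMINAL = ".!?"


def tokenize_sentence(sentence_text: str, base_offset: int = 0) -> list[Token]:
    """Tokenize one sentence, offsets relative to the full document."""
    return [
        Token(m.group(0), base_offset + m.start(), base_offset + m.end())
        for m in _TOKEN_RE.finditer(sentence_text)
    ]


def _is_boundary(text: str, i: int) -> bool:
    """Is the terminal character at position i a sentence boundary?"""
    ch = text[i]
    # require following whitespace then an uppercase opener (or end of text)
    j = i + 1
    while j < len(text) and text[j] in _TERMINAL + "\"')]":
        j += 1
    if j >= len(text):
        return True
    if not text[j].isspace():
        return False
    k = j
    while k < len(text) and text[k].isspace():
        k += 1
    if k >= len(text):
        return True
    if not (text[k].isupper() or text[k].isdigit() or text[k] in "\"'(["):
        return False
    if ch == ".":
        # suppress after a single/double capital abbreviation: "E." / "Ch" no
        p = i - 1
        if p >= 0 and text[p].isalpha() and text[p].isupper():
            q = p - 1
            if q >= 0 and text[q].isalpha() and text[q].isupper():
                q -= 1
            if q < 0 or not text[q].isalpha():
                return False
    return True


def split_sentences(document: Document) -> list[Sentence]:
    """Segment a document into tokenized sentences with document offsets.

    Heuristic terminal-punctuation splitting; never splits after a bare
    capital-letter abbreviation, so "E. coli is a bacterium." stays one
    sentence.  Empty text yields an empty list.
    """
    text = document.text
    sentences: list[Sentence] = []
    sent_start: int | None = None
    i = 0
    while i < len(text):
        ch = text[i]
        if sent_start is None:
            if not ch.isspace():
                sent_start = i
            i += 1
            continue
        if ch in _TERMINAL and _is_boundary(text, i):
            end = i + 1
            while end < len(text) and text[end] in _TERMINAL + "\"')]":
                end += 1
            _append(sentences, text, sent_start, end)
            sent_start = None
            i = end
        else:
            i += 1
    if sent_start is not None:
        _append(sentences, text, sent_start, len(text))
    return sentences


def _append(sentences: list[Sentence], text: str, start: int, end: int) -> None:
    while end > start and text[end - 1].isspace():
        end -= 1
    if end <= start:
        return
    tokens = tuple(tokenize_sentence(text[start:end], start))
    if tokens:
        sentences.append(Sentence(tokens=tokens, start=start, end=end))
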