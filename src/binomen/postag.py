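"""A tiny deterministic part-of-speech tagger: closed-class word table,
then suffix rules, then a default noun tag.  It exists to supply stable
context tags for the feature extractor; any callable with the same
signature can be configured in its place."""

from __future__ import annotations

CLOSED_CLASS: dict[str, str] = {
    # determiners
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "every": "DT", "some": "DT",
    "any": "DT", "no": "DT", "all": "DT", "both": "DT",
    # prepositions / subordinators
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "with": "IN",
    "from": "IN", "into": "IN", "near": "IN", "for": "IN", "as": "IN",
    "during": "IN", "after": "IN", "before": "IN", "between": "IN",
    "under": "IN", "over": "IN", "through": "IN", "about": "IN",
    "among": "IN", "within": "IN", "while": "IN", "because": "IN",
    "until": "IN", "since": "IN", "to": "TO",
    # conjunctions
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "yet": "CC",
    # pronouns
    "it": "PRP", "he": "PRP", "she": "PRP", "they": "PRP", "we": "PRP",
    "i": "PRP", "you": "PRP", "its": "PRP$", "his": "PRP$", "her": "PRP$",
    "their": "PRP$", "our": "PRP$", "your": "PRP$",
    # auxiliaries and common verbs
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    "can": "MD", "could": "MD", "may": "MD", "might": "MD", "will": "MD",
    "would": "MD", "shall": "MD", "should": "MD", "must": "MD",
    # adverbs / misc
    "not": "RB", "very": "RB", "also": "RB", "only": "RB", "most": "RBS",
    "more": "RBR", "there": "EX", "here": "RB", "then": "RB", "often": "RB",
    # quantifying adjectives common in descriptive prose
    "several": "JJ", "many": "JJ", "much": "JJ", "few": "JJ", "other": "JJ",
    "new": "JJ", "same": "JJ", "such": "JJ", "own": "JJ", "last": "JJ",
    "first": "JJ", "second": "JJ", "third": "JJ",
}

_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ly", "RB"),
    ("ing", "VBG"),
    ("ed", "VBD"),
    ("tion", "NN"),
    ("sion", "NN"),
    ("ment", "NN"),
    ("ness", "NN"),
    ("ous", "JJ"),
    ("ful", "JJ"),
    ("ive", "JJ"),
    ("ical", "JJ"),
    ("able", "JJ"),
)


def tag_token(surface: str) -> str:
    low = surface.lower()
    if low in CLOSED_CLASS:
        return CLOSED_CLASS[low]
    if not any(ch.isalpha() for ch in surface):
        if any(ch.isdigit() for ch in surface):
            return "CD"
        return surface  # punctuation tags itself, Treebank style
    for suffix, tag in _SUFFIX_RULES:
        if len(low) > len(suffix) + 1 and low.endswith(suffix):
            return tag
    if surface[0].isupper():
        return "NNP"
    if low.endswith("s") and len(low) > 3 and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def pos_tag(tokens: list[str]) -> list[str]:
    """Tag a sentence's token surfaces; deterministic, context-free."""
    return [tag_token(t) for t in tokens]
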