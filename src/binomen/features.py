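"""Feature extraction: turn a candidate plus its sentence context into the
named nominal features consumed by both classifiers.

Structural features are computed per constituent token slot (three slots;
slots beyond the candidate's rank carry the ``<NONE>`` sentinel so every
vector has the same keys):

* last-3 / last-2 / last-1 character substrings, first and second character;
* membership of the last, second-last and third-last character in each
  configured partition of ``{a,e,i,o,u,s,m}``;
* vowel count, capped into a ``"5+"`` category;
* membership of the lowercased token in the name-dictionary word set;

plus one ``rank`` feature.  Contextual features are the lowercased word and
POS tag at 1..cspan positions left and right of the candidate within its
sentence, with ``<PAD>`` past the sentence edge.  All values are strings so
both the Naive Bayes tables and the MaxEnt indicator functions treat them
uniformly as nominal.
"""

from __future__ import annotations

from binomen.candidates import Candidate
from binomen.config import Config
from binomen.postag import pos_tag
from binomen.tokenize import Sentence

SENTINEL = "<NONE>"
PAD = "<PAD>"

FeatureVector = dict[str, str]

_VOWELS = frozenset("aeiou")


def _token_slot(prefix: str, surface: str | None, config: Config,
                dictionary: frozenset[str]) -> FeatureVector:
    fv: FeatureVector = {}
    if surface is None:
        fv[f"{prefix}_last3"] = SENTINEL
        fv[f"{prefix}_last2"] = SENTINEL
        fv[f"{prefix}_last1"] = SENTINEL
        fv[f"{prefix}_first"] = SENTINEL
        fv[f"{prefix}_second"] = SENTINEL
        for pos_name in ("last", "last2nd", "last3rd"):
            for part in config.partitions:
                fv[f"{prefix}_{pos_name}_in_{part}"] = SENTINEL
        fv[f"{prefix}_vowels"] = SENTINEL
        fv[f"{prefix}_in_dict"] = SENTINEL
        return fv
    fv[f"{prefix}_last3"] = surface[-3:]
    fv[f"{prefix}_last2"] = surface[-2:]
    fv[f"{prefix}_last1"] = surface[-1:]
    fv[f"{prefix}_first"] = surface[0]
    fv[f"{prefix}_second"] = surface[1] if len(surface) > 1 else SENTINEL
    low = surface.lower()
    for pos_name, idx in (("last", -1), ("last2nd", -2), ("last3rd", -3)):
        ch = low[idx] if len(low) >= -idx else None
        for part, chars in config.partitions.items():
            key = f"{prefix}_{pos_name}_in_{part}"
            fv[key] = SENTINEL if ch is None else str(ch in chars)
    nv = sum(ch in _VOWELS for ch in low)
    fv[f"{prefix}_vowels"] = str(nv) if nv < config.vowel_cap else f"{config.vowel_cap}+"
    fv[f"{prefix}_in_dict"] = str(low.rstrip(".") in dictionary)
    return fv


def structural_features(candidate: Candidate, config: Config) -> FeatureVector:
    """Character-shape, vowel-count and dictionary features of the candidate
    string itself (no context)."""
    surfaces = candidate.surfaces
    fv: FeatureVector = {"rank": candidate.rank}
    for t in range(3):
        surface = surfaces[t] if t < len(surfaces) else None
        fv.update(_token_slot(f"t{t}", surface, config, config.dictionary))
    return fv


def contextual_features(candidate: Candidate, sentence: Sentence, cspan: int) -> FeatureVector:
    """Neighbor words and POS tags at 1..cspan positions on each side of the
    candidate; ``<PAD>`` beyond the sentence edge.  cspan=0 -> empty."""
    if cspan < 0:
        raise ValueError(f"cspan must be >= 0, got {cspan}")
    fv: FeatureVector = {}
    if cspan == 0:
        return fv
    spans = [(t.start, t.end) for t in sentence.tokens]
    try:
        first = spans.index((candidate.tokens[0].start, candidate.tokens[0].end))
        last = spans.index((candidate.tokens[-1].start, candidate.tokens[-1].end))
    except ValueError:
        raise ValueError("candidate tokens not found in sentence") from None
    surfaces = [t.surface for t in sentence.tokens]
    tags = pos_tag(surfaces)
    for i in range(1, cspan + 1):
        li, ri = first - i, last + i
        fv[f"ctx_l{i}_w"] = surfaces[li].lower() if li >= 0 else PAD
        fv[f"ctx_l{i}_p"] = tags[li] if li >= 0 else PAD
        fv[f"ctx_r{i}_w"] = surfaces[ri].lower() if ri < len(surfaces) else PAD
        fv[f"ctx_r{i}_p"] = tags[ri] if ri < len(tags) else PAD
    return fv


def extract_features(candidate: Candidate, sentence: Sentence, config: Config) -> FeatureVector:
    """Full feature vector: structural plus contextual at the configured
    cspan.  Pure function of its inputs."""
    fv = structural_features(candidate, config)
    fv.update(contextual_features(candidate, sentence, config.cspan))
    return fv


# re-exported for configurability checks and tests
__all__ = [
    "FeatureVector",
    "SENTINEL",
    "PAD",
    "structural_features",
    "contextual_features",
    "extract_features",
    "pos_tag",
]
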