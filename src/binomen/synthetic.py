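"""Seedable generator of synthetic annotated corpora.

The generator emulates the kind of prose the recognizer targets: English
sentences with embedded Latin binomial/trinomial names, uninominal genus
mentions, abbreviated genus mentions with earlier antecedents, capitalized
English distractors (places, surnames — several with deliberately
Latin-looking endings), and optional character-level OCR corruption from a
small confusion table.  Everything is driven by one ``random.Random`` seed:
the same spec yields a byte-identical corpus and gold standard.

What it does **not** emulate: real OCR segmentation damage, page layout,
authorship strings ("(Linnaeus, 1758)"), non-English prose, or the long-tail
vocabulary of real books.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from binomen.config import load_distractor_words
from binomen.textio import Document, GoldAnnotation

GENUS_ENDINGS = ("us", "a", "um", "is", "es", "ix")
EPITHET_ENDINGS = ("us", "a", "um", "ii", "ensis", "alis")

_ONSETS = (
    "b", "c", "d", "f", "g", "h", "l", "m", "n", "p", "r", "s", "t", "v", "z",
    "ch", "th", "ph", "br", "cr", "dr", "tr", "pl", "st",
)
_VOWELS = ("a", "e", "i", "o", "u")

#: default OCR confusion table: single-character substitutions plus the two
#: classic merges rn->m and fi->h
OCR_SINGLE = {"e": "c", "c": "e", "l": "i", "i": "l", "u": "n", "n": "u", "o": "e"}
OCR_PAIRS = {"rn": "m", "fi": "h"}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic corpus.

    name_density: fraction of sentences containing a planted name.
    distractor_rate: fraction of the name-free sentences that contain a
    capitalized English distractor (place or surname).
    ocr_rate: per-character corruption probability applied after planting.
    """

    n_sentences: int = 500
    name_density: float = 0.3
    ocr_rate: float = 0.0
    seed: int = 42
    distractor_rate: float = 0.5

    def __post_init__(self):
        for attr in ("name_density", "ocr_rate", "distractor_rate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be >= 0")


_CODAS = ("n", "r", "t", "l", "s", "m", "c", "d", "g", "nt", "st", "ct", "rm")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS)


def _genus(rng: random.Random) -> str:
    stem = "".join(_syllable(rng) for _ in range(rng.randint(2, 3)))
    if rng.random() < 0.25:  # drop the first onset: vowel-initial genus
        while stem and not stem[0] in _VOWELS:
            stem = stem[1:]
    if rng.random() < 0.65:
        stem += rng.choice(_CODAS)
    return (stem + rng.choice(GENUS_ENDINGS)).capitalize()


def _epithet(rng: random.Random) -> str:
    stem = "".join(_syllable(rng) for _ in range(rng.randint(1, 3)))
    if rng.random() < 0.65:
        stem += rng.choice(_CODAS)
    return stem + rng.choice(EPITHET_ENDINGS)


def gen_name(rng: random.Random, rank: str) -> str:
    """One random Latin-shaped name of the given rank; every token passes
    the candidate role rules by construction."""
    if rank == "uninominal":
        return _genus(rng)
    if rank == "binomial":
        return f"{_genus(rng)} {_epithet(rng)}"
    if rank == "trinomial":
        return f"{_genus(rng)} {_epithet(rng)} {_epithet(rng)}"
    raise ValueError(f"unknown rank {rank!r}")


# name-bearing sentence templates; {name} is the planted name
_NAME_TEMPLATES = (
    "{name} was collected near {place}.",
    "Specimens of {name} were examined in detail.",
    "The species {name} differs from its congeners.",
    "{name} occurs in {place} and adjacent regions.",
    "Field surveys recorded {name} at several sites.",
)
# templates only sensible for a bare genus
_UNINOMIAL_TEMPLATES = (
    "{name} is a genus of pelagic marine gastropods.",
    "The genus {name} comprises several species.",
    "{name} is a genus of small ground beetles.",
)
# name-free sentences with a capitalized distractor
_DISTRACTOR_TEMPLATES = (
    "The city {place} is in the state of {place2}.",
    "Professor {surname} visited {place} last summer.",
    "The town of {place} lies to the north.",
    "Records from {place} were archived by {surname}.",
    "Many travellers admired {place} during the expedition.",
)
# plain name-free filler
_PLAIN_SENTENCES = (
    "The specimens were stored in ethanol and examined later.",
    "The results of the survey were published in a short report.",
    "Several samples were measured and the values were recorded.",
    "The weather during the expedition was often cold and wet.",
    "A detailed map of the region was prepared by the team.",
    "The collection was deposited in the national museum.",
    "Most of the material was obtained during the last field season.",
    "The report describes the methods used during the survey.",
)

_RANK_WEIGHTS = (("binomial", 0.60), ("uninominal", 0.25), ("trinomial", 0.15))
_ABBREV_PROB = 0.15  # chance a name sentence reuses an earlier binomial abbreviated


def _pick_rank(rng: random.Random) -> str:
    x = rng.random()
    acc = 0.0
    for rank, w in _RANK_WEIGHTS:
        acc += w
        if x < acc:
            return rank
    return _RANK_WEIGHTS[-1][0]


def gen_corpus(spec: SynthSpec) -> tuple[Document, GoldAnnotation]:
    """Generate one corpus and its gold standard.

    Gold lists every planted name surface with its exact character span.
    If ``spec.ocr_rate > 0`` the corrupted text and remapped gold are
    returned.
    """
    rng = random.Random(spec.seed)
    places = load_distractor_words("places")
    surnames = load_distractor_words("surnames")
    parts: list[str] = []
    offset = 0
    names: set[str] = set()
    mentions: list[tuple[int, int]] = []
    planted_binomials: list[tuple[str, str]] = []  # (genus, rest-of-name)

    for _ in range(spec.n_sentences):
        if rng.random() < spec.name_density:
            if planted_binomials and rng.random() < _ABBREV_PROB:
                genus, rest = rng.choice(planted_binomials)
                name = f"{genus[0]}. {rest}"
                template = rng.choice(_NAME_TEMPLATES)
            else:
                rank = _pick_rank(rng)
                name = gen_name(rng, rank)
                if rank == "uninominal":
                    template = rng.choice(_UNINOMIAL_TEMPLATES + _NAME_TEMPLATES[-1:])
                else:
                    template = rng.choice(_NAME_TEMPLATES)
                    head, _, tail = name.partition(" ")
                    if tail:
                        planted_binomials.append((head, tail))
            sentence = template.format(name=name, place=rng.choice(places))
            start = offset + sentence.index(name)
            names.add(name)
            mentions.append((start, start + len(name)))
        elif rng.random() < spec.distractor_rate:
            template = rng.choice(_DISTRACTOR_TEMPLATES)
            sentence = template.format(
                place=rng.choice(places), place2=rng.choice(places),
                surname=rng.choice(surnames),
            )
        else:
            sentence = rng.choice(_PLAIN_SENTENCES)
        parts.append(sentence)
        offset += len(sentence) + 1  # single-space join

    text = " ".join(parts)
    doc = Document(text=text, id=f"synthetic-{spec.seed}")
    gold = GoldAnnotation(names=frozenset(names), mentions=tuple(mentions))
    if spec.ocr_rate > 0:
        doc, gold = inject_ocr_noise(doc, gold, spec.ocr_rate, rng)
    return doc, gold


def inject_ocr_noise(document: Document, gold: GoldAnnotation, ocr_rate: float,
                     rng: random.Random) -> tuple[Document, GoldAnnotation]:
    """Apply per-character confusion-table corruption with probability
    ``ocr_rate`` and remap gold spans onto the corrupted text.

    Gold names whose surface changed are flagged in ``corrupted``.
    """
    if not 0.0 <= ocr_rate <= 1.0:
        raise ValueError(f"ocr_rate must be in [0, 1], got {ocr_rate}")
    text = document.text
    if ocr_rate == 0.0:
        return document, gold
    out: list[str] = []
    newpos = [0] * (len(text) + 1)
    i = 0
    cur = 0
    while i < len(text):
        newpos[i] = cur
        pair = text[i:i + 2]
        if pair in OCR_PAIRS and rng.random() < ocr_rate:
            repl = OCR_PAIRS[pair]
            out.append(repl)
            newpos[i + 1] = cur  # both source chars collapse onto the merge
            i += 2
            cur += len(repl)
            continue
        ch = text[i]
        if ch in OCR_SINGLE and rng.random() < ocr_rate:
            out.append(OCR_SINGLE[ch])
        else:
            out.append(ch)
        i += 1
        cur += 1
    newpos[len(text)] = cur
    new_text = "".join(out)

    new_mentions: list[tuple[int, int]] = []
    new_names: set[str] = set()
    corrupted: set[str] = set()
    originals = {(s, e): text[s:e] for (s, e) in (gold.mentions or ())}
    for (s, e) in gold.mentions or ():
        ns, ne = newpos[s], newpos[e]
        surface = new_text[ns:ne]
        new_mentions.append((ns, ne))
        new_names.add(surface)
        if surface != originals[(s, e)]:
            corrupted.add(surface)
    new_gold = GoldAnnotation(
        names=frozenset(new_names),
        mentions=tuple(new_mentions),
        corrupted=frozenset(corrupted),
    )
    return Document(text=new_text, id=document.id), new_gold
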