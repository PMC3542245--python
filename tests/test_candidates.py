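import random

import pytest
from hypothesis import given, settings, strategies as st

from binomen.candidates import (
    ROLE_ABBREV_GENUS,
    ROLE_EPITHET,
    ROLE_GENUS,
    generate_candidates,
    token_matches_role,
)
from binomen.synthetic import SynthSpec, gen_corpus
from binomen.tokenize import Sentence, tokenize_sentence


def _sentence(text):
    toks = tokenize_sentence(text)
    return Sentence(tokens=tuple(toks), start=0, end=len(text))


class TestRoleRules:
    @pytest.mark.parametrize(
        "surface,role,expected",
        [
            ("Gymnotus", ROLE_GENUS, True),
            ("THE", ROLE_GENUS, False),
            ("S.", ROLE_ABBREV_GENUS, True),
            ("Ch.", ROLE_ABBREV_GENUS, False),  # second letter must be uppercase
            ("ST.", ROLE_ABBREV_GENUS, True),
            ("S", ROLE_ABBREV_GENUS, False),
            ("omarorum", ROLE_EPITHET, True),
            ("novae-zelandiae", ROLE_EPITHET, True),
            ("Omarorum", ROLE_EPITHET, False),
            ("x", ROLE_EPITHET, False),
            ("B2", ROLE_GENUS, False),
            ("carap0", ROLE_EPITHET, False),
            ("Ab", ROLE_GENUS, False),  # needs two following lowercase letters
            ("Neo-avian", ROLE_GENUS, True),  # internal hyphen is allowed
            ("Aglaja", ROLE_GENUS, True),
        ],
    )
    def test_examples(self, surface, role, expected):
        assert token_matches_role(surface, role) is expected

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            token_matches_role("Gymnotus", "subgenus")


class TestCascade:
    def test_binomial_emitted(self):
        cands = generate_candidates(
            _sentence("Gymnotus omarorum was described ."),
            stoplist={"was", "described"})
        assert len(cands) == 1
        assert cands[0].rank == "binomial"
        assert cands[0].surfaces == ("Gymnotus", "omarorum")

    def test_no_capitalized_token_no_candidates(self):
        assert generate_candidates(_sentence("the quick brown fox")) == []

    def test_stoplist_blocks_trinomial_falls_back_to_binomial(self):
        sent = _sentence("Oxyuranus temporalis venom")
        [cand] = generate_candidates(sent, stoplist={"venom"})
        assert cand.rank == "binomial"
        assert cand.surfaces == ("Oxyuranus", "temporalis")
        # without the stoplist the same window is a trinomial
        [cand] = generate_candidates(sent)
        assert cand.rank == "trinomial"

    def test_stoplist_blocks_capitalized_genus(self):
        sent = _sentence("The city was large")
        assert generate_candidates(sent, stoplist={"the", "city", "was", "large"}) == []

    def test_abbreviated_genus_candidate(self):
        [cand] = generate_candidates(_sentence("S. ysbryda was found ."),
                                     stoplist={"was", "found"})
        assert cand.rank == "binomial"
        assert cand.surfaces == ("S.", "ysbryda")

    def test_short_uninomial_needs_min_length(self):
        stop = {"flows", "grows"}
        assert generate_candidates(_sentence("Rio flows"), stoplist=stop) == []
        [cand] = generate_candidates(_sentence("Ruta grows"), stoplist=stop,
                                     min_uninomial_len=4)
        assert cand.surfaces == ("Ruta",)


def _brute_force(sentence, stoplist, min_uninomial_len=4):
    """Independent oracle: greedy scan re-derived from the role rules by
    explicit window enumeration at each position."""
    from binomen.candidates import RANK_OF_SIZE

    def window_ok(window):
        if any(t.surface.lower() in stoplist for t in window):
            return False
        first = window[0].surface
        first_ok = token_matches_role(first, ROLE_ABBREV_GENUS) or (
            token_matches_role(first, ROLE_GENUS)
            and not (len(window) == 1 and len(first) < min_uninomial_len)
        )
        return first_ok and all(
            token_matches_role(t.surface, ROLE_EPITHET) for t in window[1:]
        )

    toks = list(sentence.tokens)
    out, i = [], 0
    while i < len(toks):
        for size in (3, 2, 1):
            if i + size <= len(toks) and window_ok(toks[i:i + size]):
                out.append((tuple(t.surface for t in toks[i:i + size]), RANK_OF_SIZE[size]))
                i += size
                break
        else:
            i += 1
    return out


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_matches_brute_force_on_random_synthetic_sentences(seed):
    from binomen.tokenize import split_sentences

    doc, _ = gen_corpus(SynthSpec(n_sentences=25, name_density=0.5, seed=seed))
    stoplist = {"the", "of", "was", "in", "is", "a", "city", "state", "near"}
    for sent in split_sentences(doc):
        got = [(c.surfaces, c.rank) for c in generate_candidates(sent, stoplist)]
        assert got == _brute_force(sent, stoplist)
        # every emitted token passes its positional role rule
        for c in generate_candidates(sent, stoplist):
            first = c.surfaces[0]
            assert token_matches_role(first, ROLE_GENUS) or token_matches_role(
                first, ROLE_ABBREV_GENUS)
            assert all(token_matches_role(s, ROLE_EPITHET) for s in c.surfaces[1:])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_no_overlap_and_stoplist_monotonicity(seed):
    from binomen.tokenize import split_sentences

    doc, _ = gen_corpus(SynthSpec(n_sentences=25, name_density=0.5, seed=seed))
    stoplist = {"the", "of", "was", "city"}
    for sent in split_sentences(doc):
        with_stop = generate_candidates(sent, stoplist)
        spans = [c.span for c in with_stop]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        # removing the stop-list can only grow the token coverage
        without = generate_candidates(sent, frozenset())
        covered_with = {t for c in with_stop for t in c.surfaces}
        covered_without = {t for c in without for t in c.surfaces}
        assert covered_with <= covered_without or len(without) >= len(with_stop)
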