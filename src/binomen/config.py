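"""Run-time configuration shared by the feature extractor, the candidate
rules and the training pipeline.

A model remembers the feature configuration it was trained under (the
"fingerprint"); recognition refuses to run a model against a configuration
that would produce differently shaped feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

#: Default partitions of the character set {a,e,i,o,u,s,m} used for the
#: "is the last / second-last / third-last character in this partition"
#: boolean features.  Latin name endings are dominated by vowels, -s and -m,
#: hence the three groups.
DEFAULT_PARTITIONS: dict[str, str] = {"vowel": "aeiou", "s": "s", "m": "m"}


def load_default_stoplist() -> frozenset[str]:
    """Bundled stop-list of common English words (lowercased)."""
    text = resources.files("binomen.data").joinpath("stoplist.txt").read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_distractor_words(kind: str) -> tuple[str, ...]:
    """Bundled distractor vocabulary for the synthetic generator.

    kind is ``"places"`` or ``"surnames"``.
    """
    text = resources.files("binomen.data").joinpath(f"{kind}.txt").read_text("utf-8")
    return tuple(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class Config:
    """All tunable feature, rule and training parameters.

    cspan
        number of context positions on each side of a candidate from which
        word/POS features are drawn; 0 = structural features only.
    partitions
        named character groups tested against the last three characters of
        every candidate token.
    vowel_cap
        vowel counts above the cap collapse into a single ``"<cap>+"``
        category so counts stay nominal.
    min_uninomial_len
        minimum surface length for a non-abbreviated one-word candidate.
    stoplist / dictionary
        lowercased common-word stop-list; lowercased word set of a known
        genus/species name dictionary (used only as a feature, never as a
        filter).
    """

    cspan: int = 1
    partitions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PARTITIONS))
    vowel_cap: int = 5
    min_uninomial_len: int = 4
    stoplist: frozenset[str] = frozenset()
    dictionary: frozenset[str] = frozenset()
    # training
    alpha: float = 1.0
    classifier: str = "nb"  # "nb" | "maxent"
    maxent_method: str = "gis"
    max_iter: int = 100
    tol: float = 1e-6
    bootstrap_threshold: float = 0.99

    def feature_fingerprint(self) -> dict:
        """The part of the configuration that fixes feature-vector shape."""
        return {
            "cspan": self.cspan,
            "partitions": {k: "".join(sorted(v)) for k, v in sorted(self.partitions.items())},
            "vowel_cap": self.vowel_cap,
        }

    def with_cspan(self, cspan: int) -> "Config":
        return replace(self, cspan=cspan)

    def replace(self, **kw) -> "Config":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        """Load a configuration from a YAML key/value file.

        Unknown keys raise; ``stoplist`` and ``dictionary`` entries are
        lowercased and frozen.
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path!r} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stoplist", "dictionary"):
            if key in raw:
                raw[key] = frozenset(str(w).lower() for w in raw[key])
        return cls(**raw)
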