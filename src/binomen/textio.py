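"""Reading and writing of the external representations: documents,
wordlists, gold annotations (standoff TSV), mention output and serialized
models.

Conventions: character offsets are 0-based half-open ``[start, end)`` into
``Document.text``; wordlists are one entry per line with ``#`` comments;
gold and mention files are TSV with a header row.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Document:
    """An immutable UTF-8 text with an opaque identifier."""

    text: str
    id: str = "doc"


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold standard for one document: the set of unique name surfaces and,
    optionally, exact mention spans.  ``corrupted`` flags names whose
    surface was altered by simulated OCR noise."""

    names: frozenset[str]
    mentions: tuple[tuple[int, int], ...] | None = None
    corrupted: frozenset[str] = field(default_factory=frozenset)


def read_document(path, doc_id: str | None = None) -> Document:
    p = Path(path)
    return Document(text=p.read_text("utf-8"), id=doc_id or p.stem)


def read_wordlist(path) -> set[str]:
    """One entry per line; ``#`` lines are comments; entries lowercased,
    trimmed and deduplicated."""
    try:
        raw = Path(path).read_text("utf-8")
    except OSError as exc:
        raise IOError(f"cannot read wordlist {path!r}: {exc}") from exc
    out: set[str] = set()
    for line in raw.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return out


def read_gold(path) -> GoldAnnotation:
    """Read a gold TSV (header ``surface[<TAB>start<TAB>end]``).

    Mention spans are populated only when both offsets are present on every
    data row; a row with ``end <= start`` or a ragged row is rejected with
    its line number.
    """
    names: set[str] = set()
    spans: list[tuple[int, int]] = []
    have_spans = True
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"gold file {path!r} is empty (expected a header row)")
        ncol = len(header)
        if ncol not in (1, 3):
            raise ValueError(f"gold file {path!r}: header must have 1 or 3 columns, got {ncol}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise ValueError(f"gold file {path!r}, line {lineno}: expected {ncol} columns, got {len(row)}")
            names.add(row[0])
            if ncol == 3:
                try:
                    start, end = int(row[1]), int(row[2])
                except ValueError:
                    raise ValueError(f"gold file {path!r}, line {lineno}: non-integer span")
                if end <= start or start < 0:
                    raise ValueError(f"gold file {path!r}, line {lineno}: invalid span ({start}, {end})")
                spans.append((start, end))
            else:
                have_spans = False
    mentions = tuple(spans) if (have_spans and ncol == 3) else None
    return GoldAnnotation(names=frozenset(names), mentions=mentions)


def write_gold(gold: GoldAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if gold.mentions is None:
            writer.writerow(["surface"])
            for name in sorted(gold.names):
                writer.writerow([name])
        else:
            raise ValueError("write_gold with spans requires per-mention surfaces; use write_mentions")


_MENTION_HEADER = ["doc_id", "start", "end", "surface", "rank", "score", "expansion"]


def write_mentions(mentions: Sequence, sink, document: Document | None = None) -> None:
    """Write mentions as TSV.  If ``document`` is given, every span is
    checked to slice the text to its surface before anything is written."""
    if document is not None:
        for m in mentions:
            if document.text[m.start:m.end] != m.surface:
                raise ValueError(
                    f"mention span ({m.start}, {m.end}) does not slice document "
                    f"{document.id!r} to {m.surface!r}; nothing written"
                )
    rows = [
        [m.doc_id, str(m.start), str(m.end), m.surface, m.rank, repr(m.score), m.expansion]
        for m in mentions
    ]
    close = False
    if isinstance(sink, (str, Path)):
        fh = open(sink, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh = sink
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MENTION_HEADER)
        writer.writerows(rows)
    finally:
        if close:
            fh.close()


def read_mentions(path) -> list:
    from binomen.recognize import NameMention

    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _MENTION_HEADER:
            raise ValueError(f"mention file {path!r}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_MENTION_HEADER):
                raise ValueError(f"mention file {path!r}, line {lineno}: ragged row")
            doc_id, start, end, surface, rank, score, expansion = row
            out.append(
                NameMention(
                    surface=surface,
                    start=int(start),
                    end=int(end),
                    rank=rank,
                    score=float(score),
                    expansion=expansion,
                    doc_id=doc_id,
                )
            )
    return out


def save_model(model, path) -> None:
    """Serialize a trained model to a versioned, self-describing JSON file."""
    payload = model.to_dict()
    payload["format_version"] = MODEL_FORMAT_VERSION
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False)


def load_model(path):
    from binomen.classify import MaxEntModel, NBModel

    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot load model {path!r}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise IOError(
            f"model {path!r}: format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    kind = payload.get("kind")
    if kind == "nb":
        return NBModel.from_dict(payload)
    if kind == "maxent":
        return MaxEntModel.from_dict(payload)
    raise IOError(f"model {path!r}: unknown model kind {kind!r}")
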