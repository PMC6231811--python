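"""Data model for events/narratives, tokenization, sentence segmentation,
and readers/writers for pipeline artifacts.

Each domestic-violence event owns one or more free-text narratives.  All
downstream processing works on character offsets into the original
narrative text (0-based, half-open), so every annotation can be traced
back to the exact source span.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from dvmh.errors import DuplicateKeyError, SchemaError

__all__ = [
    "Narrative", "Token", "Sentence",
    "tokenize", "segment_sentences",
    "read_narratives", "write_records", "read_records",
]


@dataclass(frozen=True)
class Narrative:
    """One free-text narrative belonging to a DV event."""

    event_id: str
    narrative_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("narrative text must be non-empty after stripping")


@dataclass(frozen=True)
class Token:
    """A token with character offsets into the source text.

    ``folded`` is the lowercase surface used for case-insensitive
    dictionary and rule matching (police prose mixes upper/lower case
    freely, e.g. "POI", "poi", "Poi").
    """

    surface: str
    start: int
    end: int
    folded: str


@dataclass(frozen=True)
class Sentence:
    """Half-open token-index span; the scope within which rules match."""

    begin: int
    end: int


# Alphanumeric runs keep internal hyphens/apostrophes ("self-harm",
# "POI's") as one token so multiword dictionary terms match literally;
# any other non-space character is a single-character token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

_SENTENCE_FINAL = {".", "!", "?"}


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into offset-anchored tokens.

    Deterministic and pure; whitespace is never tokenized, so the tokens
    partition the non-whitespace content of ``text``.  Empty or
    whitespace-only input yields an empty list.
    """
    text = unicodedata.normalize("NFC", text)
    return [
        Token(m.group(), m.start(), m.end(), m.group().lower())
        for m in _TOKEN_RE.finditer(text)
    ]


def segment_sentences(tokens: Sequence[Token], text: str | None = None) -> list[Sentence]:
    """Partition ``tokens`` into sentences.

    Splits after sentence-final punctuation (. ! ?) and wherever the gap
    between consecutive tokens contains a newline.  ``text`` is needed
    only for the newline criterion; without it, only punctuation splits
    apply.
    """
    if not tokens:
        return []
    sentences: list[Sentence] = []
    begin = 0
    for i, tok in enumerate(tokens):
        split = tok.surface in _SENTENCE_FINAL
        if not split and i + 1 < len(tokens) and text is not None:
            if "\n" in text[tok.end:tokens[i + 1].start]:
                split = True
        if split:
            sentences.append(Sentence(begin, i + 1))
            begin = i + 1
    if begin < len(tokens):
        sentences.append(Sentence(begin, len(tokens)))
    return sentences


_REQUIRED_COLUMNS = ("event_id", "narrative_id", "text")


def _build_corpus(rows: Iterable[dict]) -> list[Narrative]:
    corpus: list[Narrative] = []
    seen: set[tuple[str, str]] = set()
    for row in rows:
        for col in _REQUIRED_COLUMNS:
            if col not in row or row[col] is None:
                raise SchemaError(f"missing required column: {col!r}")
        key = (str(row["event_id"]), str(row["narrative_id"]))
        if key in seen:
            raise DuplicateKeyError(f"duplicate (event_id, narrative_id): {key}")
        seen.add(key)
        corpus.append(Narrative(key[0], key[1], str(row["text"])))
    return corpus


def read_narratives(path: str | Path, format: str = "jsonl") -> list[Narrative]:
    """Read a corpus of narratives.

    ``format`` is one of ``jsonl`` (one JSON object per line with keys
    event_id / narrative_id / text), ``csv`` or ``tsv`` (header row with
    the same columns).  Raises :class:`SchemaError` on a missing column
    and :class:`DuplicateKeyError` on a repeated key.
    """
    path = Path(path)
    if format == "jsonl":
        rows = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        return _build_corpus(rows)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", dtype=str)
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        return _build_corpus(df.to_dict(orient="records"))
    raise SchemaError(f"unknown corpus format: {format!r}")


def write_records(path: str | Path, records: Iterable[dict]) -> None:
    """Write records as record-per-line JSON (UTF-8, one object per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_records(path: str | Path) -> list[dict]:
    """Read record-per-line JSON written by :func:`write_records`."""
    with Path(path).open(encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_narratives(path: str | Path, corpus: Iterable[Narrative]) -> None:
    """Write a corpus in the jsonl narrative format (round-trip stable)."""
    write_records(
        path,
        (
            {"event_id": n.event_id, "narrative_id": n.narrative_id, "text": n.text}
            for n in corpus
        ),
    )
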