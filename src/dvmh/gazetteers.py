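"""Loading, validation and matching of the 13 task-specific dictionaries.

Dictionaries (gazetteers) are plain-text ``.lst`` files, one entry per
line, with optional tab-separated fields::

    surface term<TAB>Canonical form<TAB>key=value key=value

Multiword terms are tokenized with the pipeline tokenizer, so matching
is over token sequences, not raw substrings.  Every ``mental_disorder``
entry must carry a canonical (standardized) disorder name; misspellings
("schitzophrenia") are explicit entries pointing at the same canonical —
there is no fuzzy matching at runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from dvmh.corpus_io import Token, tokenize
from dvmh.errors import ConfigError, ValidationError

__all__ = [
    "DICTIONARY_NAMES", "CAPTURE_DICTIONARIES",
    "GazetteerEntry", "Gazetteer", "GazetteerSet", "Lookup",
    "load_gazetteers", "default_gazetteers", "match_gazetteers",
]

#: The 13 dictionary names of the extraction system.
DICTIONARY_NAMES = (
    "adjectives", "be", "drug_addiction", "drug_names", "drug_types",
    "family", "have", "history", "mental_disorder", "negation",
    "poi", "verbs", "victim",
)

#: Dictionaries whose matches may be captured as disorder mentions.
CAPTURE_DICTIONARIES = frozenset(
    {"mental_disorder", "drug_names", "drug_types", "drug_addiction", "adjectives"}
)

#: Dictionaries whose entries must carry a canonical form.
_NEED_CANONICAL = CAPTURE_DICTIONARIES


@dataclass(frozen=True)
class GazetteerEntry:
    term: tuple[str, ...]           # case-folded token sequence
    dictionary: str
    canonical: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    @property
    def surface(self) -> str:
        return " ".join(self.term)


@dataclass
class Gazetteer:
    """One dictionary: entries indexed by first token for fast matching."""

    name: str
    entries: list[GazetteerEntry]

    def __post_init__(self) -> None:
        self._by_first: dict[str, list[GazetteerEntry]] = {}
        seen: set[tuple[str, ...]] = set()
        for e in self.entries:
            if e.term in seen:
                raise ValidationError(f"duplicate entry {e.surface!r} in {self.name!r}")
            seen.add(e.term)
            self._by_first.setdefault(e.term[0], []).append(e)
        # longer terms first so the first hit at a position is the longest
        for lst in self._by_first.values():
            lst.sort(key=lambda e: -len(e.term))

    def longest_match(self, folded: Sequence[str], i: int) -> GazetteerEntry | None:
        """Longest entry whose token sequence starts at index ``i``."""
        for e in self._by_first.get(folded[i], ()):
            n = len(e.term)
            if tuple(folded[i:i + n]) == e.term:
                return e
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Lookup:
    """A dictionary match over a half-open token-index span."""

    begin: int
    end: int
    dictionary: str
    entry: GazetteerEntry


class GazetteerSet(dict):
    """Mapping of dictionary name -> :class:`Gazetteer`."""

    def manifest(self) -> dict[str, int]:
        """Per-dictionary entry counts (reference metadata, not invariants)."""
        return {name: len(self[name]) for name in sorted(self)}


def _parse_line(line: str, name: str) -> GazetteerEntry | None:
    line = line.rstrip("\n")
    if not line.strip() or line.lstrip().startswith("#"):
        return None
    parts = line.split("\t")
    term_tokens = tuple(t.folded for t in tokenize(parts[0]))
    if not term_tokens:
        raise ValidationError(f"empty term line in dictionary {name!r}")
    canonical = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
    attributes: dict[str, str] = {}
    if len(parts) > 2 and parts[2].strip():
        for kv in parts[2].split():
            if "=" not in kv:
                raise ValidationError(f"bad attribute {kv!r} in {name!r}")
            k, _, v = kv.partition("=")
            attributes[k] = v
    return GazetteerEntry(term_tokens, name, canonical, attributes)


def load_gazetteers(directory: str | Path) -> GazetteerSet:
    """Load all 13 dictionaries from ``directory`` (one ``.lst`` per name).

    Raises :class:`ConfigError` for unknown or missing dictionary files
    and :class:`ValidationError` for empty dictionaries or capture-side
    entries lacking a canonical form.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.lst"))
    found: dict[str, Path] = {}
    for f in files:
        if f.stem not in DICTIONARY_NAMES:
            raise ConfigError(f"unknown dictionary file: {f.name}")
        found[f.stem] = f
    missing = [n for n in DICTIONARY_NAMES if n not in found]
    if missing:
        raise ConfigError(f"missing dictionary files: {missing}")

    gset = GazetteerSet()
    for name in DICTIONARY_NAMES:
        entries = []
        for line in found[name].read_text(encoding="utf-8").splitlines():
            entry = _parse_line(line, name)
            if entry is not None:
                entries.append(entry)
        if not entries:
            raise ValidationError(f"dictionary {name!r} is empty")
        if name in _NEED_CANONICAL:
            for e in entries:
                if not e.canonical:
                    raise ValidationError(
                        f"entry {e.surface!r} in {name!r} lacks a canonical form"
                    )
        gset[name] = Gazetteer(name, entries)
    return gset


def default_gazetteers() -> GazetteerSet:
    """Load the dictionaries shipped with the package."""
    from importlib.resources import files

    return load_gazetteers(Path(str(files("dvmh").joinpath("data/dicts"))))


def match_gazetteers(tokens: Sequence[Token], gazetteers: GazetteerSet) -> list[Lookup]:
    """Match every dictionary over ``tokens``.

    Per dictionary the scan is leftmost-longest: at each position the
    longest entry wins and the scan resumes after it, so a multiword
    entry suppresses shorter entries it covers within the same
    dictionary.  Lookups from *different* dictionaries may overlap
    freely (a role anchor and a disorder term must be able to coexist in
    one clause).  Output is sorted by span start, then dictionary name.
    """
    folded = [t.folded for t in tokens]
    lookups: list[Lookup] = []
    for name in sorted(gazetteers):
        gaz = gazetteers[name]
        i = 0
        while i < len(folded):
            entry = gaz.longest_match(folded, i)
            if entry is not None:
                lookups.append(Lookup(i, i + len(entry.term), name, entry))
                i += len(entry.term)
            else:
                i += 1
    lookups.sort(key=lambda lk: (lk.begin, lk.dictionary, -lk.end))
    return lookups
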