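"""Standardization and hierarchical ICD-10 mapping of disorder mentions.

The mapping schema extends ICD-10 Chapter V with eight custom level-1
categories (four psychotropic-medication classes, drug prescription
abuse, unspecified substance abuse, traumatic brain injury and
unspecified drug-induced disorder), giving exactly 26 level-1
categories.  Below level 1 sit reconstructed level-2 and level-3
rubrics; a handful of level-4 rubrics exist and are merged into level 3
for reporting (e.g. "Intermittent explosive disorder" is reported as a
level-3 value).

Mapping is term-group driven: each category owns a set of trigger
terms; a canonical disorder name is assigned to the deepest category
whose term group matches it (longest matching term first, then deepest
level), and the ancestor chain is filled backward.  Medication mentions
map only to the four medication categories — they never imply a
diagnosis.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from dvmh.errors import SchemaError, UnmappedTermError
from dvmh.rule_engine import Mention

__all__ = [
    "Category", "IcdSchema", "DisorderRecord", "EventExtraction",
    "load_schema", "default_schema", "validate_schema",
    "map_to_icd", "map_mentions", "deduplicate",
    "UNSPECIFIED_MENTAL_DISORDER", "GENERIC_MARKERS",
]

UNSPECIFIED_MENTAL_DISORDER = "Unspecified mental disorder"

#: Tokens marking a generic mental-health mention; names carrying one of
#: these but matching no term group fall back to the unspecified category.
GENERIC_MARKERS = frozenset({"mental", "psychiatric", "psychological"})


@dataclass(frozen=True)
class Category:
    level: int
    name: str
    parent: str | None


@dataclass
class IcdSchema:
    categories: dict[tuple[int, str], Category]
    term_groups: dict[str, tuple[int, str]]   # folded term -> (level, category name)

    def parent_of(self, cat: Category) -> Category | None:
        if cat.parent is None:
            return None
        key = (cat.level - 1, cat.parent)
        if key not in self.categories:
            raise SchemaError(
                f"level-{cat.level} category {cat.name!r} has unknown parent {cat.parent!r}"
            )
        return self.categories[key]

    def chain(self, cat: Category) -> dict[int, str]:
        """Ancestor chain of ``cat`` as {level: name}, including itself."""
        out: dict[int, str] = {}
        node: Category | None = cat
        while node is not None:
            out[node.level] = node.name
            node = self.parent_of(node)
        return out

    def level_count(self, level: int) -> int:
        return sum(1 for (lvl, _) in self.categories if lvl == level)


@dataclass(frozen=True)
class DisorderRecord:
    """A mapped, role-attributed disorder for one narrative."""

    event_id: str
    narrative_id: str
    role: str
    canonical: str
    level1: str
    level2: str | None = None
    level3: str | None = None


@dataclass(frozen=True)
class EventExtraction:
    """Deduplicated records for one event plus role flags."""

    event_id: str
    records: tuple[DisorderRecord, ...]
    poi_any: bool = field(default=False)
    victim_any: bool = field(default=False)

    @property
    def both(self) -> bool:
        return self.poi_any and self.victim_any


def load_schema(categories_path: str | Path, term_groups_path: str | Path) -> IcdSchema:
    """Load and validate the two schema tables.

    ``categories.tsv`` columns: level, name, parent (parent empty for
    level 1).  ``term_groups.tsv`` columns: term, category.
    """
    categories: dict[tuple[int, str], Category] = {}
    with Path(categories_path).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            level = int(row["level"])
            name = row["name"].strip()
            parent = (row.get("parent") or "").strip() or None
            if level < 1 or level > 4:
                raise SchemaError(f"bad level {level} for {name!r}")
            if (level == 1) != (parent is None):
                raise SchemaError(f"level-{level} category {name!r} parent mismatch")
            key = (level, name)
            if key in categories:
                raise SchemaError(f"duplicate category {name!r} at level {level}")
            categories[key] = Category(level, name, parent)

    by_name: dict[str, list[Category]] = {}
    for cat in categories.values():
        by_name.setdefault(cat.name.lower(), []).append(cat)

    term_groups: dict[str, tuple[int, str]] = {}
    with Path(term_groups_path).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            term = row["term"].strip().lower()
            target = row["category"].strip()
            cands = by_name.get(target.lower())
            if not cands:
                raise SchemaError(f"term {term!r} targets unknown category {target!r}")
            # deepest category of that name (names unique per level)
            cat = max(cands, key=lambda c: c.level)
            if term in term_groups and term_groups[term] != (cat.level, cat.name):
                raise SchemaError(f"term {term!r} assigned to two categories")
            term_groups[term] = (cat.level, cat.name)

    schema = IcdSchema(categories, term_groups)
    validate_schema(schema)
    return schema


def default_schema() -> IcdSchema:
    """Load the schema tables shipped with the package."""
    from importlib.resources import files

    base = files("dvmh").joinpath("data/schema")
    return load_schema(Path(str(base.joinpath("categories.tsv"))),
                      Path(str(base.joinpath("term_groups.tsv"))))


def validate_schema(schema: IcdSchema) -> dict:
    """QC report: category counts per level, orphan check, term collisions.

    Raises :class:`SchemaError` on an invariant violation (orphan
    category, broken parent chain).
    """
    orphans = []
    for cat in schema.categories.values():
        try:
            schema.chain(cat)
        except SchemaError:
            orphans.append((cat.level, cat.name))
    if orphans:
        raise SchemaError(f"orphan categories: {orphans}")
    counts = Counter(lvl for (lvl, _) in schema.categories)
    return {
        "level_counts": {lvl: counts.get(lvl, 0) for lvl in (1, 2, 3, 4)},
        "n_terms": len(schema.term_groups),
        "orphans": [],
    }


def _matching_terms(folded: str, schema: IcdSchema) -> list[str]:
    if folded in schema.term_groups:
        return [folded]
    words = folded.split()
    hits = []
    for term in schema.term_groups:
        tw = term.split()
        n = len(tw)
        if any(words[i:i + n] == tw for i in range(len(words) - n + 1)):
            hits.append(term)
    return hits


def map_to_icd(canonical: str, schema: IcdSchema) -> tuple[str, str | None, str | None]:
    """Map a canonical disorder name to its (level1, level2, level3) triple.

    The longest matching term wins, ties resolved to the deepest
    category (specificity first); ancestors are filled backward.
    Level-4 hits are reported in the level-3 slot.  A name with no
    term-group match maps to the unspecified category only when it
    carries a generic mental-health marker; otherwise
    :class:`UnmappedTermError` is raised so the caller can surface it in
    a QC report.
    """
    folded = canonical.strip().lower()
    hits = _matching_terms(folded, schema)
    if not hits:
        if GENERIC_MARKERS & set(folded.replace("-", " ").split()):
            return (UNSPECIFIED_MENTAL_DISORDER, None, None)
        raise UnmappedTermError(f"no ICD mapping for {canonical!r}")
    term = max(hits, key=lambda t: (len(t.split()), len(t), schema.term_groups[t][0]))
    level, name = schema.term_groups[term]
    chain = schema.chain(schema.categories[(level, name)])
    level3 = chain.get(4, chain.get(3))   # level-4 rubrics reported as level 3
    return (chain[1], chain.get(2), level3)


def map_mentions(
    mentions: Iterable[Mention], schema: IcdSchema
) -> tuple[list[DisorderRecord], list[dict]]:
    """Map mentions to :class:`DisorderRecord`; unmapped ones go to a QC list."""
    records: list[DisorderRecord] = []
    unmapped: list[dict] = []
    for m in mentions:
        try:
            l1, l2, l3 = map_to_icd(m.canonical, schema)
        except UnmappedTermError:
            unmapped.append({
                "event_id": m.event_id, "narrative_id": m.narrative_id,
                "canonical": m.canonical, "surface": m.surface,
            })
            continue
        records.append(DisorderRecord(
            m.event_id, m.narrative_id, m.role, m.canonical, l1, l2, l3,
        ))
    return records, unmapped


def deduplicate(
    records: Sequence[DisorderRecord], grouping: str = "narrative"
) -> list[EventExtraction]:
    """Deduplicate records and roll them up into per-event extractions.

    ``grouping="narrative"`` keeps records unique on
    (narrative_id, role, canonical) — the narrative-level unification of
    the extraction pipeline; ``grouping="event"`` unions across an
    event's narratives, unique on (role, canonical).  Idempotent.
    """
    if grouping not in ("narrative", "event"):
        raise ValueError(f"unknown grouping {grouping!r}")
    by_event: dict[str, dict[tuple, DisorderRecord]] = {}
    for rec in records:
        if grouping == "narrative":
            key = (rec.narrative_id, rec.role, rec.canonical.lower())
        else:
            key = (rec.role, rec.canonical.lower())
        by_event.setdefault(rec.event_id, {}).setdefault(key, rec)
    out = []
    for event_id in sorted(by_event):
        recs = tuple(sorted(
            by_event[event_id].values(),
            key=lambda r: (r.narrative_id, r.role, r.canonical),
        ))
        out.append(EventExtraction(
            event_id, recs,
            poi_any=any(r.role == "POI" for r in recs),
            victim_any=any(r.role == "victim" for r in recs),
        ))
    return out
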