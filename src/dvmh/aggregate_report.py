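"""Corpus-level aggregation and narrative-level evaluation.

Aggregation counts events and deduplicated disorder records by role and
ICD level, with percentages taken against the role's own level total
(e.g. each level-1 POI category over all level-1 POI mentions).
Evaluation compares predicted against gold annotations expressed as
unique (narrative_id, role, canonical) triples and reports precision,
recall and F-score per role; inter-annotator agreement is the absolute
agreement rate between two annotation sets.

Display percentages are rounded half-up (2 decimals for corpus shares,
1 decimal for metrics); full precision is retained internally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from dvmh.errors import InputError, UndefinedMetricError
from dvmh.icd_mapper import DisorderRecord, EventExtraction

__all__ = [
    "CorpusSummary", "EvalCounts", "Metrics",
    "round_half_up", "percentage",
    "precision", "recall", "f_score",
    "summarize", "evaluate", "absolute_agreement",
]

ROLES = ("POI", "victim")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 87.05 -> 87.1, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """``100 * count / total`` rounded half-up; undefined for total == 0."""
    if total <= 0:
        raise UndefinedMetricError("percentage undefined for zero total")
    return round_half_up(100.0 * count / total, ndigits)


# ------------------------------------------------------------- metrics

def precision(tp: int, fp: int) -> float:
    """100 * TP / (TP + FP); raises :class:`UndefinedMetricError` if TP+FP=0."""
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    return 100.0 * tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """100 * TP / (TP + FN); raises :class:`UndefinedMetricError` if TP+FN=0."""
    if tp + fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return 100.0 * tp / (tp + fn)


def f_score(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R) of precision and recall percentages."""
    if p + r == 0:
        raise UndefinedMetricError("F-score undefined: P + R = 0")
    return 2.0 * p * r / (p + r)


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("TP/FP/FN must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Percentages at full precision; ``None`` marks an undefined value."""

    precision: float | None
    recall: float | None
    f_score: float | None

    def rounded(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else round_half_up(v, 1))
            for k, v in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f_score", self.f_score),
            )
        }


def metrics_from_counts(counts: EvalCounts) -> Metrics:
    try:
        p = precision(counts.tp, counts.fp)
    except UndefinedMetricError:
        p = None
    try:
        r = recall(counts.tp, counts.fn)
    except UndefinedMetricError:
        r = None
    f = None
    if p is not None and r is not None and p + r > 0:
        f = f_score(p, r)
    return Metrics(p, r, f)


# ------------------------------------------------------------ summarize

@dataclass
class CorpusSummary:
    n_events_total: int
    n_events_with_mention: int
    n_events_poi_only: int
    n_events_victim_only: int
    n_events_both: int
    #: {(level, role): Counter of category -> mention count}
    counts: dict[tuple[int, str], Counter] = field(default_factory=dict)

    def role_level_total(self, level: int, role: str) -> int:
        return sum(self.counts.get((level, role), Counter()).values())

    def percentages(self, level: int, role: str) -> dict[str, float | None]:
        total = self.role_level_total(level, role)
        cats = self.counts.get((level, role), Counter())
        if total == 0:
            return {cat: None for cat in cats}
        return {cat: percentage(n, total) for cat, n in cats.items()}

    @property
    def pct_events_with_mention(self) -> float:
        return percentage(self.n_events_with_mention, self.n_events_total)

    def to_dict(self) -> dict:
        out = {
            "n_events_total": self.n_events_total,
            "n_events_with_mention": self.n_events_with_mention,
            "n_events_poi_only": self.n_events_poi_only,
            "n_events_victim_only": self.n_events_victim_only,
            "n_events_both": self.n_events_both,
            "levels": {},
        }
        for level in (1, 2, 3):
            out["levels"][level] = {}
            for role in ROLES:
                cats = self.counts.get((level, role), Counter())
                out["levels"][level][role] = {
                    "total": self.role_level_total(level, role),
                    "categories": dict(sorted(cats.items(), key=lambda kv: (-kv[1], kv[0]))),
                }
        return out


def summarize(extractions: Sequence[EventExtraction], n_events_total: int) -> CorpusSummary:
    """Aggregate deduplicated extractions over a corpus of ``n_events_total``.

    A record lacking level ℓ contributes to levels below ℓ only (not
    every mention is specific enough for levels 2-3).  Raises
    :class:`InputError` if the corpus size is smaller than the number of
    events with mentions.
    """
    with_mention = [e for e in extractions if e.records]
    if n_events_total < len(with_mention):
        raise InputError("n_events_total < number of events with mentions")
    counts: dict[tuple[int, str], Counter] = {}
    for ext in with_mention:
        for rec in ext.records:
            for level, value in ((1, rec.level1), (2, rec.level2), (3, rec.level3)):
                if value is not None:
                    counts.setdefault((level, rec.role), Counter())[value] += 1
    summary = CorpusSummary(
        n_events_total=n_events_total,
        n_events_with_mention=len(with_mention),
        n_events_poi_only=sum(1 for e in with_mention if e.poi_any and not e.victim_any),
        n_events_victim_only=sum(1 for e in with_mention if e.victim_any and not e.poi_any),
        n_events_both=sum(1 for e in with_mention if e.both),
        counts=counts,
    )
    assert (summary.n_events_poi_only + summary.n_events_victim_only
            + summary.n_events_both) == summary.n_events_with_mention
    return summary


# ------------------------------------------------------------- evaluate

Triple = tuple[str, str, str]   # (narrative_id, role, canonical folded)


def _as_triples(records: Iterable, events: dict[str, str]) -> set[Triple]:
    triples: set[Triple] = set()
    for rec in records:
        if isinstance(rec, DisorderRecord):
            event_id, narrative_id, role, canonical = (
                rec.event_id, rec.narrative_id, rec.role, rec.canonical)
        elif isinstance(rec, Mapping):
            event_id = rec["event_id"]
            narrative_id = rec["narrative_id"]
            role = rec["role"]
            canonical = rec["canonical"]
        else:   # (event_id, narrative_id, role, canonical)
            event_id, narrative_id, role, canonical = rec
        if events.setdefault(narrative_id, event_id) != event_id:
            raise InputError(
                f"narrative {narrative_id!r} appears under two event ids"
            )
        triples.add((narrative_id, role, canonical.strip().lower()))
    return triples


def evaluate(gold: Iterable, predicted: Iterable) -> dict[str, dict]:
    """Narrative-level evaluation per role.

    Both sides are reduced to unique (narrative_id, role, canonical)
    triples; TP are triples present on both sides, FP predicted-only,
    FN gold-only.  Returns ``{role: {"counts": EvalCounts, "metrics":
    Metrics}}``.  Raises :class:`InputError` when a narrative id maps to
    different event ids across the two sides.
    """
    events: dict[str, str] = {}
    gold_t = _as_triples(gold, events)
    pred_t = _as_triples(predicted, events)
    out = {}
    for role in ROLES:
        g = {t for t in gold_t if t[1] == role}
        p = {t for t in pred_t if t[1] == role}
        counts = EvalCounts(tp=len(g & p), fp=len(p - g), fn=len(g - p))
        out[role] = {"counts": counts, "metrics": metrics_from_counts(counts)}
    return out


def absolute_agreement(annotator1: Iterable, annotator2: Iterable) -> float:
    """Absolute agreement rate between two annotation sets.

    Operationalized as 100 * |intersection| / |union| of the annotation
    triples; undefined (raises) when both sets are empty.
    """
    events: dict[str, str] = {}
    a = _as_triples(annotator1, events)
    b = _as_triples(annotator2, events)
    if not a and not b:
        raise UndefinedMetricError("agreement undefined for two empty sets")
    return 100.0 * len(a & b) / len(a | b)
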