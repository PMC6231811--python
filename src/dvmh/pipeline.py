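"""End-to-end glue: tokenize -> gazetteer lookup -> rules -> map -> dedup."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from dvmh.corpus_io import Narrative, segment_sentences, tokenize
from dvmh.gazetteers import GazetteerSet, default_gazetteers, match_gazetteers
from dvmh.icd_mapper import (
    DisorderRecord, EventExtraction, IcdSchema, default_schema, deduplicate, map_mentions,
)
from dvmh.rule_engine import Mention, Rule, apply_rules, load_default_rules

__all__ = ["PipelineResult", "extract_mentions", "run_pipeline"]


@dataclass
class PipelineResult:
    mentions: list[Mention]
    records: list[DisorderRecord]
    extractions: list[EventExtraction]
    unmapped: list[dict]

    def triples(self) -> set[tuple[str, str, str]]:
        """Deduplicated (narrative_id, role, canonical) triples."""
        return {
            (r.narrative_id, r.role, r.canonical.lower())
            for ext in self.extractions for r in ext.records
        }


def extract_mentions(
    narrative: Narrative,
    gazetteers: GazetteerSet,
    rules: Sequence[Rule],
) -> list[Mention]:
    """Run tokenization, lookup and rule application on one narrative."""
    tokens = tokenize(narrative.text)
    sentences = segment_sentences(tokens, narrative.text)
    lookups = match_gazetteers(tokens, gazetteers)
    return apply_rules(narrative, tokens, sentences, lookups, rules)


def run_pipeline(
    narratives: Iterable[Narrative],
    gazetteers: GazetteerSet | None = None,
    rules: Sequence[Rule] | None = None,
    schema: IcdSchema | None = None,
    grouping: str = "narrative",
) -> PipelineResult:
    """Extract, standardize, map and deduplicate a whole corpus."""
    gazetteers = gazetteers or default_gazetteers()
    rules = rules if rules is not None else load_default_rules(gazetteers)
    schema = schema or default_schema()
    mentions: list[Mention] = []
    for narrative in narratives:
        mentions.extend(extract_mentions(narrative, gazetteers, rules))
    records, unmapped = map_mentions(mentions, schema)
    extractions = deduplicate(records, grouping=grouping)
    return PipelineResult(mentions, records, extractions, unmapped)
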