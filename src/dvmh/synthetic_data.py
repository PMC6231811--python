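"""Seeded generator of synthetic DV-style narratives with gold annotations.

The generator assembles narratives from the same building blocks the
extraction rules target: a role anchor (sampled from the poi/victim
dictionaries, including abbreviations like "vic" and "pinop"), a
linking template (semifrozen expressions such as "is suffering from",
"has a history of", "takes"), a disorder or medication term drawn from
the shipped gazetteers (optionally a gazetteer-listed misspelling),
optional negation (negated plants yield NO gold record), optional
comma/"and" enumeration, plus distractor sentences containing neither
role anchors nor disorder terms.  Gold is defined at the deduplicated
(narrative, role, canonical) triple level — the unit at which the
pipeline is evaluated.

It makes no attempt to mimic real police prose style or PII; it only
reproduces the lexical phenomena the extractor must handle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

from dvmh.corpus_io import Narrative
from dvmh.errors import ConfigError
from dvmh.gazetteers import GazetteerSet, default_gazetteers
from dvmh.icd_mapper import IcdSchema, default_schema, map_to_icd

__all__ = [
    "GenerationConfig", "GoldAnnotation", "AdversarialCase",
    "generate_corpus", "adversarial_suite",
]


@dataclass(frozen=True)
class GenerationConfig:
    """Study-shaped defaults: ~15.8% of events carry a mention, POI
    mentions roughly 4x victim mentions, both-role events ~1% — the
    qualitative shape of the large DV corpus the system targets."""

    n_events: int = 1000
    narratives_per_event: tuple[int, int] = (1, 2)
    p_poi_mention: float = 0.1323      # P(event has >=1 POI mention)
    p_victim_mention: float = 0.0365   # P(event has >=1 victim mention)
    p_both: float = 0.0104             # P(both roles mentioned)
    p_negation: float = 0.1
    p_enumeration: float = 0.15
    p_misspelling: float = 0.1
    p_medication: float = 0.15
    p_distractor_sentence: float = 0.7
    enumeration_length: tuple[int, int] = (2, 3)
    oov_misspellings: bool = False     # emit out-of-vocabulary misspellings
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_poi_mention": self.p_poi_mention,
            "p_victim_mention": self.p_victim_mention,
            "p_both": self.p_both,
            "p_negation": self.p_negation,
            "p_enumeration": self.p_enumeration,
            "p_misspelling": self.p_misspelling,
            "p_medication": self.p_medication,
            "p_distractor_sentence": self.p_distractor_sentence,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.p_both > min(self.p_poi_mention, self.p_victim_mention):
            raise ConfigError("p_both must not exceed min(p_poi, p_victim)")
        lo, hi = self.enumeration_length
        if not (1 <= lo <= hi):
            raise ConfigError("bad enumeration_length range")
        if self.n_events < 0:
            raise ConfigError("n_events must be >= 0")


@dataclass(frozen=True)
class GoldAnnotation:
    event_id: str
    narrative_id: str
    role: str
    canonical: str
    level1: str

    def to_dict(self) -> dict:
        return asdict(self)


# Linking templates.  ``neg`` is the template with a negation token in
# its natural slot; every positive form is matchable by the shipped
# rule set and every negated form is provably unmatchable (the
# exclusion windows refuse negation tokens).
@dataclass(frozen=True)
class _Template:
    name: str
    pos: str
    neg: str
    source: str            # mental_disorder | adjectives | drug
    enumerable: bool = False


_TEMPLATES: tuple[_Template, ...] = (
    _Template("suffer_prog", "{anchor} is suffering from {term}.",
              "{anchor} is not suffering from {term}.", "mental_disorder", True),
    _Template("suffer", "{anchor} suffers from {term}.",
              "{anchor} does not suffer from {term}.", "mental_disorder", True),
    _Template("suffer_perf", "{anchor} has been suffering from {term}.",
              "{anchor} has not been suffering from {term}.", "mental_disorder", True),
    _Template("history", "{anchor} has a history of {term}.",
              "{anchor} has no history of {term}.", "mental_disorder", True),
    _Template("history_long", "{anchor} has a long history of {term}.",
              "{anchor} denied any history of {term}.", "mental_disorder", True),
    _Template("has", "{anchor} has {term}.",
              "{anchor} does not have {term}.", "mental_disorder", True),
    _Template("diagnosed", "{anchor} was diagnosed with {term}.",
              "{anchor} was never diagnosed with {term}.", "mental_disorder", True),
    _Template("struggles", "{anchor} struggles with {term}.",
              "{anchor} denies struggling with {term}.", "mental_disorder", True),
    _Template("treated", "{anchor} is being treated for {term}.",
              "{anchor} is not being treated for {term}.", "mental_disorder", True),
    _Template("copula", "{anchor} is {term}.",
              "{anchor} is not {term}.", "adjectives", False),
    _Template("takes", "{anchor} takes {term}.",
              "{anchor} denies taking {term}.", "drug", False),
    _Template("takes_many", "{anchor} takes a number of {term}.",
              "{anchor} does not take any {term}.", "drug_types_only", False),
)

_POI_ANCHORS = ("The POI", "The accused", "The defendant", "The offender", "The suspect", "POI")
_VICTIM_ANCHORS = ("The victim", "The vic", "The pinop", "The complainant", "Victim")

_DISTRACTORS = (
    "Police attended the address after a report of an argument.",
    "The parties were spoken to and the matter was recorded.",
    "There was broken glass on the kitchen floor.",
    "Neighbours heard loud shouting earlier in the evening.",
    "The incident occurred at about ten pm.",
    "Both parties were advised of the order conditions.",
    "A short time later the male left the premises in a taxi.",
    "The argument started over money.",
    "Property was damaged during the incident.",
    "Officers completed the paperwork at the station.",
)

# mental_disorder surfaces starting with these tokens read as verb
# phrases and are skipped when filling noun slots in templates.
_NON_NOMINAL_FIRST = {"abuses", "abusing", "cut", "cuts", "cutting", "attempted", "tried"}


def _surface_pools(gazetteers: GazetteerSet) -> dict[str, dict[str, dict[str, list[str]]]]:
    """Per source dictionary: canonical -> {"plain": [...], "misspelled": [...]}."""
    pools: dict[str, dict[str, dict[str, list[str]]]] = {}
    for dname in ("mental_disorder", "adjectives", "drug_names", "drug_types", "drug_addiction"):
        by_canon: dict[str, dict[str, list[str]]] = {}
        for e in gazetteers[dname].entries:
            if dname == "mental_disorder" and e.term[0] in _NON_NOMINAL_FIRST:
                continue
            slot = "misspelled" if e.attributes.get("misspelling") == "1" else "plain"
            by_canon.setdefault(e.canonical, {"plain": [], "misspelled": []})[slot].append(
                " ".join(e.term)
            )
        pools[dname] = {c: s for c, s in by_canon.items() if s["plain"]}
    return pools


def _oov_mutate(surface: str, rng: random.Random, gazetteers: GazetteerSet) -> str:
    """Seeded single-character edits (letter doubling) making the surface
    out-of-vocabulary.  Every word is mutated so that no embedded
    partial phrase remains matchable."""
    known_tokens = {tok for g in gazetteers.values() for e in g.entries for tok in e.term}
    out = []
    for word in surface.split(" "):
        letters = [i for i, ch in enumerate(word) if ch.isalpha()]
        if not letters:
            out.append(word)
            continue
        for _ in range(20):
            i = rng.choice(letters)
            cand = word[:i] + word[i] + word[i:]
            if cand.lower() not in known_tokens:
                word = cand
                break
        else:
            word = word + "x"
        out.append(word)
    return " ".join(out)


def generate_corpus(
    config: GenerationConfig,
    gazetteers: GazetteerSet | None = None,
    schema: IcdSchema | None = None,
) -> tuple[list[Narrative], list[GoldAnnotation]]:
    """Generate a seeded corpus and its gold annotations.

    Fixed seed implies a byte-identical corpus.  Negated plants produce
    no gold record; enumerated plants produce one gold record per
    enumerated disorder; gold is deduplicated per (narrative, role,
    canonical).
    """
    config.validate()
    gazetteers = gazetteers or default_gazetteers()
    schema = schema or default_schema()
    pools = _surface_pools(gazetteers)
    level1_cache: dict[str, str] = {}

    def level1_of(canonical: str) -> str:
        if canonical not in level1_cache:
            level1_cache[canonical] = map_to_icd(canonical, schema)[0]
        return level1_cache[canonical]

    rng = random.Random(config.seed)
    narratives: list[Narrative] = []
    gold: dict[tuple[str, str, str], GoldAnnotation] = {}

    md_templates = [t for t in _TEMPLATES if t.source == "mental_disorder"]
    cop_template = next(t for t in _TEMPLATES if t.source == "adjectives")
    takes_template = next(t for t in _TEMPLATES if t.name == "takes")
    takes_many = next(t for t in _TEMPLATES if t.name == "takes_many")

    def pick_surface(dname: str, canonical: str) -> str:
        pool = pools[dname][canonical]
        if pool["misspelled"] and rng.random() < config.p_misspelling:
            surface = rng.choice(sorted(pool["misspelled"]))
        else:
            surface = rng.choice(sorted(pool["plain"]))
        if config.oov_misspellings and rng.random() < config.p_misspelling:
            surface = _oov_mutate(surface, rng, gazetteers)
        return surface

    def plant_sentence(role: str) -> tuple[str, list[tuple[str, str]]]:
        """One sentence for ``role``; returns (text, [(role, canonical), ...])."""
        anchor = rng.choice(_POI_ANCHORS if role == "POI" else _VICTIM_ANCHORS)
        negate = rng.random() < config.p_negation
        if rng.random() < config.p_medication:
            u = rng.random()
            if u < 0.6:
                dname, template = "drug_names", takes_template
            elif u < 0.8:
                dname, template = "drug_types", takes_many
            else:
                dname, template = "drug_addiction", takes_template
            canonical = rng.choice(sorted(pools[dname]))
            term = pick_surface(dname, canonical)
            plants = [(role, canonical)]
        else:
            template = rng.choice(md_templates + [cop_template])
            dname = "adjectives" if template.source == "adjectives" else "mental_disorder"
            if template.enumerable and rng.random() < config.p_enumeration:
                k = rng.randint(*config.enumeration_length)
                canonicals = rng.sample(sorted(pools[dname]), k)
                surfaces = [pick_surface(dname, c) for c in canonicals]
                term = ", ".join(surfaces[:-1]) + (", and " if k > 2 else " and ") + surfaces[-1]
                plants = [(role, c) for c in canonicals]
            else:
                canonical = rng.choice(sorted(pools[dname]))
                term = pick_surface(dname, canonical)
                plants = [(role, canonical)]
        text = (template.neg if negate else template.pos).format(anchor=anchor, term=term)
        return text, ([] if negate else plants)

    for ev in range(config.n_events):
        event_id = f"E{ev:06d}"
        u = rng.random()
        if u < config.p_both:
            roles = ["POI", "victim"]
        elif u < config.p_poi_mention:
            roles = ["POI"]
        elif u < config.p_poi_mention + (config.p_victim_mention - config.p_both):
            roles = ["victim"]
        else:
            roles = []
        n_narr = rng.randint(*config.narratives_per_event)
        plants_by_narr: dict[int, list[str]] = {i: [] for i in range(n_narr)}
        for role in roles:
            plants_by_narr[rng.randrange(n_narr)].append(role)
        for ni in range(n_narr):
            narrative_id = f"{event_id}-{ni + 1}"
            sentences: list[str] = []
            planted: list[tuple[str, str]] = []
            for role in plants_by_narr[ni]:
                text, plants = plant_sentence(role)
                sentences.append(text)
                planted.extend(plants)
            n_distr = sum(rng.random() < config.p_distractor_sentence for _ in range(3))
            n_distr = max(n_distr, 0 if sentences else 1)   # narratives are non-empty
            sentences.extend(rng.choice(_DISTRACTORS) for _ in range(n_distr))
            rng.shuffle(sentences)
            narratives.append(Narrative(event_id, narrative_id, " ".join(sentences)))
            for role, canonical in planted:
                key = (narrative_id, role, canonical.lower())
                if key not in gold:
                    gold[key] = GoldAnnotation(
                        event_id, narrative_id, role, canonical, level1_of(canonical)
                    )
    return narratives, sorted(gold.values(), key=lambda g: (g.narrative_id, g.role, g.canonical))


# ----------------------------------------------------- adversarial suite

@dataclass(frozen=True)
class AdversarialCase:
    """A documented failure-mode narrative with the EXPECTED system output.

    ``expected_mentions`` is exactly what the extractor should emit
    (including known false positives); ``expected_misses`` are true
    mentions the extractor is expected to miss (known false negatives).
    """

    narrative: Narrative
    expected_mentions: tuple[tuple[str, str], ...]   # (role, canonical)
    expected_misses: tuple[tuple[str, str], ...] = ()
    note: str = ""


def adversarial_suite() -> list[AdversarialCase]:
    """Regression set of documented failure modes (deidentified paraphrases)."""
    def case(i: int, text: str, mentions, misses, note) -> AdversarialCase:
        return AdversarialCase(
            Narrative(f"ADV{i:02d}", f"ADV{i:02d}-1", text),
            tuple(mentions), tuple(misses), note,
        )

    return [
        case(1, "POI has the potential to become violent with the victims due to her alcoholism.",
             [("victim", "Alcohol abuse")], [("POI", "Alcohol abuse")],
             "ambiguous pattern: disorder belongs to the POI but a victim-anchored "
             "short-window rule attributes it to the victim (expected false positive)"),
        case(2, "As a result of the glass on the floor the defendant had cut herself.",
             [("POI", "Self-harm")], [],
             "situational phrase maps to a disorder term (expected false positive for POI)"),
        case(3, "There has been a history of alcohol abuse and malicious damage "
                "perpetrated by the accused.",
             [], [("POI", "Alcohol abuse")],
             "unseen pattern: anchor follows the disorder (expected false negative)"),
        case(4, "The victim also stated to police that during her time with the POI she "
                "was intoxicated as she has an alcohol addiction.",
             [], [("victim", "Alcohol abuse")],
             "anchor too distant from the disorder mention (expected false negative)"),
        case(5, "Her child's behavior is because of a condition ADHD.",
             [], [("POI", "Attention deficit hyperactivity disorder")],
             "no semantic role anchor; rules decline third parties (expected false negative)"),
        case(6, "XXX was admitted to YYY house for depression and anorexia.",
             [], [("victim", "Depression"), ("victim", "Anorexia nervosa")],
             "name placeholder instead of a role anchor (expected false negatives)"),
    ]
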