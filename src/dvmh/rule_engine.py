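"""JAPE-style lexical pattern rules for role-attributed disorder mentions.

A rule is an ordered sequence of pattern elements matched over the
tokens and gazetteer lookups of one sentence (rules never cross a
sentence boundary).  Element kinds:

``lit:word``
    a literal token, case-insensitive;
``dict:name``
    a lookup from the named dictionary (consumes the whole lookup span);
``not:name``
    a single token that is *not* part of any lookup from the named
    dictionary — the negation-exclusion window of GATE's
    ``{Token!Lookup}`` construct;
``any``
    any single token;
``cap:name``
    like ``dict:`` but marks the capture slot whose lookup yields the
    disorder mention (must be a disorder/medication dictionary).

Quantifiers: a trailing ``?`` makes an element optional ((0,1)); a
trailing ``{m,n}`` repeats it between m and n times.  Rule files are
plain text, one rule per block::

    rule poi_verb_mental_disorder
    role POI
    pattern dict:poi dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:mental_disorder

After a capture, comma/"and" enumerations are expanded: each further
disorder lookup separated by "," / "and" / ", and" yields its own
mention with the same role, stopping at the first token that is neither
separator nor disorder lookup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from dvmh.corpus_io import Narrative, Sentence, Token
from dvmh.errors import ConfigError, ValidationError
from dvmh.gazetteers import CAPTURE_DICTIONARIES, GazetteerSet, Lookup

__all__ = [
    "PatternElement", "Rule", "Mention",
    "parse_rules", "load_default_rules", "build_default_rule_text",
    "apply_rules", "apply_negation", "expand_enumeration",
]

_MAX_REPEAT = 6   # small bound on element quantifiers

ROLES = ("POI", "victim")


@dataclass(frozen=True)
class PatternElement:
    kind: str                 # literal | lookup | not_in_dictionary | wildcard
    payload: str | None       # literal string or dictionary name
    min: int = 1
    max: int = 1
    capture: bool = False


@dataclass(frozen=True)
class Rule:
    rule_id: str
    role: str                 # POI | victim
    elements: tuple[PatternElement, ...]

    @property
    def capture_index(self) -> int:
        return next(i for i, e in enumerate(self.elements) if e.capture)


@dataclass(frozen=True)
class Mention:
    """A role-attributed disorder mention with source offsets."""

    event_id: str
    narrative_id: str
    role: str
    surface: str
    canonical: str
    start: int
    end: int
    rule_id: str

    def triple(self) -> tuple[str, str, str]:
        return (self.narrative_id, self.role, self.canonical)


# ---------------------------------------------------------------- parsing

_ELEM_RE = re.compile(
    r"^(?P<kind>lit|dict|not|cap|any)(?::(?P<payload>[^\s{?]+))?"
    r"(?P<quant>\?|\{\d+,\d+\})?$"
)


def _parse_element(spec: str, gazetteers: GazetteerSet) -> PatternElement:
    m = _ELEM_RE.match(spec)
    if not m:
        raise ValidationError(f"bad pattern element: {spec!r}")
    kind_tag, payload, quant = m.group("kind"), m.group("payload"), m.group("quant")
    lo, hi = 1, 1
    if quant == "?":
        lo = 0
    elif quant:
        lo, hi = (int(x) for x in quant[1:-1].split(","))
        if lo > hi or hi > _MAX_REPEAT:
            raise ValidationError(f"bad quantifier in {spec!r}")
    if kind_tag == "any":
        if payload:
            raise ValidationError(f"'any' takes no payload: {spec!r}")
        return PatternElement("wildcard", None, lo, hi)
    if not payload:
        raise ValidationError(f"missing payload in {spec!r}")
    if kind_tag == "lit":
        return PatternElement("literal", payload.lower(), lo, hi)
    if payload not in gazetteers:
        raise ConfigError(f"unknown dictionary {payload!r} in element {spec!r}")
    if kind_tag == "dict":
        return PatternElement("lookup", payload, lo, hi)
    if kind_tag == "not":
        return PatternElement("not_in_dictionary", payload, lo, hi)
    # cap
    if payload not in CAPTURE_DICTIONARIES:
        raise ValidationError(
            f"capture must be over a disorder/medication dictionary, got {payload!r}"
        )
    if (lo, hi) != (1, 1):
        raise ValidationError("capture element cannot carry a quantifier")
    return PatternElement("lookup", payload, 1, 1, capture=True)


def parse_rules(source: str | Path, gazetteers: GazetteerSet) -> list[Rule]:
    """Parse a rule file (path or rule text) against loaded gazetteers."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)

    rules: list[Rule] = []
    block: dict[str, str] = {}

    def flush() -> None:
        if not block:
            return
        for key in ("rule", "role", "pattern"):
            if key not in block:
                raise ValidationError(f"rule block missing {key!r}: {block}")
        if block["role"] not in ROLES:
            raise ValidationError(f"unknown role {block['role']!r}")
        elements = tuple(
            _parse_element(tok, gazetteers) for tok in block["pattern"].split()
        )
        if not elements:
            raise ValidationError("empty pattern")
        captures = [e for e in elements if e.capture]
        if len(captures) != 1:
            raise ValidationError(
                f"rule {block['rule']!r} must have exactly one capture element"
            )
        rules.append(Rule(block["rule"], block["role"], elements))
        block.clear()

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            if not line:
                flush()
            continue
        key, _, value = line.partition(" ")
        block[key] = value.strip()
    flush()
    if not rules:
        raise ValidationError("no rules found")
    seen = set()
    for r in rules:
        if r.rule_id in seen:
            raise ValidationError(f"duplicate rule id {r.rule_id!r}")
        seen.add(r.rule_id)
    return rules


# ----------------------------------------------------- default rule set

# Linking templates are enumerated from the lexical patterns the system
# targets: semifrozen verb expressions ("is suffering from", "takes"),
# history phrases ("has a history of"), plain "has X", adjectival copula
# ("is schizophrenic"), and a short-window direct association.  Each is
# crossed with both role anchors and with the capture dictionaries that
# make sense for it.  Exclusion windows never absorb negation tokens, so
# "does not suffer from", "denies having" etc. kill the match.
_TEMPLATES: list[tuple[str, str, tuple[str, ...]]] = [
    ("verb", "dict:{anchor} dict:have? dict:be? not:negation{{0,1}} dict:verbs not:negation{{0,3}} cap:{cap}",
     ("mental_disorder", "drug_names", "drug_types", "drug_addiction")),
    ("hist", "dict:{anchor} not:negation{{0,1}} dict:have? not:negation{{0,1}} dict:history cap:{cap}",
     ("mental_disorder", "drug_addiction")),
    ("have", "dict:{anchor} not:negation{{0,1}} dict:have not:negation{{0,2}} cap:{cap}",
     ("mental_disorder",)),
    ("cop", "dict:{anchor} dict:be not:negation{{0,1}} cap:{cap}",
     ("adjectives",)),
    ("direct", "dict:{anchor} not:negation{{0,3}} cap:{cap}",
     ("mental_disorder",)),
]


def build_default_rule_text() -> str:
    """Compose the shipped rule set: {role anchor} x {template} x {capture}."""
    blocks = []
    for role, anchor in (("POI", "poi"), ("victim", "victim")):
        for name, pattern, caps in _TEMPLATES:
            for cap in caps:
                blocks.append(
                    f"rule {role.lower()}_{name}_{cap}\n"
                    f"role {role}\n"
                    f"pattern {pattern.format(anchor=anchor, cap=cap)}\n"
                )
    header = "# Role-attributed disorder-mention rules (composed; see docs/methods.md)\n"
    return header + "\n" + "\n".join(blocks)


def load_default_rules(gazetteers: GazetteerSet) -> list[Rule]:
    """Parse the rule file shipped under ``dvmh/data/rules``."""
    from importlib.resources import files

    return parse_rules(Path(str(files("dvmh").joinpath("data/rules/default.rules"))), gazetteers)


# ------------------------------------------------------------- matching

@dataclass(frozen=True)
class _Parse:
    end: int                                  # token index past the match
    capture: Lookup
    windows: tuple[tuple[str, int], ...]      # (dictionary, token index) per not-element token


def apply_negation(parse: _Parse, covered: dict[str, set[int]]) -> bool:
    """Keep (True) or drop (False) a candidate match.

    A candidate is dropped when any token consumed by one of its
    exclusion windows belongs to a lookup from the window's dictionary
    (e.g. "not" / "denies" inside a negation window).
    """
    return not any(idx in covered.get(dname, ()) for dname, idx in parse.windows)


def _match_rule_at(
    rule: Rule,
    start: int,
    sent_end: int,
    folded: Sequence[str],
    lookup_at: dict[tuple[str, int], Lookup],
    covered: dict[str, set[int]],
) -> _Parse | None:
    """All parses of ``rule`` anchored at ``start``; longest surviving one."""
    parses: list[_Parse] = []

    def step(ei: int, pos: int, capture: Lookup | None, windows: tuple) -> None:
        if ei == len(rule.elements):
            if capture is not None:
                parses.append(_Parse(pos, capture, windows))
            return
        elem = rule.elements[ei]

        def consume(n_done: int, p: int, cap: Lookup | None, win: tuple) -> None:
            if n_done >= elem.min:
                step(ei + 1, p, cap, win)
            if n_done == elem.max or p >= sent_end:
                return
            if elem.kind == "literal":
                if folded[p] == elem.payload:
                    consume(n_done + 1, p + 1, cap, win)
            elif elem.kind == "wildcard":
                consume(n_done + 1, p + 1, cap, win)
            elif elem.kind == "not_in_dictionary":
                consume(n_done + 1, p + 1, cap, win + ((elem.payload, p),))
            else:  # lookup
                lk = lookup_at.get((elem.payload, p))
                if lk is not None and lk.end <= sent_end:
                    consume(n_done + 1, lk.end, lk if elem.capture else cap, win)

        consume(0, pos, capture, windows)

    step(0, start, None, ())
    surviving = [p for p in parses if apply_negation(p, covered)]
    if not surviving:
        return None
    # earliest capture wins (windows must not swallow the first disorder
    # of an enumeration), then the longest overall span
    return max(surviving, key=lambda p: (-p.capture.begin, p.end))


_SEPARATOR_COMMA = ","
_SEPARATOR_AND = "and"


def expand_enumeration(
    capture: Lookup,
    sent_end: int,
    folded: Sequence[str],
    lookup_at: dict[tuple[str, int], Lookup],
) -> list[Lookup]:
    """The capture lookup plus any comma/"and"-enumerated disorder lookups.

    Enumeration stops at the first position that is neither a separator
    nor a disorder lookup.
    """
    out = [capture]
    pos = capture.end
    while True:
        j = pos
        saw_sep = False
        if j < sent_end and folded[j] == _SEPARATOR_COMMA:
            j += 1
            saw_sep = True
        if j < sent_end and folded[j] == _SEPARATOR_AND:
            j += 1
            saw_sep = True
        if not saw_sep:
            break
        nxt = None
        for dname in sorted(CAPTURE_DICTIONARIES):
            lk = lookup_at.get((dname, j))
            if lk is not None and lk.end <= sent_end and (nxt is None or lk.end > nxt.end):
                nxt = lk
        if nxt is None:
            break
        out.append(nxt)
        pos = nxt.end
    return out


def apply_rules(
    narrative: Narrative,
    tokens: Sequence[Token],
    sentences: Sequence[Sentence],
    lookups: Sequence[Lookup],
    rules: Iterable[Rule],
) -> list[Mention]:
    """Apply every rule independently over each sentence.

    For a fixed rule, overlapping candidate matches resolve
    leftmost-longest.  Duplicate mentions (same role, span and
    canonical) are emitted once with the lexicographically smallest
    rule id; output is ordered by span start, then role, then rule id.
    """
    folded = [t.folded for t in tokens]
    lookup_at: dict[tuple[str, int], Lookup] = {}
    covered: dict[str, set[int]] = {}
    for lk in lookups:
        lookup_at[(lk.dictionary, lk.begin)] = lk
        covered.setdefault(lk.dictionary, set()).update(range(lk.begin, lk.end))

    raw: dict[tuple[str, int, int, str], Mention] = {}
    for rule in rules:
        for sent in sentences:
            pos = sent.begin
            while pos < sent.end:
                parse = _match_rule_at(rule, pos, sent.end, folded, lookup_at, covered)
                if parse is None:
                    pos += 1
                    continue
                for lk in expand_enumeration(parse.capture, sent.end, folded, lookup_at):
                    start = tokens[lk.begin].start
                    end = tokens[lk.end - 1].end
                    key = (rule.role, start, end, lk.entry.canonical or "")
                    mention = Mention(
                        narrative.event_id, narrative.narrative_id, rule.role,
                        narrative.text[start:end], lk.entry.canonical or "",
                        start, end, rule.rule_id,
                    )
                    prev = raw.get(key)
                    if prev is None or mention.rule_id < prev.rule_id:
                        raw[key] = mention
                pos = parse.end  # leftmost-longest: resume after the match
    out = list(raw.values())
    out.sort(key=lambda m: (m.start, m.role, m.rule_id))
    return out
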