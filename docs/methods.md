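# Methods note

This note documents the design of the `dvmh` pipeline: the extraction model
and its assumptions, the resources it ships, the synthetic-data generator
used for testing, and the numerical and design choices made where the design
was genuinely open.

## Extraction model

The extractor is knowledge-driven: no learned components. A mention is
emitted only when three things co-occur inside one sentence, in order —
a **role anchor** (a term from the `poi` or `victim` dictionary), a
**linking template** (a lexical pattern built from the `be`/`have`/`verbs`/
`history` dictionaries and bounded wildcard windows), and a **captured
disorder term** (a lookup from `mental_disorder`, `drug_names`,
`drug_types`, `drug_addiction`, or `adjectives`, each of which carries a
canonical standardized name).

Assumptions baked into this design:

- **Sentence locality.** Rules never match across sentence boundaries.
  Patterns of this kind are clause-local; cross-sentence matching mostly
  manufactures role-attribution errors. Sentences split after `.` `!` `?`
  and at newlines.
- **Precision first.** Wildcard windows between anchor and disorder are
  capped at 3 tokens, and no rule fires without a role anchor. Mentions
  about third parties ("her child", a named person) are deliberately not
  captured; widening the rules to catch them would create false positives
  for other individuals involved in an event.
- **Negation by exclusion windows.** Window elements match any token *not*
  in the `negation` dictionary, so a negation cue ("not", "denies", "no",
  "doesn't", ...) between anchor and disorder blocks the match. There is no
  scope model beyond this window semantics.
- **No fuzzy matching.** Misspellings are explicit dictionary entries
  ("schitzophrenia" → Schizophrenia). An out-of-vocabulary misspelling is
  simply missed; the acceptance script quantifies that recall cost.

### Rule set

The shipped rule file (`src/dvmh/data/rules/default.rules`) is composed
mechanically as {role anchor} × {linking template} × {capture dictionary}
(18 rules; `dvmh.rule_engine.build_default_rule_text` regenerates it). The
templates are: verb links ("is suffering from", "takes", "was diagnosed
with"), history phrases ("has a history of", "hx of"), plain possession
("has X"), adjectival copula ("is schizophrenic"), and a short-window
direct association. Rule counts are configuration, not a claim: users can
extend the file without touching code.

Family-prefixed anchors ("the accused's mother has depression") were
considered and excluded: the disorder there belongs to the relative, not to
either role, and emitting it for the anchor role would be a systematic
false positive. The `family` dictionary ships for users who want to build
such rules themselves.

The direct-association template is the precision/recall compromise that
reproduces a documented failure mode on purpose: in "POI has the potential
to become violent with the victims due to her alcoholism", the victim
anchor sits within three tokens of "alcoholism" and the system attributes
the disorder to the victim. `dvmh.synthetic_data.adversarial_suite()`
freezes this and five other catalogued failure cases (expected false
positives and false negatives) as regression tests; "fixing" them would
change documented behavior.

### Matching semantics

- Gazetteer matching is case-insensitive and leftmost-longest **per
  dictionary** (a multiword entry suppresses shorter entries it covers);
  dictionaries may overlap each other freely. Equivalence with a
  brute-force all-spans oracle is property-tested.
- For one rule, overlapping candidate matches resolve leftmost-longest;
  among parses anchored at one position the parse with the **earliest
  capture** wins (otherwise a wildcard window could swallow the first item
  of an enumeration), with ties broken toward the longest span.
- Enumeration: after a capture, repeated {`,` | `and` | `, and`} +
  disorder-lookup groups each emit a mention with the same role; expansion
  stops at the first token that is neither separator nor disorder lookup.
- Identical (role, span, canonical) mentions from different rules are
  emitted once, keeping the lexicographically smallest rule id; output is
  ordered by span start, then role, then rule id — reruns are
  byte-identical.

## Dictionaries

Thirteen dictionaries ship as editable one-entry-per-line `.lst` files with
optional tab-separated canonical forms and `key=value` attributes
(misspelling flags, medication classes). Their contents are representative
reconstructions: disorder terms are seeded from ICD-10 Chapter V rubric
names plus every published example (including misspellings such as
"scitzophrenia" and "aspergus syndrome"); entry counts are reported by a
manifest and are deliberately not invariants. Disorder-side entries must
carry a canonical name; loading fails otherwise.

## ICD-10 mapping schema

Two TSV tables define the schema: `categories.tsv` (level, name, parent)
and `term_groups.tsv` (trigger term → category). Level 1 has exactly 26
categories — 18 ICD-10-derived plus 8 custom ones (medications-
antidepressants/-antianxiety/-antipsychotics/-neuroleptics, drug
prescription abuse, substance abuse (unspecified), traumatic brain injury,
unspecified drug-induced disorder). The reconstructed level-2/level-3
membership (39 and 32 categories in the shipped tables) covers every
category the pipeline's own resources can produce; both tables are data,
not code, and can be extended.

Mapping rules:

- the longest matching trigger term wins, ties to the deepest category
  (specificity first: "postpartum depression" beats "depression");
- ancestors are filled backward, so a level-3 assignment always implies
  consistent level-2 and level-1 values;
- the few level-4 rubrics (e.g. "Intermittent explosive disorder") are
  reported in the level-3 slot, replacing the residual "other ..." rubric;
- a name with no trigger hit maps to "Unspecified mental disorder" only if
  it carries a generic marker token ("mental", "psychiatric",
  "psychological"); anything else raises and is surfaced in a QC report,
  never dropped silently;
- medication mentions map only to the four medication categories and never
  imply a diagnosis. "Mood stabilizer" has no natural home among the four
  classes; it is routed to medications-antipsychotics as the least-bad
  choice (lithium and several atypical antipsychotics are prescribed as
  mood stabilizers), a judgment call recorded here.

Deduplication keys on (narrative, role, canonical) — not on the level-1
category — so distinct disorders under one category are preserved;
event-level grouping unions across an event's narratives.

## Evaluation and aggregation

Precision, recall and F-score are computed per role over deduplicated
(narrative, role, canonical) triples. Zero denominators raise an
undefined-metric signal rather than returning 0. Display rounding is
half-up (1 decimal for metrics, 2 for corpus percentages); full precision
is kept internally. Inter-annotator agreement is operationalized as
intersection-over-union of the two annotators' triple sets (the "absolute
agreement rate"); this is a design choice — the alternative (mean pairwise
per-narrative agreement) can be computed from the same triples. Corpus
percentages are taken against the role's own level total (each level-1 POI
category over all level-1 POI mentions), the convention that makes the
published-style tables internally consistent.

## Synthetic-data generator

`GenerationConfig` defaults encode the qualitative shape of the target
corpus: P(event has a POI mention) = 0.1323, victim = 0.0365, both =
0.0104, giving ≈15.8% of events with any mention and a ≈4:1 POI:victim
ratio. Narratives have 1–2 records per event, 1–6 sentences each
(planted sentences plus 0–3 distractors drawn at p = 0.7 per slot);
negation probability 0.1, enumeration 0.15 (length 2–3), misspelling 0.1,
medication 0.15. Misspelled plants use only gazetteer-listed variants, so
the clean configuration is fully recoverable; an `oov_misspellings` switch
perturbs every word of the surface with seeded character doublings that are
provably out of vocabulary, to measure recall degradation. Negated plants
produce no gold record; gold is defined at the deduplicated triple level,
the same unit the evaluator uses.

What the generator does **not** emulate: real police prose style, narrative
length distributions (unknown — the real data are restricted), named
entities, coreference, or structurally ambiguous sentences beyond the
frozen adversarial suite. Perfect scores on the clean synthetic
configuration therefore demonstrate the pipeline's internal consistency
(every planted phenomenon is recovered exactly), not field performance on
real narratives.

## Problem sizes and numerical choices

Property suites run at sizes chosen to make sampling error negligible while
keeping the default test run fast: 10,000 events for the end-to-end
recovery and prevalence checks (prevalence asserted within 3 standard
errors), 1,000 random instances for the matcher-vs-oracle equivalence, and
a few hundred events for idempotence/monotonicity checks. All randomness is
seeded; generation and extraction are deterministic functions of the seed.

## Known limitations

- Mentions are what police wrote, not clinical diagnoses; veracity is out
  of scope.
- Recall on real text hinges on dictionary and template coverage, which is
  reconstructed here and intentionally conservative.
- One anchor does not distribute across coordinated predicates ("the
  accused is suffering from X **and takes Y**" yields only X) — accepting
  this miss keeps the windows short and precision high.
- No de-identification or PII handling: the package never sees restricted
  data and the generator emits none.
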