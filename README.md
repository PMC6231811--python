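# dvmh — mental-health disorder mentions in domestic-violence police narratives

`dvmh` is a rule-based text-mining pipeline that detects mentions of
mental-health disorders in free-text domestic-violence (DV) police event
narratives, attributes each mention to the **person of interest (POI)** or the
**victim**, standardizes noisy surface forms (misspellings, abbreviations,
drug brand names), maps them into an extended four-level ICD-10 schema, and
deduplicates to one record per (narrative, role, disorder). It is aimed at
health-informatics and public-health researchers who need structured
mental-health signals from police free text for surveillance and research.

Because real police narratives are access-restricted, the package ships a
seeded **synthetic-narrative generator** that emulates the phenomena the
extractor must handle — role anchors ("accused", "vic", "pinop"), semifrozen
expressions ("is suffering from", "has a history of"), misspellings
("schitzophrenia"), medication names ("Zoloft", "Xanax"), negation ("denies",
"not"), comma/"and" enumerations, and distractor sentences — together with
gold annotations, so the whole pipeline is testable end to end.

## How it works

1. **Tokenize + segment.** Offset-anchored tokens (hyphenated compounds such
   as "self-harm" stay single tokens); sentences are the scope within which
   rules match.
2. **Gazetteer lookup.** Thirteen hand-curated dictionaries (role anchors,
   verbs, history phrases, negation cues, disorder terms with canonical
   forms, drug names/classes/substances) are matched case-insensitively,
   leftmost-longest per dictionary.
3. **Pattern rules.** JAPE-style rules combine a role anchor with a linking
   template and a captured disorder lookup, e.g.

   ```
   rule poi_verb_mental_disorder
   role POI
   pattern dict:poi dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:mental_disorder
   ```

   `not:negation{m,n}` windows match tokens that are **not** negation cues,
   so "POI does not suffer from depression" never fires. A capture followed
   by `,`/`and`-separated disorder lookups expands into one mention per
   enumerated disorder.
4. **ICD-10 mapping.** Each canonical form maps to the deepest category whose
   term group contains it (longest term, then deepest level), with ancestors
   filled backward across a 26-category level-1 schema (18 ICD-10 derived + 8
   custom categories such as the four psychotropic-medication classes and
   traumatic brain injury). Level-4 rubrics are reported as level 3.
5. **Deduplicate + aggregate + evaluate.** Records are unique per
   (narrative, role, canonical); corpus summaries count events and mentions
   per role and level; evaluation computes precision `TP/(TP+FP)`, recall
   `TP/(TP+FN)` and F-score `2PR/(P+R)` per role over deduplicated triples.

## Worked example

```python
from dvmh import Narrative
from dvmh.gazetteers import default_gazetteers
from dvmh.rule_engine import load_default_rules
from dvmh.pipeline import run_pipeline

gaz = default_gazetteers()
rules = load_default_rules(gaz)

text = ("The accused is suffering from schitzophrenia and takes Risperdal. "
        "The victim has a history of depression, self-harm, and suicidal tendencies. "
        "The accused does not have anxiety. "
        "Police attended the address after a report of an argument.")
result = run_pipeline([Narrative("E0001", "E0001-1", text)], gaz, rules)
for rec in result.extractions[0].records:
    print(f"{rec.role:7s} {rec.canonical:20s} L1={rec.level1}")
    print(f"        {'':20s} L2={rec.level2}  L3={rec.level3}")
```

prints

```
POI     Schizophrenia        L1=Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
                             L2=Schizophrenia  L3=Schizophrenia, unspecified
victim  Depression           L1=Mood (affective) disorders
                             L2=Major depressive disorder, single episode  L3=None
victim  Self-harm            L1=Intentional self-harm
                             L2=None  L3=None
victim  Suicidal tendencies  L1=Symptoms, signs, and abnormal clinical and laboratory findings
                             L2=Symptoms and signs involving emotional state  L3=Suicidal ideations
```

The misspelling "schitzophrenia" standardizes to *Schizophrenia* and is
attributed to the POI; the victim's three enumerated disorders each become a
record; the negated "does not have anxiety" is suppressed. "takes Risperdal"
is deliberately missed: the clause has no role anchor of its own, and the
rules decline anchor-less attributions to protect precision. Note that
`L3=None` means the mention was not specific enough for a third-level code.

Command-line equivalents: `dvmh synth`, `dvmh extract`, `dvmh aggregate`,
`dvmh evaluate`, `dvmh validate-schema` (see `dvmh --help`).

## Limitations

Dictionaries and rules are representative reconstructions (their coverage is
configurable, not fixed); there is no fuzzy matching, coreference, or
handling of third parties (witnesses, children), and mentions reflect what
police recorded, not clinical diagnoses. See `docs/methods.md` for the full
methods note, including known failure modes that are intentionally preserved
and regression-tested.
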