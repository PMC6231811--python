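import pytest

from dvmh.errors import SchemaError, UnmappedTermError
from dvmh.icd_mapper import (
    DisorderRecord, deduplicate, load_schema, map_to_icd, validate_schema,
)


class TestMapping:
    @pytest.mark.parametrize("canonical,expected", [
        ("Oppositional defiance disorder",
         ("Behavioral and emotional disorders with onset usually occurring in childhood and adolescence",
          "Conduct disorders", "Oppositional defiance disorder")),
        ("Zoloft", ("Medications-antidepressants", None, None)),
        ("Self-harm", ("Intentional self-harm", None, None)),
        ("Schizophrenia",
         ("Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders",
          "Schizophrenia", "Schizophrenia, unspecified")),
        ("Intermittent explosive disorder",
         ("Disorders of adult personality and behavior",
          "Impulse disorders", "Intermittent explosive disorder")),
    ])
    def test_mapping_examples(self, schema, canonical, expected):
        assert map_to_icd(canonical, schema) == expected

    def test_level_four_reported_as_level_three(self, schema):
        # the fourth-level rubric replaces the "other" third-level name
        l1, l2, l3 = map_to_icd("Intermittent explosive disorder", schema)
        assert l3 == "Intermittent explosive disorder"
        assert l2 == "Impulse disorders"

    def test_generic_marker_falls_back_to_unspecified(self, schema):
        assert map_to_icd("long-standing mental health concerns", schema) == (
            "Unspecified mental disorder", None, None)

    def test_unknown_name_without_marker_raises(self, schema):
        with pytest.raises(UnmappedTermError):
            map_to_icd("broken arm", schema)

    def test_specificity_longest_term_wins(self, schema):
        # "postpartum depression" must not collapse onto plain "depression"
        assert map_to_icd("Postpartum depression", schema)[2] == "Postpartum depression"
        assert map_to_icd("Depression", schema) == (
            "Mood (affective) disorders", "Major depressive disorder, single episode", None)

    def test_mapping_is_pure(self, schema):
        assert map_to_icd("Anxiety", schema) == map_to_icd("Anxiety", schema)

    def test_backward_fill_matches_ancestor_chain(self, schema):
        """Every term group's emitted triple equals the schema ancestor chain."""
        for term, (level, name) in schema.term_groups.items():
            l1, l2, l3 = map_to_icd(term, schema)
            chain = schema.chain(schema.categories[(level, name)])
            assert l1 == chain[1]
            assert l2 == chain.get(2)
            assert l3 == chain.get(4, chain.get(3))
            if l3 is not None:
                assert l2 is not None
            if l2 is not None:
                assert l1 is not None


class TestSchemaValidation:
    def test_shipped_schema_has_26_level1_categories(self, schema):
        report = validate_schema(schema)
        assert report["level_counts"][1] == 26
        assert report["level_counts"][2] > 0 and report["level_counts"][3] > 0

    def test_orphan_category_rejected(self, tmp_path):
        cats = tmp_path / "categories.tsv"
        cats.write_text("level\tname\tparent\n1\tTop\n3\tLost\tNowhere\n")
        terms = tmp_path / "term_groups.tsv"
        terms.write_text("term\tcategory\nx\tTop\n")
        with pytest.raises(SchemaError):
            load_schema(cats, terms)

    def test_term_collision_rejected(self, tmp_path):
        cats = tmp_path / "categories.tsv"
        cats.write_text("level\tname\tparent\n1\tA\n1\tB\n")
        terms = tmp_path / "term_groups.tsv"
        terms.write_text("term\tcategory\nx\tA\nx\tB\n")
        with pytest.raises(SchemaError, match="two categories"):
            load_schema(cats, terms)


def rec(event, narr, role, canonical, level1="Mood (affective) disorders"):
    return DisorderRecord(event, narr, role, canonical, level1)


class TestDeduplicate:
    def test_same_canonical_collapses_within_narrative(self):
        records = [
            rec("E1", "N1", "POI", "Depression"),
            rec("E1", "N1", "POI", "Depression"),
            rec("E1", "N1", "POI", "depression"),
        ]
        (ext,) = deduplicate(records)
        assert len(ext.records) == 1

    def test_both_roles_set_both_flag(self):
        records = [
            rec("E1", "N1", "POI", "Schizophrenia"),
            rec("E1", "N1", "victim", "Depression"),
        ]
        (ext,) = deduplicate(records)
        assert ext.poi_any and ext.victim_any and ext.both

    def test_empty_input(self):
        assert deduplicate([]) == []

    def test_event_grouping_unions_across_narratives(self):
        records = [
            rec("E1", "N1", "POI", "Depression"),
            rec("E1", "N2", "POI", "Depression"),
        ]
        (narr_ext,) = deduplicate(records, grouping="narrative")
        (event_ext,) = deduplicate(records, grouping="event")
        assert len(narr_ext.records) == 2
        assert len(event_ext.records) == 1

    def test_idempotent(self):
        records = [
            rec("E1", "N1", "POI", "Depression"),
            rec("E1", "N1", "POI", "Anxiety"),
            rec("E2", "N3", "victim", "Depression"),
        ]
        once = deduplicate(records)
        again = deduplicate([r for e in once for r in e.records])
        assert once == again

    def test_dedup_preserves_distinct_role_level1_pairs(self):
        records = [
            rec("E1", "N1", "POI", "Depression"),
            rec("E1", "N1", "POI", "Depression"),
            rec("E1", "N1", "victim", "Self-harm", "Intentional self-harm"),
        ]
        pairs_before = {(r.role, r.level1) for r in records}
        pairs_after = {(r.role, r.level1) for e in deduplicate(records) for r in e.records}
        assert pairs_before == pairs_after
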