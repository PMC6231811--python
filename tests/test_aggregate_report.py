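import pytest

from dvmh.aggregate_report import (
    EvalCounts, absolute_agreement, evaluate, f_score, metrics_from_counts,
    percentage, precision, recall, round_half_up, summarize,
)
from dvmh.errors import InputError, UndefinedMetricError
from dvmh.icd_mapper import DisorderRecord, deduplicate


class TestMetricArithmetic:
    def test_precision_example(self):
        assert round_half_up(precision(27, 4)) == 87.1

    def test_recall_example(self):
        assert round_half_up(recall(164, 44)) == 78.8

    def test_f_score_example(self):
        assert round_half_up(f_score(88.9, 90.2)) == 89.5

    @pytest.mark.parametrize("x", [1.0, 50.0, 87.1, 100.0])
    def test_f_score_fixed_point(self, x):
        assert f_score(x, x) == pytest.approx(x)

    def test_f_score_symmetric(self):
        assert f_score(70.0, 90.0) == pytest.approx(f_score(90.0, 70.0))

    def test_f_between_p_and_r(self):
        p, r = 97.5, 78.5
        f = f_score(p, r)
        assert min(p, r) <= f <= max(p, r)

    def test_monotonicity_in_errors(self):
        assert precision(50, 10) > precision(50, 11)
        assert recall(50, 10) > recall(50, 11)

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            precision(0, 0)
        with pytest.raises(UndefinedMetricError):
            recall(0, 0)
        with pytest.raises(UndefinedMetricError):
            f_score(0.0, 0.0)

    def test_round_half_up_not_bankers(self):
        assert round_half_up(87.05, 1) == 87.1
        assert round_half_up(0.125, 2) == 0.13


def triple(narr, role, canonical, event=None):
    return (event or narr.split("-")[0], narr, role, canonical)


class TestEvaluate:
    def test_identical_sets_are_perfect(self):
        gold = [triple(f"E{i}-1", "POI", f"d{i}") for i in range(10)]
        res = evaluate(gold, gold)
        m = res["POI"]["metrics"]
        assert (m.precision, m.recall, m.f_score) == (100.0, 100.0, 100.0)

    def test_partial_overlap_counts(self):
        gold = [triple("E1-1", "POI", c) for c in "ABC"]
        pred = [triple("E1-1", "POI", c) for c in "ABD"]
        res = evaluate(gold, pred)
        c = res["POI"]["counts"]
        assert (c.tp, c.fp, c.fn) == (2, 1, 1)
        m = res["POI"]["metrics"].rounded()
        assert m["precision"] == 66.7 and m["recall"] == 66.7

    def test_empty_prediction_undefined_precision_zero_recall(self):
        gold = [triple("E1-1", "victim", "Depression")]
        res = evaluate(gold, [])
        m = res["victim"]["metrics"]
        assert m.precision is None
        assert m.recall == 0.0

    def test_swapping_gold_and_predicted_swaps_p_and_r(self):
        gold = [triple("E1-1", "POI", c) for c in "ABCDE"]
        pred = [triple("E1-1", "POI", c) for c in "ABX"]
        fwd = evaluate(gold, pred)["POI"]["metrics"]
        rev = evaluate(pred, gold)["POI"]["metrics"]
        assert fwd.precision == pytest.approx(rev.recall)
        assert fwd.recall == pytest.approx(rev.precision)

    def test_mismatched_event_ids_rejected(self):
        gold = [("E1", "N1", "POI", "A")]
        pred = [("E2", "N1", "POI", "A")]
        with pytest.raises(InputError):
            evaluate(gold, pred)


class TestAbsoluteAgreement:
    def test_identical_sets(self):
        a = [triple("E1-1", "POI", "x")]
        assert absolute_agreement(a, a) == 100.0

    def test_eight_of_ten(self):
        a = [triple("E1-1", "POI", c) for c in "ABCDEFGHI"]
        b = [triple("E1-1", "POI", c) for c in "ABCDEFGHJ"]
        assert absolute_agreement(a, b) == pytest.approx(80.0)

    def test_disjoint_sets(self):
        a = [triple("E1-1", "POI", "x")]
        b = [triple("E1-1", "POI", "y")]
        assert absolute_agreement(a, b) == 0.0

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            absolute_agreement([], [])


def rec(event, narr, role, canonical, l1, l2=None, l3=None):
    return DisorderRecord(event, narr, role, canonical, l1, l2, l3)


class TestSummarize:
    def make_extractions(self):
        records = [
            rec("E1", "E1-1", "POI", "Depression", "Mood (affective) disorders",
                "Major depressive disorder, single episode"),
            rec("E2", "E2-1", "POI", "Self-harm", "Intentional self-harm"),
            rec("E2", "E2-1", "victim", "Anxiety",
                "Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders",
                "Other anxiety disorders"),
        ]
        return deduplicate(records)

    def test_role_flags_and_event_counts(self):
        s = summarize(self.make_extractions(), 10)
        assert s.n_events_with_mention == 2
        assert (s.n_events_poi_only, s.n_events_victim_only, s.n_events_both) == (1, 0, 1)

    def test_counts_close_under_role_level_totals(self):
        s = summarize(self.make_extractions(), 10)
        for level in (1, 2, 3):
            for role in ("POI", "victim"):
                cats = s.counts.get((level, role), {})
                assert sum(cats.values()) == s.role_level_total(level, role)
        # record lacking level 2 contributes to level 1 only
        assert s.role_level_total(1, "POI") == 2
        assert s.role_level_total(2, "POI") == 1
        assert s.role_level_total(3, "POI") == 0

    def test_percentages_sum_to_100(self):
        s = summarize(self.make_extractions(), 10)
        total = sum(s.percentages(1, "POI").values())
        assert total == pytest.approx(100.0, abs=0.26)

    def test_empty_extractions(self):
        s = summarize([], 5)
        assert s.n_events_with_mention == 0
        assert s.percentages(1, "POI") == {}

    def test_total_smaller_than_observed_rejected(self):
        with pytest.raises(InputError):
            summarize(self.make_extractions(), 1)

    def test_percentage_helper(self):
        assert percentage(5111, 77995) == 6.55
        with pytest.raises(UndefinedMetricError):
            percentage(1, 0)
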