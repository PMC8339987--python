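import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctstage.corpus import EntityMention
from ctstage.evaluate import (
    answer_metrics,
    cohen_kappa,
    ner_metrics,
    rc_metrics,
    render_table,
)
from ctstage.schema import AnswerSet, EntityType, RelationType


def _m(etype, start, end, mid="T1"):
    return EntityMention(mid, etype, start, end, "x" * (end - start))


class TestNerMetrics:
    def test_identical_sets_all_100(self):
        gold = [_m(EntityType.MASS, 0, 3), _m(EntityType.SIZE, 5, 8, "T2")]
        for scheme in ("exact", "inexact"):
            rep = ner_metrics({"d": gold}, {"d": list(gold)}, scheme)
            assert rep.micro == rep.macro
            assert rep.micro.f1 == 100.0

    def test_partial_span_exact_miss_inexact_hit(self):
        # prediction covers 2 of 3 gold characters
        gold = {"d": [_m(EntityType.LOCATION, 0, 3)]}
        pred = {"d": [_m(EntityType.LOCATION, 0, 2)]}
        exact = ner_metrics(gold, pred, "exact").per_class["Location"]
        inexact = ner_metrics(gold, pred, "inexact").per_class["Location"]
        assert exact.precision == 0.0 and exact.recall == 0.0
        assert inexact.precision == 100.0 and inexact.recall == 100.0

    def test_two_partials_give_200_percent_inexact_recall(self):
        gold = {"d": [_m(EntityType.LYMPH_NODE, 0, 6)]}
        pred = {
            "d": [
                _m(EntityType.LYMPH_NODE, 0, 2, "P1"),
                _m(EntityType.LYMPH_NODE, 3, 6, "P2"),
            ]
        }
        rep = ner_metrics(gold, pred, "inexact").per_class["LymphNode"]
        assert rep.recall == 200.0
        assert rep.precision == 100.0

    def test_type_mismatch_never_matches(self):
        gold = {"d": [_m(EntityType.MASS, 0, 3)]}
        pred = {"d": [_m(EntityType.SIZE, 0, 3)]}
        for scheme in ("exact", "inexact"):
            rep = ner_metrics(gold, pred, scheme)
            assert rep.per_class["Mass"].recall == 0.0
            assert rep.per_class["Size"].precision == 0.0

    def test_duplicate_predictions_matched_one_to_one_exact(self):
        gold = {"d": [_m(EntityType.MASS, 0, 3)]}
        pred = {"d": [_m(EntityType.MASS, 0, 3, "P1"), _m(EntityType.MASS, 0, 3, "P2")]}
        rep = ner_metrics(gold, pred, "exact").per_class["Mass"]
        assert rep.precision == 50.0 and rep.recall == 100.0

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            ner_metrics({}, {}, "fuzzy")

    def test_document_set_mismatch(self):
        with pytest.raises(ValueError):
            ner_metrics({"a": []}, {"b": []})

    def test_order_invariance(self, docs200):
        gold = {d.report.doc_id: d.mentions for d in docs200[:10]}
        pred = {d.report.doc_id: list(reversed(d.mentions[:-1])) for d in docs200[:10]}
        a = ner_metrics(gold, pred, "exact")
        b = ner_metrics(gold, {k: list(reversed(v)) for k, v in pred.items()}, "exact")
        assert a == b

    @staticmethod
    def _random_mentions(rng, n):
        out = []
        for i in range(n):
            s = int(rng.integers(0, 40))
            e = s + int(rng.integers(1, 6))
            et = list(EntityType)[int(rng.integers(14))]
            out.append(_m(et, s, e, f"M{i}"))
        return out

    def test_inexact_dominates_exact_on_arbitrary_sets(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            gold = {"d": self._random_mentions(rng, int(rng.integers(0, 10)))}
            pred = {"d": self._random_mentions(rng, int(rng.integers(0, 10)))}
            exact = ner_metrics(gold, pred, "exact")
            inexact = ner_metrics(gold, pred, "inexact")
            for cls in exact.per_class:
                assert inexact.per_class[cls].precision >= exact.per_class[cls].precision
                assert inexact.per_class[cls].recall >= exact.per_class[cls].recall


class TestRcMetrics:
    def test_all_correct(self):
        labels = [RelationType.AT, RelationType.NEGATE, RelationType.NO_RELATION]
        rep = rc_metrics(labels, list(labels))
        assert rep.micro.f1 == 100.0 and rep.macro.f1 == 100.0

    def test_macro_is_mean_of_per_class_f1(self):
        gold = [RelationType.AT] * 2 + [RelationType.SIZE_OF] * 2 + [
            RelationType.RELATED,
            RelationType.NEGATE,
            RelationType.NO_RELATION,
        ]
        pred = list(gold)
        pred[0] = RelationType.NO_RELATION  # one At fully... partially wrong
        rep = rc_metrics(gold, pred)
        expected_macro = np.mean([rep.per_class[r.value].f1 for r in RelationType])
        assert rep.macro.f1 == pytest.approx(expected_macro)

    def test_micro_p_equals_micro_r_single_label_per_pair(self):
        rng = np.random.default_rng(1)
        labels = list(RelationType)
        gold = [labels[int(rng.integers(5))] for _ in range(100)]
        pred = [labels[int(rng.integers(5))] for _ in range(100)]
        rep = rc_metrics(gold, pred)
        assert rep.micro.precision == pytest.approx(rep.micro.recall)

    def test_universe_mismatch(self):
        with pytest.raises(ValueError):
            rc_metrics([RelationType.AT], [])


class TestAnswerMetrics:
    def _answers(self, over=None):
        base = {q: False for q in range(1, 20)}
        base[1] = True
        base[2] = 25.0
        base[20] = None
        base[21] = None
        base[22] = None
        base.update(over or {})
        return AnswerSet(base)

    def test_identical_sets_100(self):
        gold = {f"d{i}": self._answers() for i in range(4)}
        rep = answer_metrics(gold, dict(gold))
        assert rep.micro.f1 == 100.0

    def test_one_missed_yes_among_5_gives_recall_80(self):
        gold = {f"d{i}": self._answers({12: True}) for i in range(5)}
        pred = {f"d{i}": self._answers({12: i > 0}) for i in range(5)}
        rep = answer_metrics(gold, pred)
        assert rep.per_class["Q12"].recall == 80.0

    def test_numeric_off_by_any_margin_is_wrong(self):
        gold = {"d": self._answers({2: 25.0})}
        pred = {"d": self._answers({2: 25.1})}
        rep = answer_metrics(gold, pred)
        assert rep.per_class["Q2"].f1 == 0.0

    def test_text_exact_match_required(self):
        gold = {"d": self._answers({20: "边缘见毛刺"})}
        assert answer_metrics(gold, {"d": self._answers({20: "边缘毛刺"})}).per_class["Q20"].f1 == 0.0
        assert answer_metrics(gold, {"d": self._answers({20: "边缘见毛刺"})}).per_class["Q20"].f1 == 100.0


class TestKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(list("aabbc"), list("aabbc")) == 1.0

    def test_constant_identical_raters(self):
        assert cohen_kappa(["x"] * 10, ["x"] * 10) == 1.0

    def test_hand_built_confusion_kappa_0_8(self):
        # 2x2 confusion a=45, b=5, c=5, d=45 -> p_o=.9, p_e=.5, kappa=.8
        a = ["P"] * 50 + ["N"] * 50
        b = ["P"] * 45 + ["N"] * 5 + ["P"] * 5 + ["N"] * 45
        assert cohen_kappa(a, b) == pytest.approx(0.8)

    def test_independent_random_near_zero(self):
        rng = np.random.default_rng(2718)
        n = 10_000
        a = rng.integers(0, 2, n).tolist()
        b = rng.integers(0, 2, n).tolist()
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_range_bounds(self):
        assert cohen_kappa(["a", "b"], ["b", "a"]) >= -1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 2])

    @given(st.lists(st.sampled_from("abc"), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_kappa_in_unit_interval(self, labels):
        assert -1.0 - 1e-9 <= cohen_kappa(labels, labels[::-1]) <= 1.0 + 1e-9


class TestFormatting:
    def test_micro_f1_is_harmonic_mean(self):
        gold = {"d": [_m(EntityType.MASS, 0, 3)]}
        pred = {"d": [_m(EntityType.MASS, 0, 3, "P1"), _m(EntityType.MASS, 5, 7, "P2")]}
        rep = ner_metrics(gold, pred, "exact")
        p, r = rep.micro.precision, rep.micro.recall
        assert rep.micro.f1 == pytest.approx(2 * p * r / (p + r))

    def test_render_table_layout(self):
        rep = rc_metrics([RelationType.AT], [RelationType.AT])
        table = render_table(rep)
        lines = table.strip().splitlines()
        assert lines[0].split("\t") == ["class", "precision", "recall", "f1"]
        assert lines[-1].startswith("micro\t")
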