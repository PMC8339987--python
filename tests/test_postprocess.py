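import numpy as np
import pytest

from ctstage.corpus import EntityMention, RelationMention
from ctstage.errors import SizeParseError
from ctstage.postprocess import (
    Finding,
    FindingGraph,
    ParsedLocation,
    answer_document,
    answer_questions,
    assemble_findings,
    parse_location,
    parse_size,
    read_answers,
    select_primary_tumor,
    write_answers,
)
from ctstage.schema import AnswerSet, EntityType, RelationType


class TestParseSize:
    def test_cm_pair(self):
        s = parse_size("25×22 cm")
        assert s.dims_mm == (250.0, 220.0) and s.greatest_mm == 250.0

    def test_malformed_unit_defaults_to_mm(self):
        s = parse_size("14×12m")
        assert s.dims_mm == (14.0, 12.0) and s.greatest_mm == 14.0

    def test_single_dimension(self):
        assert parse_size("8mm").greatest_mm == 8.0

    def test_decimal_cm(self):
        assert parse_size("2.3×1.8cm").dims_mm == (23.0, 18.0)

    def test_asterisk_and_x_separators(self):
        assert parse_size("10x8mm").dims_mm == (10.0, 8.0)
        assert parse_size("10*8mm").dims_mm == (10.0, 8.0)

    def test_no_number_raises(self):
        with pytest.raises(SizeParseError):
            parse_size("大小不详")


class TestParseLocation:
    def test_partial_span_keeps_key_characters(self):
        loc = parse_location("右肺下叶基")
        assert loc.side == "right" and loc.lobe == "lower"

    def test_worked_example(self):
        loc = parse_location("左肺门及纵隔4、5组")
        assert loc.side == "left"
        assert loc.regions >= {"hilar", "mediastinal"}
        assert loc.stations == {4, 5}

    def test_no_cues_all_unknown(self):
        loc = parse_location("实性")
        assert loc.side == "unknown" and loc.lobe == "unknown"
        assert not loc.regions and not loc.stations

    def test_bilateral(self):
        assert parse_location("双肺").side == "bilateral"
        assert parse_location("左右肺").side == "bilateral"

    def test_supraclavicular_shang_is_not_a_lobe(self):
        loc = parse_location("左锁骨上")
        assert loc.lobe == "unknown"
        assert loc.regions == {"supraclavicular"}

    def test_station_implies_region(self):
        loc = parse_location("纵隔7组")
        assert "subcarinal" in loc.regions and 7 in loc.stations


def _make_doc_mentions():
    # 左肺门及纵隔4、5组见肿大淋巴结，较大约14×12mm
    text = "左肺门及纵隔4、5组见肿大淋巴结，较大约14×12mm"
    mentions = [
        EntityMention("T1", EntityType.LOCATION, 0, 10, text[0:10]),
        EntityMention("T2", EntityType.LYMPH_NODE, 11, 16, text[11:16]),
        EntityMention("T3", EntityType.SIZE, 20, 27, text[20:27]),
    ]
    relations = [
        RelationMention(RelationType.AT, "T1", "T2"),
        RelationMention(RelationType.SIZE_OF, "T3", "T2"),
    ]
    return mentions, relations


class TestAssemble:
    def test_worked_example_node_with_location_and_size(self):
        mentions, relations = _make_doc_mentions()
        graph = assemble_findings(mentions, relations)
        assert len(graph.nodes) == 1
        node = graph.nodes[0]
        assert node.side == "left" and "mediastinal" in node.regions
        assert node.size.greatest_mm == 14.0
        assert graph.attachment_count == 2

    def test_negate_sets_flag(self):
        mentions = [
            EntityMention("T1", EntityType.NEGATION, 0, 2, "未见"),
            EntityMention("T2", EntityType.EFFUSION, 2, 6, "胸腔积液"),
        ]
        relations = [RelationMention(RelationType.NEGATE, "T1", "T2")]
        graph = assemble_findings(mentions, relations)
        (eff,) = graph.of_kind(EntityType.EFFUSION)
        assert eff.negated is True

    def test_triple_count_conservation(self, docs200):
        for doc in docs200:
            graph = assemble_findings(doc.mentions, doc.relations)
            assert graph.attachment_count == len(doc.relations)


def _mass(order, size=None, negated=False, side="right", lobe="lower", **kw):
    f = Finding(
        kind=EntityType.MASS,
        mention_id=f"T{order}",
        surface="肿物",
        order=order,
        negated=negated,
        **kw,
    )
    if size is not None:
        from ctstage.postprocess import ParsedSize

        f.size = ParsedSize(dims_mm=(float(size),), greatest_mm=float(size))
    if side or lobe:
        f.locations.append(ParsedLocation(side=side, lobe=lobe))
    return f


class TestPrimarySelection:
    def test_largest_wins(self):
        graph = FindingGraph(findings=[_mass(1, 8), _mass(2, 25)])
        assert select_primary_tumor(graph).mention_id == "T2"

    def test_single_mass(self):
        graph = FindingGraph(findings=[_mass(1, 10)])
        assert select_primary_tumor(graph).mention_id == "T1"

    def test_sizeless_falls_back_to_first(self):
        graph = FindingGraph(findings=[_mass(2), _mass(1)])
        assert select_primary_tumor(graph).mention_id == "T1"

    def test_only_negated_masses_gives_none_and_q1_no(self):
        graph = FindingGraph(findings=[_mass(1, 20, negated=True)])
        assert select_primary_tumor(graph) is None
        assert answer_questions(graph)[1] is False


def _node(order, side, regions):
    f = Finding(
        kind=EntityType.LYMPH_NODE,
        mention_id=f"N{order}",
        surface="肿大淋巴结",
        order=order,
    )
    f.locations.append(
        ParsedLocation(side=side, regions=frozenset(regions))
    )
    return f


class TestAnswerQuestions:
    def test_empty_graph(self):
        ans = answer_questions(FindingGraph())
        assert ans[1] is False and ans[2] is None
        assert all(ans[q] is False for q in range(3, 20))
        assert ans[20] is None

    def test_ipsilateral_vs_contralateral(self):
        graph = FindingGraph(
            findings=[_mass(1, 25, side="right"), _node(2, "left", {"mediastinal"})]
        )
        ans = answer_questions(graph)
        assert ans[12] is False and ans[14] is True

    def test_q2_is_primary_greatest_dimension(self):
        graph = FindingGraph(findings=[_mass(1, 25), _mass(2, 8)])
        assert answer_questions(graph)[2] == 25.0

    def test_subcarinal_side_agnostic(self):
        graph = FindingGraph(
            findings=[_mass(1, 25, side="right"), _node(2, "left", {"subcarinal"})]
        )
        assert answer_questions(graph)[13] is True

    def test_no_primary_side_dependent_answered_no(self, caplog):
        graph = FindingGraph(findings=[_node(1, "left", {"mediastinal"})])
        with caplog.at_level("WARNING"):
            ans = answer_questions(graph)
        assert ans[12] is False and ans[14] is False
        assert any("relative position" in r.message for r in caplog.records)

    def test_gold_annotations_match_oracle(self, corpus200):
        mismatches = 0
        for g in corpus200:
            if answer_document(g.document) != g.answers:
                mismatches += 1
        assert mismatches == 0


class TestAnswerIO:
    def test_round_trip(self, corpus200):
        answers = {
            g.document.report.doc_id: dict(g.answers.items()) for g in corpus200[:20]
        }
        text = write_answers(answers)
        back = read_answers(text)
        for doc_id, ans in answers.items():
            assert back[doc_id] == AnswerSet(ans)


def _random_graph(rng) -> FindingGraph:
    findings = []
    order = 1
    findings.append(_mass(order, int(rng.integers(15, 40))))
    order += 1
    for _ in range(int(rng.integers(0, 3))):
        findings.append(
            _mass(
                order,
                int(rng.integers(3, 12)) if rng.random() < 0.6 else None,
                side=str(rng.choice(["left", "right"])),
                lobe=str(rng.choice(["upper", "middle", "lower"])),
                negated=bool(rng.random() < 0.2),
            )
        )
        order += 1
    for _ in range(int(rng.integers(0, 3))):
        findings.append(
            _node(
                order,
                str(rng.choice(["left", "right", "unknown"])),
                {
                    str(
                        rng.choice(
                            ["hilar", "mediastinal", "subcarinal", "supraclavicular"]
                        )
                    )
                },
            )
        )
        findings[-1].negated = bool(rng.random() < 0.3)
        order += 1
    for kind in (
        EntityType.BRONCHUS,
        EntityType.PLEURA,
        EntityType.VESSEL,
        EntityType.EFFUSION,
        EntityType.PAOP,
    ):
        if rng.random() < 0.4:
            f = Finding(
                kind=kind,
                mention_id=f"T{order}",
                surface="胸膜结节" if kind is EntityType.PLEURA and rng.random() < 0.5 else "所见",
                order=order,
                negated=bool(rng.random() < 0.3),
            )
            if kind is EntityType.PAOP and rng.random() < 0.5:
                f.locations.append(ParsedLocation(regions=frozenset({"hilar"})))
            findings.append(f)
            order += 1
    return FindingGraph(findings=findings)


BOOL_QUESTIONS = [q for q in range(1, 20) if q != 2]


class TestMutationProperties:
    """Negation dominance and monotonicity over randomized graphs.

    Mutations never touch the primary tumor (negating it or outgrowing it
    re-anchors every laterality question, which is a re-interpretation of the
    report, not a monotone evidence change).
    """

    def test_negation_dominance_1000_mutations(self):
        rng = np.random.default_rng(123)
        done = 0
        while done < 1000:
            graph = _random_graph(rng)
            primary = select_primary_tumor(graph)
            candidates = [
                f
                for f in graph.findings
                if not f.negated
                and (primary is None or f.mention_id != primary.mention_id)
            ]
            if not candidates:
                continue
            before = answer_questions(graph)
            victim = candidates[int(rng.integers(len(candidates)))]
            victim.negated = True  # simulate an added Negate triple
            after = answer_questions(graph)
            victim.negated = False
            for q in BOOL_QUESTIONS:
                if before[q] is False:
                    assert after[q] is False, f"Q{q} flipped No->Yes after negation"
            done += 1

    def test_monotonicity_1000_added_findings(self):
        rng = np.random.default_rng(321)
        done = 0
        while done < 1000:
            graph = _random_graph(rng)
            before = answer_questions(graph)
            primary = select_primary_tumor(graph)
            # add a supporting finding that cannot usurp the primary
            kind = rng.choice(
                [
                    "node",
                    "satellite",
                    "effusion",
                    "bronchus",
                    "pleura_nodule",
                ]
            )
            order = len(graph.findings) + 10
            if kind == "node":
                extra = _node(order, str(rng.choice(["left", "right"])), {"mediastinal"})
            elif kind == "satellite":
                cap = int(primary.size.greatest_mm) if primary and primary.size else 10
                extra = _mass(
                    order,
                    max(2, min(9, cap - 1)),
                    side=str(rng.choice(["left", "right"])),
                    lobe=str(rng.choice(["upper", "lower"])),
                )
            elif kind == "effusion":
                extra = Finding(
                    kind=EntityType.EFFUSION, mention_id=f"T{order}", surface="胸腔积液", order=order
                )
            elif kind == "bronchus":
                extra = Finding(
                    kind=EntityType.BRONCHUS, mention_id=f"T{order}", surface="支气管狭窄", order=order
                )
            else:
                extra = Finding(
                    kind=EntityType.PLEURA, mention_id=f"T{order}", surface="胸膜结节", order=order
                )
            graph.findings.append(extra)
            after = answer_questions(graph)
            graph.findings.pop()
            for q in BOOL_QUESTIONS:
                if before[q] is True:
                    assert after[q] is True, f"Q{q} flipped Yes->No after adding support"
            done += 1
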