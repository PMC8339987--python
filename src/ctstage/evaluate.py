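"""Metric suite: per-class precision/recall/F1 with macro and micro averages
for NER (exact and inexact span matching), relation classification, and
question answering, plus Cohen's kappa for inter-annotator agreement.

All values are reported on the 0-100 scale.

Inexact NER matching counts a prediction as correct when it overlaps (shares
at least one character with) any same-type gold mention; the recall numerator
counts every such predicted match without deduplicating gold mentions, so
inexact recall can legitimately exceed 100% when several partial predictions
cover one gold mention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .schema import AnswerSet, EntityType, RelationType, load_questions

__all__ = [
    "PRF",
    "MetricReport",
    "ner_metrics",
    "rc_metrics",
    "answer_metrics",
    "cohen_kappa",
    "render_table",
]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MetricReport:
    per_class: dict
    macro: PRF
    micro: PRF


def _prf(tp: float, n_pred: float, n_gold: float) -> PRF:
    if n_pred == 0 and n_gold == 0:
        return PRF(100.0, 100.0, 100.0)  # identical-empty convention
    p = 100.0 * tp / n_pred if n_pred else 0.0
    r = 100.0 * tp / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return PRF(p, r, f1)


def _aggregate(counts: Mapping) -> MetricReport:
    """counts: class -> (tp, n_pred, n_gold)."""
    per_class = {c: _prf(*counts[c]) for c in counts}
    names = sorted(per_class)
    macro = PRF(
        sum(per_class[c].precision for c in names) / len(names),
        sum(per_class[c].recall for c in names) / len(names),
        sum(per_class[c].f1 for c in names) / len(names),
    )
    tp = sum(counts[c][0] for c in names)
    n_pred = sum(counts[c][1] for c in names)
    n_gold = sum(counts[c][2] for c in names)
    return MetricReport(per_class=per_class, macro=macro, micro=_prf(tp, n_pred, n_gold))


# ---------------------------------------------------------------------------
# NER
# ---------------------------------------------------------------------------


def _as_doc_map(obj) -> dict:
    if isinstance(obj, Mapping):
        return dict(obj)
    return {"<doc>": obj}


def ner_metrics(gold, pred, scheme: str = "exact") -> MetricReport:
    """Span-level NER metrics under the exact or inexact matching scheme.

    ``gold`` and ``pred`` are mappings ``doc_id -> sequence of EntityMention``
    (or bare mention sequences for a single document) using document offsets.

    exact: a prediction is correct iff its type and span match a gold mention
    exactly, matched one-to-one greedily in document order.  inexact: every
    prediction overlapping any same-type gold mention counts as a match, with
    no gold deduplication on the recall side.
    """
    if scheme not in ("exact", "inexact"):
        raise ValueError(f"unknown scheme {scheme!r}")
    gold_map, pred_map = _as_doc_map(gold), _as_doc_map(pred)
    if set(gold_map) != set(pred_map):
        raise ValueError("gold and pred cover different document sets")
    counts = {et.value: [0, 0, 0] for et in EntityType}
    for doc_id in sorted(gold_map):
        gms = list(gold_map[doc_id])
        pms = list(pred_map[doc_id])
        for et in EntityType:
            c = counts[et.value]
            g = sorted((m.start, m.end) for m in gms if m.etype is et)
            p = sorted((m.start, m.end) for m in pms if m.etype is et)
            c[1] += len(p)
            c[2] += len(g)
            if scheme == "exact":
                c[0] += sum((Counter(g) & Counter(p)).values())
            else:
                for ps, pe in p:
                    if any(ps < ge and gs < pe for gs, ge in g):
                        c[0] += 1
    return _aggregate(counts)


# ---------------------------------------------------------------------------
# RC
# ---------------------------------------------------------------------------


def rc_metrics(gold: Sequence, pred: Sequence) -> MetricReport:
    """Five-class relation metrics over a shared candidate-pair universe."""
    if len(gold) != len(pred):
        raise ValueError("gold and pred universes differ in size")
    counts = {r.value: [0, 0, 0] for r in RelationType}
    for g, p in zip(gold, pred):
        g, p = RelationType(g), RelationType(p)
        counts[p.value][1] += 1
        counts[g.value][2] += 1
        if g is p:
            counts[g.value][0] += 1
    return _aggregate(counts)


# ---------------------------------------------------------------------------
# QA
# ---------------------------------------------------------------------------


def _answer_match(a, b) -> bool:
    if isinstance(a, bool) or isinstance(b, bool):
        return a is b
    return a == b


def answer_metrics(gold, pred) -> MetricReport:
    """Per-question P/R/F1 over a report set.

    A positive is a Yes (boolean), or a present value (numeric/text); numeric
    and text answers must match exactly to count as true positives.
    """
    gold_map, pred_map = _as_doc_map(gold), _as_doc_map(pred)
    if set(gold_map) != set(pred_map):
        raise ValueError("gold and pred cover different report sets")
    questions = load_questions()
    counts = {f"Q{q.id}": [0, 0, 0] for q in questions}
    for doc_id in sorted(gold_map):
        g_ans: AnswerSet = gold_map[doc_id]
        p_ans: AnswerSet = pred_map[doc_id]
        for q in questions:
            c = counts[f"Q{q.id}"]
            g = g_ans.answers.get(q.id)
            p = p_ans.answers.get(q.id)
            g_pos = g is True if q.answer_type == "boolean" else g is not None
            p_pos = p is True if q.answer_type == "boolean" else p is not None
            if p_pos:
                c[1] += 1
            if g_pos:
                c[2] += 1
            if g_pos and p_pos and (q.answer_type == "boolean" or _answer_match(g, p)):
                c[0] += 1
    return _aggregate(counts)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) in [-1, 1].

    Defined as 1.0 when both raters are constant and identical (p_e = 1).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label sequences")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def render_table(report: MetricReport, title: str = "class") -> str:
    """Delimited text table mirroring the per-class + macro/micro layout."""
    lines = [f"{title}\tprecision\trecall\tf1"]
    for name, prf in sorted(report.per_class.items()):
        lines.append(f"{name}\t{prf.precision:.2f}\t{prf.recall:.2f}\t{prf.f1:.2f}")
    lines.append(
        f"macro\t{report.macro.precision:.2f}\t{report.macro.recall:.2f}\t{report.macro.f1:.2f}"
    )
    lines.append(
        f"micro\t{report.micro.precision:.2f}\t{report.micro.recall:.2f}\t{report.micro.f1:.2f}"
    )
    return "\n".join(lines) + "\n"
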