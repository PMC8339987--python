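"""Annotated-corpus I/O: brat standoff read/write, span <-> BIO conversion,
CoNLL export, and deterministic corpus splitting.

Conventions
-----------
* All offsets are 0-based, half-open character offsets into the report text.
* Tokenization is per Unicode character (Chinese clinical text); ASCII
  digit/letter runs are also split per character so labels stay aligned.
* Sentences are split on ``。 ； ; ！ ! ？ ?`` and newlines; delimiters are
  excluded from sentences.
* Entity mentions must fall inside a single sentence, and relations link
  mentions of the same sentence only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AnnotationConflictError,
    CorruptAnnotationError,
    InsufficientDataError,
    SchemaViolationError,
)
from .schema import EntityType, RelationMap, RelationType, admissible_relation

__all__ = [
    "Report",
    "EntityMention",
    "RelationMention",
    "BioSequence",
    "Document",
    "split_sentences",
    "read_brat",
    "write_brat",
    "to_bio",
    "from_bio",
    "to_conll",
    "split_corpus",
]

_SENTENCE_DELIMS = "。；;！!？?\n"


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character intervals of the sentences of ``text`` (delimiters excluded)."""
    spans = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _SENTENCE_DELIMS:
            if i > start:
                spans.append((start, i))
            start = i + 1
    if len(text) > start:
        spans.append((start, len(text)))
    return spans


@dataclass(frozen=True)
class Report:
    doc_id: str
    text: str
    sentence_spans: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.sentence_spans is None:
            object.__setattr__(
                self, "sentence_spans", tuple(split_sentences(self.text))
            )
        else:
            object.__setattr__(self, "sentence_spans", tuple(self.sentence_spans))

    def sentence_text(self, index: int) -> str:
        s, e = self.sentence_spans[index]
        return self.text[s:e]

    def sentence_of(self, start: int, end: int) -> int:
        """Index of the single sentence containing [start, end)."""
        for i, (s, e) in enumerate(self.sentence_spans):
            if start >= s and end <= e:
                return i
        raise AnnotationConflictError(
            f"{self.doc_id}: span [{start},{end}) does not lie within one sentence"
        )


@dataclass(frozen=True)
class EntityMention:
    mention_id: str
    etype: EntityType
    start: int
    end: int
    surface: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise SchemaViolationError(
                f"{self.mention_id}: bad span [{self.start},{self.end})"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RelationMention:
    rtype: RelationType
    arg1: str  # mention_id
    arg2: str  # mention_id

    def __post_init__(self):
        if RelationType(self.rtype) is RelationType.NO_RELATION:
            raise SchemaViolationError("stored relations must be non-null")


@dataclass(frozen=True)
class BioSequence:
    tokens: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.tokens) != len(self.labels):
            raise SchemaViolationError("tokens and labels must have equal length")


@dataclass
class Document:
    """A report together with its (gold or predicted) annotations."""

    report: Report
    mentions: list = field(default_factory=list)
    relations: list = field(default_factory=list)

    def mention_by_id(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def mentions_in_sentence(self, index: int) -> list:
        s, e = self.report.sentence_spans[index]
        return [m for m in self.mentions if m.start >= s and m.end <= e]


# ---------------------------------------------------------------------------
# brat standoff
# ---------------------------------------------------------------------------

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_LINE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")


def read_brat(
    txt_content: str,
    ann_content: str,
    doc_id: str = "doc",
    relation_map: Optional[RelationMap] = None,
) -> Document:
    """Parse a brat ``.txt`` / ``.ann`` pair into a validated :class:`Document`.

    T-lines become entity mentions whose surface is verified against the text
    offsets; R-lines become relation mentions checked against the relation map
    and the same-sentence constraint.
    """
    report = Report(doc_id=doc_id, text=txt_content)
    mentions: dict[str, EntityMention] = {}
    relations: list[RelationMention] = []
    for raw in ann_content.splitlines():
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if not m:
                raise CorruptAnnotationError(f"{doc_id}: unparsable T-line: {line!r}")
            tid, tname, s, e, surface = m.groups()
            try:
                etype = EntityType(tname)
            except ValueError as exc:
                raise SchemaViolationError(
                    f"{doc_id}: unknown entity type in line: {line!r}"
                ) from exc
            start, end = int(s), int(e)
            if txt_content[start:end] != surface:
                raise CorruptAnnotationError(
                    f"{doc_id}: surface/offset mismatch in line: {line!r} "
                    f"(text slice {txt_content[start:end]!r})"
                )
            report.sentence_of(start, end)  # reject cross-sentence entities
            if tid in mentions:
                raise CorruptAnnotationError(f"{doc_id}: duplicate id {tid}")
            mentions[tid] = EntityMention(tid, etype, start, end, surface)
        elif line.startswith("R"):
            m = _R_LINE.match(line)
            if not m:
                raise CorruptAnnotationError(f"{doc_id}: unparsable R-line: {line!r}")
            rid, rname, a1, a2 = m.groups()
            try:
                rtype = RelationType(rname)
            except ValueError as exc:
                raise SchemaViolationError(
                    f"{doc_id}: unknown relation type in line: {line!r}"
                ) from exc
            relations.append(RelationMention(rtype, a1, a2))
        elif line.startswith("#"):
            continue  # comments/notes are ignored
        else:
            raise CorruptAnnotationError(
                f"{doc_id}: unsupported annotation line: {line!r}"
            )
    doc = Document(report=report, mentions=list(mentions.values()), relations=relations)
    _validate_relations(doc, relation_map)
    return doc


def _validate_relations(doc: Document, relation_map: Optional[RelationMap]) -> None:
    by_id = {m.mention_id: m for m in doc.mentions}
    for rel in doc.relations:
        for arg in (rel.arg1, rel.arg2):
            if arg not in by_id:
                raise CorruptAnnotationError(
                    f"{doc.report.doc_id}: relation argument {arg} not defined"
                )
        m1, m2 = by_id[rel.arg1], by_id[rel.arg2]
        if doc.report.sentence_of(m1.start, m1.end) != doc.report.sentence_of(
            m2.start, m2.end
        ):
            raise SchemaViolationError(
                f"{doc.report.doc_id}: cross-sentence relation {rel.arg1}-{rel.arg2}"
            )
        expected = admissible_relation(m1.etype, m2.etype, relation_map)
        if RelationType(rel.rtype) is not expected:
            raise SchemaViolationError(
                f"{doc.report.doc_id}: relation {rel.rtype.value} between "
                f"{m1.etype.value} and {m2.etype.value} violates the relation map "
                f"(admissible: {expected.value})"
            )


def write_brat(doc: Document) -> tuple[str, str]:
    """Serialize a document to a brat ``(txt_content, ann_content)`` pair.

    Output parses back to an equal document (round-trip); mentions are written
    in document order with their existing ids.
    """
    lines = []
    for m in sorted(doc.mentions, key=lambda m: (m.start, m.end, m.mention_id)):
        if doc.report.text[m.start : m.end] != m.surface:
            raise CorruptAnnotationError(
                f"{doc.report.doc_id}: mention {m.mention_id} surface mismatch"
            )
        lines.append(f"{m.mention_id}\t{m.etype.value} {m.start} {m.end}\t{m.surface}")
    for i, rel in enumerate(doc.relations, start=1):
        lines.append(f"R{i}\t{rel.rtype.value} Arg1:{rel.arg1} Arg2:{rel.arg2}")
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return doc.report.text, ann


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------


def to_bio(report: Report, mentions: Sequence, sentence_index: int) -> BioSequence:
    """Character-level BIO labels for one sentence.

    Mentions outside the sentence are ignored; overlapping mentions within the
    sentence raise :class:`AnnotationConflictError`.
    """
    s, e = report.sentence_spans[sentence_index]
    chars = tuple(report.text[s:e])
    labels = ["O"] * len(chars)
    local = sorted(
        (m for m in mentions if m.start >= s and m.end <= e),
        key=lambda m: (m.start, m.end),
    )
    prev_end = -1
    for m in local:
        if m.start < prev_end:
            raise AnnotationConflictError(
                f"{report.doc_id}: overlapping mentions in sentence {sentence_index}"
            )
        prev_end = m.end
        ls, le = m.start - s, m.end - s
        labels[ls] = f"B-{m.etype.value}"
        for i in range(ls + 1, le):
            labels[i] = f"I-{m.etype.value}"
    return BioSequence(tokens=chars, labels=tuple(labels))


def from_bio(bio: BioSequence) -> list[tuple[EntityType, int, int]]:
    """Decode BIO labels into (type, start, end) triples with sentence-local
    offsets.  A stray ``I-x`` with no open ``B-x``/``I-x`` run is repaired to
    ``B-x``; the function is total."""
    out: list[tuple[EntityType, int, int]] = []
    cur_type: Optional[str] = None
    cur_start = 0
    for i, lab in enumerate(bio.labels):
        if lab == "O":
            if cur_type is not None:
                out.append((EntityType(cur_type), cur_start, i))
                cur_type = None
            continue
        prefix, _, tname = lab.partition("-")
        if prefix == "B" or cur_type != tname:
            if cur_type is not None:
                out.append((EntityType(cur_type), cur_start, i))
            cur_type = tname
            cur_start = i
    if cur_type is not None:
        out.append((EntityType(cur_type), cur_start, len(bio.labels)))
    return out


def to_conll(report: Report, mentions: Sequence) -> str:
    """Two-column ``character TAB label`` export, blank line between sentences."""
    blocks = []
    for i in range(len(report.sentence_spans)):
        bio = to_bio(report, mentions, i)
        blocks.append(
            "\n".join(f"{tok}\t{lab}" for tok, lab in zip(bio.tokens, bio.labels))
        )
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# corpus splitting
# ---------------------------------------------------------------------------


def split_corpus(
    corpus: Sequence,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Deterministic report-level split into train/validation/test parts.

    The partition is exhaustive and disjoint; boundaries are placed at rounded
    cumulative fractions of the shuffled corpus.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(corpus)
    if n < 3:
        raise InsufficientDataError(f"cannot 3-way split a corpus of {n} reports")
    order = np.random.default_rng(seed).permutation(n)
    b1 = int(round(fractions[0] * n))
    b2 = int(round((fractions[0] + fractions[1]) * n))
    b1 = min(max(b1, 1), n - 2)
    b2 = min(max(b2, b1 + 1), n - 1)
    idx = [order[:b1], order[b1:b2], order[b2:]]
    return tuple([corpus[i] for i in part] for part in idx)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# corpus directories (<doc_id>.txt + <doc_id>.ann pairs)
# ---------------------------------------------------------------------------


def save_corpus(docs: Iterable, directory) -> None:
    """Write each document as a brat ``.txt``/``.ann`` pair under ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        txt, ann = write_brat(doc)
        (directory / f"{doc.report.doc_id}.txt").write_text(txt, encoding="utf-8")
        (directory / f"{doc.report.doc_id}.ann").write_text(ann, encoding="utf-8")


def load_corpus(directory, relation_map=None) -> list:
    """Read every ``.txt``/``.ann`` pair under ``directory`` (sorted by id)."""
    from pathlib import Path

    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        docs.append(
            read_brat(
                txt_path.read_text(encoding="utf-8"),
                ann,
                doc_id=txt_path.stem,
                relation_map=relation_map,
            )
        )
    return docs
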