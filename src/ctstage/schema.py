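"""Fixed domain knowledge: entity types, relation types, the admissible-relation
map over entity-type pairs, and the 22-question catalogue.

The relation map and the question catalogue ship as versioned YAML data files
(``ctstage/data/``) so that deployments with a different annotation schema can
override them without code changes (see the ``--schema`` CLI flag).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "EntityType",
    "RelationType",
    "RelationMap",
    "Question",
    "AnswerSet",
    "load_questions",
    "admissible_relation",
    "default_relation_map",
]


class EntityType(str, enum.Enum):
    """The 14 annotated entity types."""

    MASS = "Mass"
    LYMPH_NODE = "LymphNode"
    LOCATION = "Location"
    SIZE = "Size"
    NEGATION = "Negation"
    DENSITY = "Density"
    ENHANCEMENT = "Enhancement"
    SHAPE = "Shape"
    BRONCHUS = "Bronchus"
    PLEURA = "Pleura"
    VESSEL = "Vessel"
    VERTEBRAL_BODY = "VertebralBody"
    EFFUSION = "Effusion"
    PAOP = "PAOP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationType(str, enum.Enum):
    """Four non-null relation types plus the null label."""

    AT = "At"
    SIZE_OF = "SizeOf"
    RELATED = "Related"
    NEGATE = "Negate"
    NO_RELATION = "NoRelation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


NON_NULL_RELATIONS = (
    RelationType.AT,
    RelationType.SIZE_OF,
    RelationType.RELATED,
    RelationType.NEGATE,
)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ctstage").joinpath("data", name)))


class SchemaError(ValueError):
    """Raised when a schema data file violates its invariants."""


class RelationMap:
    """Lookup of the single admissible non-null relation per entity-type pair.

    A pair of entity types admits at most one non-null relation; pairs without
    an edge admit only :attr:`RelationType.NO_RELATION`.  The map is symmetric.
    """

    def __init__(self, edges: Mapping[frozenset, RelationType]):
        self._edges: dict[frozenset, RelationType] = {}
        for pair, rtype in edges.items():
            pair = frozenset(EntityType(t) for t in pair)
            rtype = RelationType(rtype)
            if rtype is RelationType.NO_RELATION:
                raise SchemaError("NoRelation cannot be an edge label")
            if pair in self._edges and self._edges[pair] is not rtype:
                raise SchemaError(
                    f"pair {sorted(t.value for t in pair)} mapped to two relations"
                )
            self._edges[pair] = rtype

    def admissible(self, type_a: EntityType, type_b: EntityType) -> RelationType:
        """Return the unique admissible relation for the (unordered) pair."""
        key = frozenset((EntityType(type_a), EntityType(type_b)))
        return self._edges.get(key, RelationType.NO_RELATION)

    def edges(self) -> dict[frozenset, RelationType]:
        return dict(self._edges)

    def __len__(self) -> int:
        return len(self._edges)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RelationMap":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        edges: dict[frozenset, RelationType] = {}
        for rname, pairs in doc["edges"].items():
            rtype = RelationType(rname)
            for a, b in pairs:
                pair = frozenset((EntityType(a), EntityType(b)))
                if pair in edges:
                    raise SchemaError(f"duplicate edge for pair ({a}, {b})")
                edges[pair] = rtype
        return cls(edges)


_DEFAULT_MAP: Optional[RelationMap] = None


def default_relation_map() -> RelationMap:
    """The relation map shipped with the package (cached)."""
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = RelationMap.from_yaml(_data_path("relation_map.yaml"))
    return _DEFAULT_MAP


def admissible_relation(
    type_a: EntityType,
    type_b: EntityType,
    relation_map: Optional[RelationMap] = None,
) -> RelationType:
    """Unique admissible relation for a pair of entity types (symmetric, total)."""
    rmap = relation_map if relation_map is not None else default_relation_map()
    return rmap.admissible(type_a, type_b)


@dataclass(frozen=True)
class Question:
    """One entry of the 22-question catalogue."""

    id: int
    text: str
    answer_type: str  # "boolean" | "numeric" | "text"
    stage_label: Optional[str]  # TNM category, or None for diagnosis-only items

    def __post_init__(self):
        if self.answer_type not in ("boolean", "numeric", "text"):
            raise SchemaError(f"bad answer_type {self.answer_type!r}")


_QUESTIONS_CACHE: dict[str, tuple] = {}


def load_questions(path: Union[str, Path, None] = None) -> tuple:
    """Load the question catalogue (all 22 questions in id order)."""
    p = Path(path) if path is not None else _data_path("questions.yaml")
    key = str(p)
    if key not in _QUESTIONS_CACHE:
        with open(p, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        qs = tuple(
            Question(
                id=int(q["id"]),
                text=str(q["text"]),
                answer_type=str(q["answer_type"]),
                stage_label=q["stage"],
            )
            for q in sorted(doc["questions"], key=lambda q: int(q["id"]))
        )
        ids = [q.id for q in qs]
        if ids != list(range(1, len(qs) + 1)):
            raise SchemaError("question ids must be consecutive from 1")
        _QUESTIONS_CACHE[key] = qs
    return _QUESTIONS_CACHE[key]


Answer = Union[bool, float, str, None]


@dataclass
class AnswerSet:
    """Answers to the question catalogue for one report.

    Boolean questions use ``True``/``False``; numeric/text questions use a
    value or ``None`` when unanswered.
    """

    answers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        by_id = {q.id: q for q in load_questions()}
        for qid, ans in self.answers.items():
            if qid not in by_id:
                raise SchemaError(f"unknown question id {qid}")
            atype = by_id[qid].answer_type
            if atype == "boolean" and not isinstance(ans, (bool,)):
                raise SchemaError(f"question {qid} expects a boolean, got {ans!r}")
            if atype == "numeric" and (
                isinstance(ans, bool)
                or not (ans is None or isinstance(ans, (int, float)))
            ):
                raise SchemaError(f"question {qid} expects a number, got {ans!r}")
            if atype == "text" and not (ans is None or isinstance(ans, str)):
                raise SchemaError(f"question {qid} expects text, got {ans!r}")

    def __getitem__(self, qid: int) -> Answer:
        return self.answers[qid]

    def __len__(self) -> int:
        return len(self.answers)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnswerSet):
            return NotImplemented
        return self.answers == other.answers

    def items(self) -> Iterable:
        return sorted(self.answers.items())
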