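"""Rule engine: assembles (entity, relation, entity) triples into per-report
finding graphs and answers the 22-question catalogue.

The rules reconstruct the published system's post-processing semantics from
the question wording: boolean questions default to No unless a supporting
non-negated finding exists; laterality questions compare parsed node/satellite
locations against the primary tumor's side.  Key characters inside partial
entity spans (e.g. a truncated location still containing 右 and 下) are
sufficient for the location parser, so inexactly extracted entities remain
usable.  Every rule is driven by small keyword tables below, overridable
without touching the control flow.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import SizeParseError
from .corpus import Document, EntityMention, RelationMention
from .schema import AnswerSet, EntityType, RelationType, load_questions

__all__ = [
    "ParsedLocation",
    "ParsedSize",
    "Finding",
    "FindingGraph",
    "parse_size",
    "parse_location",
    "assemble_findings",
    "select_primary_tumor",
    "answer_questions",
    "answer_document",
    "write_answers",
    "read_answers",
]

logger = logging.getLogger(__name__)

# entity types that anchor a finding; the rest attach to them via relations
CORE_TYPES = (
    EntityType.MASS,
    EntityType.LYMPH_NODE,
    EntityType.BRONCHUS,
    EntityType.PLEURA,
    EntityType.VESSEL,
    EntityType.VERTEBRAL_BODY,
    EntityType.EFFUSION,
    EntityType.PAOP,
)

_REGION_KEYWORDS = {
    "肺门": "hilar",
    "纵隔": "mediastinal",
    "隆突下": "subcarinal",
    "锁骨上": "supraclavicular",
}
_STATION_REGIONS = {
    **{1: "supraclavicular"},
    **{s: "mediastinal" for s in (2, 3, 4, 5, 6, 8, 9)},
    **{7: "subcarinal"},
    **{s: "hilar" for s in range(10, 15)},
}
_PLEURAL_NODULE_KEY = "结节"  # distinguishes pleural nodules from invasion
_LOBE_RE = re.compile(r"肺([上中下])|([上中下])(?=叶)")
_STATION_RE = re.compile(r"((?:\d+[、，,]?)+)(?=组)")
_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")
_LOBE_NAME = {"上": "upper", "中": "middle", "下": "lower"}


@dataclass(frozen=True)
class ParsedSize:
    dims_mm: tuple  # one or two positive lengths, millimetres
    greatest_mm: float


@dataclass(frozen=True)
class ParsedLocation:
    side: str = "unknown"  # left | right | bilateral | unknown
    lobe: str = "unknown"  # upper | middle | lower | unknown
    regions: frozenset = frozenset()
    stations: frozenset = frozenset()


def parse_size(text: str) -> ParsedSize:
    """Extract up to two dimensions in millimetres from a size surface.

    ``cm`` multiplies all dimensions by 10; a missing or malformed unit
    (e.g. the real-world typo ``14×12m``) defaults to millimetres.
    """
    nums = _NUMBER_RE.findall(text)
    if not nums:
        raise SizeParseError(f"no parsable number in size surface {text!r}")
    factor = 10.0 if "cm" in text.lower() else 1.0
    dims = tuple(round(float(v) * factor, 4) for v in nums[:2])
    return ParsedSize(dims_mm=dims, greatest_mm=max(dims))


def parse_location(text: str) -> ParsedLocation:
    """Parse side/lobe/nodal-region cues from a (possibly partial) location."""
    has_r, has_l = "右" in text, "左" in text
    if "双" in text or (has_r and has_l):
        side = "bilateral"
    elif has_r:
        side = "right"
    elif has_l:
        side = "left"
    else:
        side = "unknown"
    m = _LOBE_RE.search(text)
    lobe = _LOBE_NAME[m.group(1) or m.group(2)] if m else "unknown"
    regions = {region for key, region in _REGION_KEYWORDS.items() if key in text}
    stations: set[int] = set()
    for group in _STATION_RE.findall(text):
        for num in re.findall(r"\d+", group):
            st = int(num)
            if 1 <= st <= 14:
                stations.add(st)
                regions.add(_STATION_REGIONS[st])
    return ParsedLocation(
        side=side, lobe=lobe, regions=frozenset(regions), stations=frozenset(stations)
    )


@dataclass
class Finding:
    """One core finding with everything attached to it by relations."""

    kind: EntityType
    mention_id: str
    surface: str
    order: int  # document order of the anchoring mention
    locations: list = field(default_factory=list)  # ParsedLocation
    location_surfaces: list = field(default_factory=list)
    size: Optional[ParsedSize] = None
    negated: bool = False
    shapes: list = field(default_factory=list)
    densities: list = field(default_factory=list)
    enhancements: list = field(default_factory=list)
    attached: list = field(default_factory=list)  # other Findings related to a mass

    @property
    def side(self) -> str:
        for loc in self.locations:
            if loc.side != "unknown":
                return loc.side
        return "unknown"

    @property
    def lobe(self) -> str:
        for loc in self.locations:
            if loc.lobe != "unknown":
                return loc.lobe
        return "unknown"

    @property
    def regions(self) -> frozenset:
        out: set = set()
        for loc in self.locations:
            out |= loc.regions
        return frozenset(out)


@dataclass
class FindingGraph:
    findings: list = field(default_factory=list)
    attachment_count: int = 0  # one per input relation (audit invariant)

    def of_kind(self, kind: EntityType, negated: Optional[bool] = None) -> list:
        out = [f for f in self.findings if f.kind is kind]
        if negated is not None:
            out = [f for f in out if f.negated is negated]
        return out

    @property
    def masses(self) -> list:
        return self.of_kind(EntityType.MASS)

    @property
    def nodes(self) -> list:
        return self.of_kind(EntityType.LYMPH_NODE)


_ATTR_FIELD = {
    EntityType.SHAPE: "shapes",
    EntityType.DENSITY: "densities",
    EntityType.ENHANCEMENT: "enhancements",
}


def assemble_findings(
    mentions: Sequence[EntityMention], relations: Sequence[RelationMention]
) -> FindingGraph:
    """Attach locations, sizes, attributes, and negations to core findings.

    ``At`` triples attach locations, ``SizeOf`` sizes, ``Related`` attributes
    or secondary findings (to the mass), and ``Negate`` sets negated flags.
    Every input relation yields exactly one attachment.
    """
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    by_id = {m.mention_id: m for m in ordered}
    findings: dict[str, Finding] = {}
    for order, m in enumerate(ordered):
        if m.etype in CORE_TYPES:
            findings[m.mention_id] = Finding(
                kind=m.etype, mention_id=m.mention_id, surface=m.surface, order=order
            )
    graph = FindingGraph(findings=list(findings.values()))
    for rel in relations:
        m1, m2 = by_id[rel.arg1], by_id[rel.arg2]
        rtype = RelationType(rel.rtype)
        attached = False
        if rtype is RelationType.AT:
            loc, core = (m1, m2) if m1.etype is EntityType.LOCATION else (m2, m1)
            f = findings.get(core.mention_id)
            if f is not None and loc.etype is EntityType.LOCATION:
                f.locations.append(parse_location(loc.surface))
                f.location_surfaces.append(loc.surface)
                attached = True
        elif rtype is RelationType.SIZE_OF:
            size_m, core = (m1, m2) if m1.etype is EntityType.SIZE else (m2, m1)
            f = findings.get(core.mention_id)
            if f is not None and size_m.etype is EntityType.SIZE:
                try:
                    parsed = parse_size(size_m.surface)
                except SizeParseError:
                    logger.warning(
                        "unparsable size %r; question falls back to unanswered",
                        size_m.surface,
                    )
                    parsed = None
                if parsed is not None and (
                    f.size is None or parsed.greatest_mm > f.size.greatest_mm
                ):
                    f.size = parsed
                attached = True
        elif rtype is RelationType.NEGATE:
            neg, core = (m1, m2) if m1.etype is EntityType.NEGATION else (m2, m1)
            f = findings.get(core.mention_id)
            if f is not None and neg.etype is EntityType.NEGATION:
                f.negated = True
                attached = True
        elif rtype is RelationType.RELATED:
            mass, other = (m1, m2) if m1.etype is EntityType.MASS else (m2, m1)
            f = findings.get(mass.mention_id)
            if f is not None and mass.etype is EntityType.MASS:
                if other.etype in _ATTR_FIELD:
                    getattr(f, _ATTR_FIELD[other.etype]).append(other.surface)
                    attached = True
                elif other.mention_id in findings:
                    f.attached.append(findings[other.mention_id])
                    attached = True
        if attached:
            graph.attachment_count += 1
        else:
            logger.warning(
                "relation %s(%s, %s) could not be attached",
                rel.rtype.value,
                rel.arg1,
                rel.arg2,
            )
    return graph


def select_primary_tumor(graph: FindingGraph) -> Optional[Finding]:
    """The non-negated mass with the largest greatest dimension.

    Size-less candidates (or ties) fall back to first mention order; None when
    no non-negated mass exists.
    """
    candidates = graph.of_kind(EntityType.MASS, negated=False)
    if not candidates:
        return None
    sized = [f for f in candidates if f.size is not None]
    if not sized:
        return min(candidates, key=lambda f: f.order)
    best = max(sized, key=lambda f: (f.size.greatest_mm, -f.order))
    return best


def _is_pleural_nodule(f: Finding) -> bool:
    return _PLEURAL_NODULE_KEY in f.surface


def _dedup_join(surfaces: Iterable[str]) -> Optional[str]:
    seen: list[str] = []
    for s in surfaces:
        if s not in seen:
            seen.append(s)
    return "、".join(seen) if seen else None


def answer_questions(graph: FindingGraph) -> AnswerSet:
    """Answer all 22 questions from an assembled finding graph.

    Boolean questions default to No absent supporting non-negated findings;
    laterality questions are answered No (with a logged warning) when the
    primary tumor or its side cannot be determined.
    """
    primary = select_primary_tumor(graph)
    p_side = primary.side if primary is not None else "unknown"
    p_lobe = primary.lobe if primary is not None else "unknown"
    opposite = {"right": "left", "left": "right"}.get(p_side)

    def warn_relative(qid: int) -> bool:
        logger.warning(
            "Q%d: relative position undeterminable (no primary tumor side)", qid
        )
        return False

    def nodes_in(region: str, side: Optional[str] = "any") -> bool:
        for f in graph.of_kind(EntityType.LYMPH_NODE, negated=False):
            if region not in f.regions:
                continue
            if side == "any" or f.side == side:
                return True
        return False

    satellites = [
        f
        for f in graph.of_kind(EntityType.MASS, negated=False)
        if primary is not None and f.mention_id != primary.mention_id
    ]

    def satellite_where(same_side: bool, lobe_rule: str) -> bool:
        if primary is None or p_side not in ("left", "right"):
            return warn_relative({(True, "same"): 6, (True, "other"): 9, (False, "any"): 17}[(same_side, lobe_rule)])
        for f in satellites:
            if f.side not in ("left", "right"):
                continue
            side_ok = (f.side == p_side) if same_side else (f.side != p_side)
            if not side_ok:
                continue
            if lobe_rule == "same":
                if f.lobe != "unknown" and f.lobe == p_lobe:
                    return True
            elif lobe_rule == "other":
                if f.lobe != "unknown" and p_lobe != "unknown" and f.lobe != p_lobe:
                    return True
            else:
                return True
        return False

    def lateral_nodes(region: str, same_side: bool, qid: int) -> bool:
        if p_side not in ("left", "right"):
            if nodes_in(region):
                return warn_relative(qid)
            return False
        side = p_side if same_side else opposite
        return nodes_in(region, side)

    def invaded(kind: EntityType) -> bool:
        return any(
            not _is_pleural_nodule(f) if kind is EntityType.PLEURA else True
            for f in graph.of_kind(kind, negated=False)
        )

    def paop_hilar() -> bool:
        for f in graph.of_kind(EntityType.PAOP, negated=False):
            if "hilar" in f.regions or "肺门" in f.surface:
                return True
            if any("肺门" in s for s in f.location_surfaces):
                return True
        return False

    answers = {
        1: primary is not None,
        2: (
            primary.size.greatest_mm
            if primary is not None and primary.size is not None
            else None
        ),
        3: invaded(EntityType.BRONCHUS),
        4: invaded(EntityType.PLEURA),
        5: paop_hilar(),
        6: satellite_where(True, "same"),
        7: invaded(EntityType.VESSEL),
        8: invaded(EntityType.VERTEBRAL_BODY),
        9: satellite_where(True, "other"),
        10: bool(graph.of_kind(EntityType.LYMPH_NODE, negated=False)),
        11: lateral_nodes("hilar", True, 11),
        12: lateral_nodes("mediastinal", True, 12),
        13: nodes_in("subcarinal"),
        14: lateral_nodes("mediastinal", False, 14),
        15: lateral_nodes("hilar", False, 15),
        16: nodes_in("supraclavicular"),
        17: satellite_where(False, "any"),
        18: any(
            _is_pleural_nodule(f)
            for f in graph.of_kind(EntityType.PLEURA, negated=False)
        ),
        19: bool(graph.of_kind(EntityType.EFFUSION, negated=False)),
        20: _dedup_join(primary.shapes) if primary is not None else None,
        21: _dedup_join(primary.densities) if primary is not None else None,
        22: _dedup_join(primary.enhancements) if primary is not None else None,
    }
    return AnswerSet(answers)


def answer_document(doc: Document) -> AnswerSet:
    """Convenience wrapper: assemble the graph and answer the catalogue."""
    return answer_questions(assemble_findings(doc.mentions, doc.relations))


# ---------------------------------------------------------------------------
# answer sidecar I/O (one record per report: doc_id, question id, answer)
# ---------------------------------------------------------------------------


def write_answers(answer_map: Mapping) -> str:
    lines = ["doc_id\tquestion\tanswer"]
    for doc_id in sorted(answer_map):
        for qid, ans in answer_map[doc_id].items():
            if isinstance(ans, bool):
                val = "Yes" if ans else "No"
            elif ans is None:
                val = ""
            elif isinstance(ans, float):
                val = f"{ans:g}"
            else:
                val = str(ans)
            lines.append(f"{doc_id}\t{qid}\t{val}")
    return "\n".join(lines) + "\n"


def read_answers(text: str) -> dict:
    by_id = {q.id: q for q in load_questions()}
    out: dict[str, dict] = {}
    lines = [l for l in text.splitlines() if l.strip()]
    for line in lines[1:]:
        doc_id, qid_s, val = line.split("\t")
        qid = int(qid_s)
        q = by_id[qid]
        ans: object
        if q.answer_type == "boolean":
            ans = val == "Yes"
        elif q.answer_type == "numeric":
            ans = float(val) if val else None
        else:
            ans = val if val else None
        out.setdefault(doc_id, {})[qid] = ans
    return {doc_id: AnswerSet(answers) for doc_id, answers in out.items()}
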