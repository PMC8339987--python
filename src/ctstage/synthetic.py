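"""Synthetic annotated CT-report generator.

Each report is rendered from a latent :class:`ScenarioSpec` describing the
clinical state of a fictional patient (primary tumor, invasions, satellite
nodules, lymph nodes, effusion, ...).  Rendering produces brat-compatible gold
entity/relation annotations, and :func:`oracle_answers` computes the ground
truth answers for the 22-question catalogue directly from the latent state,
independent of any text, so the full NER -> RC -> rule-engine pipeline can be
trained and audited offline.

Default prevalences are tuned so that per-type entity counts follow the rank
order of the published corpus statistics (Location most frequent, vertebral
body rarest) and positive-answer rates resemble the published per-question
counts (tumor always present, subcarinal metastases rare).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .corpus import Document, EntityMention, RelationMention, Report
from .schema import (
    AnswerSet,
    EntityType,
    RelationMap,
    RelationType,
    admissible_relation,
)

__all__ = [
    "TumorSpec",
    "NodeSpec",
    "SatelliteSpec",
    "ScenarioSpec",
    "GeneratorConfig",
    "GeneratedReport",
    "default_lexicon",
    "sample_scenario",
    "oracle_answers",
    "render_report",
    "generate_corpus",
    "STATION_REGIONS",
]

# IASLC lymph-node station -> nodal region.
SUPRACLAVICULAR_STATIONS = frozenset({1})
MEDIASTINAL_STATIONS = frozenset({2, 3, 4, 5, 6, 8, 9})
SUBCARINAL_STATIONS = frozenset({7})
HILAR_STATIONS = frozenset(range(10, 15))

STATION_REGIONS = {
    **{s: "supraclavicular" for s in SUPRACLAVICULAR_STATIONS},
    **{s: "mediastinal" for s in MEDIASTINAL_STATIONS},
    **{s: "subcarinal" for s in SUBCARINAL_STATIONS},
    **{s: "hilar" for s in HILAR_STATIONS},
}

_SIDE_CHAR = {"right": "右", "left": "左"}
_LOBE_CHAR = {"upper": "上", "middle": "中", "lower": "下"}


@dataclass(frozen=True)
class TumorSpec:
    side: str  # "left" | "right"
    lobe: str  # "upper" | "middle" | "lower"
    segment: Optional[str]
    size_mm: tuple  # (d1, d2) with d1 >= d2 > 0
    shape: Optional[str]
    density: Optional[str]
    enhancement: Optional[str]

    def __post_init__(self):
        d1, d2 = self.size_mm
        if not (d1 >= d2 > 0):
            raise ValueError("size pair must be positive with greatest first")


@dataclass(frozen=True)
class NodeSpec:
    station: int  # 1-14
    side: Optional[str]  # None for midline/unspecified descriptions
    size_mm: Optional[tuple]
    negated: bool = False

    def __post_init__(self):
        if not 1 <= self.station <= 14:
            raise ValueError(f"station {self.station} outside 1-14")

    @property
    def region(self) -> str:
        return STATION_REGIONS[self.station]


@dataclass(frozen=True)
class SatelliteSpec:
    category: str  # "same_lobe" | "ipsilateral_other_lobe" | "contralateral_lobe"
    side: str
    lobe: str
    size_mm: Optional[tuple]
    shape: Optional[str]


@dataclass(frozen=True)
class ScenarioSpec:
    primary_tumor: TumorSpec
    invasions: frozenset = frozenset()  # of {"bronchus","visceral_pleura","great_vessel","vertebral_body"}
    satellite_nodules: tuple = ()
    nodes: tuple = ()
    effusion: str = "absent"  # "present" | "negated" | "absent"
    paop: str = "absent"  # "present_hilar" | "absent"
    pleural_nodules: bool = False
    # render-only routine-negative findings; they never change the oracle
    negated_remainder_mass: bool = False
    negated_pleura: bool = False


DEFAULT_PREVALENCE = {
    "density": 0.38,
    "enhancement": 0.30,
    "shape": 0.80,
    "segment": 0.60,
    "invasion_bronchus": 0.26,
    "invasion_visceral_pleura": 0.28,
    "invasion_great_vessel": 0.10,
    "invasion_vertebral_body": 0.06,
    "pleural_nodules": 0.10,
    "satellite_one": 0.30,
    "satellite_two": 0.10,
    "satellite_size": 0.35,
    "satellite_shape": 0.40,
    "node_hilar_ipsi": 0.30,
    "node_mediastinal_ipsi": 0.30,
    "node_hilar_contra": 0.08,
    "node_mediastinal_contra": 0.12,
    "node_subcarinal": 0.05,
    "node_supraclavicular": 0.07,
    "node_size": 0.60,
    "negated_mediastinal_node": 0.50,
    "negated_supraclavicular_node": 0.25,
    "effusion_present": 0.20,
    "effusion_negated": 0.68,
    "paop": 0.14,
    "negated_remainder_mass": 0.45,
    "negated_pleura": 0.45,
}

_SATELLITE_CATEGORIES = ("same_lobe", "ipsilateral_other_lobe", "contralateral_lobe")
_SATELLITE_WEIGHTS = (0.40, 0.35, 0.25)


def default_lexicon() -> dict:
    path = Path(str(resources.files("ctstage").joinpath("data", "lexicon.yaml")))
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass
class GeneratorConfig:
    n_reports: int = 100
    seed: int = 0
    prevalence: dict = field(default_factory=dict)
    lexicon: dict = field(default_factory=dict)
    distractor_rate: float = 0.25  # distractor sentences per finding sentence
    merge_prob: float = 0.30  # chance of folding the effusion clause into another sentence
    malformed_unit_prob: float = 0.05  # "14×12m"-style unit typos
    doc_id_prefix: str = "synth"
    relation_map: Optional[RelationMap] = None

    def __post_init__(self):
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        merged = dict(DEFAULT_PREVALENCE)
        merged.update(self.prevalence)
        bad = [k for k, v in merged.items() if not 0.0 <= float(v) <= 1.0]
        if bad:
            raise ValueError(f"prevalence outside [0,1]: {bad}")
        self.prevalence = merged
        if not self.lexicon:
            self.lexicon = default_lexicon()
        # Size and Location surfaces are built compositionally (number formats
        # and side/lobe/segment assembly); every other type needs lexicon entries.
        for etype in EntityType:
            if etype in (EntityType.LOCATION, EntityType.SIZE):
                continue
            if not self.lexicon["entities"].get(etype.value):
                raise ValueError(f"lexicon missing entity type {etype.value}")


# ---------------------------------------------------------------------------
# scenario sampling
# ---------------------------------------------------------------------------


def _lobes_of(side: str) -> tuple:
    return ("upper", "middle", "lower") if side == "right" else ("upper", "lower")


def _choice(rng: np.random.Generator, items: Sequence, p=None):
    return items[int(rng.choice(len(items), p=p))]


def sample_scenario(config: GeneratorConfig, rng: np.random.Generator) -> ScenarioSpec:
    """Draw one latent clinical scenario from the prevalence table."""
    prev = config.prevalence
    lex = config.lexicon

    side = "right" if rng.random() < 0.55 else "left"
    if side == "right":
        lobe = _choice(rng, ("upper", "middle", "lower"), p=(0.4, 0.2, 0.4))
    else:
        lobe = _choice(rng, ("upper", "lower"))
    segment = (
        _choice(rng, lex["location"]["segments"]) if rng.random() < prev["segment"] else None
    )
    d1 = int(rng.integers(16, 56))
    d2 = max(6, int(round(d1 * (0.6 + 0.4 * rng.random()))))
    d2 = min(d2, d1)
    primary = TumorSpec(
        side=side,
        lobe=lobe,
        segment=segment,
        size_mm=(d1, d2),
        shape=_choice(rng, lex["entities"]["Shape"]) if rng.random() < prev["shape"] else None,
        density=_choice(rng, lex["entities"]["Density"]) if rng.random() < prev["density"] else None,
        enhancement=(
            _choice(rng, lex["entities"]["Enhancement"])
            if rng.random() < prev["enhancement"]
            else None
        ),
    )

    invasions = set()
    for name in ("bronchus", "visceral_pleura", "great_vessel", "vertebral_body"):
        if rng.random() < prev[f"invasion_{name}"]:
            invasions.add(name)

    n_sat = 0
    r = rng.random()
    if r < prev["satellite_two"]:
        n_sat = 2
    elif r < prev["satellite_two"] + prev["satellite_one"]:
        n_sat = 1
    satellites = []
    other_side = "left" if side == "right" else "right"
    for _ in range(n_sat):
        category = _choice(rng, _SATELLITE_CATEGORIES, p=_SATELLITE_WEIGHTS)
        if category == "same_lobe":
            s_side, s_lobe = side, lobe
        elif category == "ipsilateral_other_lobe":
            s_side = side
            choices = [l for l in _lobes_of(side) if l != lobe]
            s_lobe = _choice(rng, choices)
        else:
            s_side = other_side
            s_lobe = _choice(rng, _lobes_of(other_side))
        size = None
        if rng.random() < prev["satellite_size"]:
            sd1 = int(rng.integers(3, 8))  # always smaller than the primary
            sd2 = max(2, sd1 - int(rng.integers(0, 3)))
            size = (sd1, sd2)
        shape = (
            _choice(rng, lex["entities"]["Shape"])
            if rng.random() < prev["satellite_shape"]
            else None
        )
        satellites.append(SatelliteSpec(category, s_side, s_lobe, size, shape))

    nodes: list[NodeSpec] = []

    def _node_size() -> Optional[tuple]:
        if rng.random() >= prev["node_size"]:
            return None
        nd1 = int(rng.integers(8, 26))
        nd2 = max(4, nd1 - int(rng.integers(1, 6)))
        return (nd1, nd2)

    for region_key, stations_pool, node_side in (
        ("node_hilar_ipsi", (10, 11), side),
        ("node_hilar_contra", (10, 11), other_side),
        ("node_mediastinal_ipsi", (2, 4, 5, 6, 8, 9), side),
        ("node_mediastinal_contra", (2, 4, 5, 6, 8, 9), other_side),
    ):
        if rng.random() < prev[region_key]:
            k = int(rng.integers(1, 3 if len(stations_pool) > 2 else 2)) + (
                1 if len(stations_pool) > 2 and rng.random() < 0.3 else 0
            )
            chosen = sorted(
                int(s) for s in rng.choice(stations_pool, size=min(k, len(stations_pool)), replace=False)
            )
            for st in chosen:
                nodes.append(NodeSpec(station=st, side=node_side, size_mm=_node_size()))
    if rng.random() < prev["node_subcarinal"]:
        nodes.append(NodeSpec(station=7, side=None, size_mm=_node_size()))
    if rng.random() < prev["node_supraclavicular"]:
        nodes.append(
            NodeSpec(station=1, side=_choice(rng, ("left", "right")), size_mm=_node_size())
        )

    has_pos_mediastinal = any(
        not n.negated and n.region == "mediastinal" for n in nodes
    )
    if not has_pos_mediastinal and rng.random() < prev["negated_mediastinal_node"]:
        nodes.append(NodeSpec(station=4, side=None, size_mm=None, negated=True))
    has_pos_supra = any(not n.negated and n.region == "supraclavicular" for n in nodes)
    if not has_pos_supra and rng.random() < prev["negated_supraclavicular_node"]:
        nodes.append(NodeSpec(station=1, side=None, size_mm=None, negated=True))

    r = rng.random()
    if r < prev["effusion_present"]:
        effusion = "present"
    elif r < prev["effusion_present"] + prev["effusion_negated"]:
        effusion = "negated"
    else:
        effusion = "absent"

    return ScenarioSpec(
        primary_tumor=primary,
        invasions=frozenset(invasions),
        satellite_nodules=tuple(satellites),
        nodes=tuple(nodes),
        effusion=effusion,
        paop="present_hilar" if rng.random() < prev["paop"] else "absent",
        pleural_nodules=rng.random() < prev["pleural_nodules"],
        negated_remainder_mass=rng.random() < prev["negated_remainder_mass"],
        negated_pleura=rng.random() < prev["negated_pleura"],
    )


# ---------------------------------------------------------------------------
# oracle answers
# ---------------------------------------------------------------------------


def oracle_answers(scenario: ScenarioSpec) -> AnswerSet:
    """Ground-truth answers computed directly from the latent state."""
    t = scenario.primary_tumor
    pos_nodes = [n for n in scenario.nodes if not n.negated]
    sats = scenario.satellite_nodules

    def node_in(region: str, side: Optional[str] = None) -> bool:
        for n in pos_nodes:
            if n.region != region:
                continue
            if side is None or n.side == side:
                return True
        return False

    other = "left" if t.side == "right" else "right"
    answers = {
        1: True,
        2: float(max(t.size_mm)),
        3: "bronchus" in scenario.invasions,
        4: "visceral_pleura" in scenario.invasions,
        5: scenario.paop == "present_hilar",
        6: any(s.category == "same_lobe" for s in sats),
        7: "great_vessel" in scenario.invasions,
        8: "vertebral_body" in scenario.invasions,
        9: any(s.category == "ipsilateral_other_lobe" for s in sats),
        10: bool(pos_nodes),
        11: node_in("hilar", t.side),
        12: node_in("mediastinal", t.side),
        13: node_in("subcarinal"),
        14: node_in("mediastinal", other),
        15: node_in("hilar", other),
        16: node_in("supraclavicular"),
        17: any(s.category == "contralateral_lobe" for s in sats),
        18: scenario.pleural_nodules,
        19: scenario.effusion == "present",
        20: t.shape,
        21: t.density,
        22: t.enhancement,
    }
    return AnswerSet(answers)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


class _Piece:
    """One finding sentence under construction: text + local annotations."""

    __slots__ = ("parts", "length", "ents", "rels")

    def __init__(self):
        self.parts: list[str] = []
        self.length = 0
        self.ents: list[tuple] = []  # (EntityType, start, end)
        self.rels: list[tuple] = []  # (RelationType, ent_idx, ent_idx)

    def lit(self, s: str) -> None:
        self.parts.append(s)
        self.length += len(s)

    def ent(self, etype: EntityType, surface: str) -> int:
        start = self.length
        self.lit(surface)
        self.ents.append((etype, start, self.length))
        return len(self.ents) - 1

    def rel(self, rtype: RelationType, i: int, j: int) -> None:
        self.rels.append((rtype, i, j))

    @property
    def text(self) -> str:
        return "".join(self.parts)

    def absorb(self, other: "_Piece", joiner: str = "，") -> None:
        offset = self.length + len(joiner)
        base = len(self.ents)
        self.lit(joiner + other.text)
        self.ents.extend((t, s + offset, e + offset) for t, s, e in other.ents)
        self.rels.extend((r, i + base, j + base) for r, i, j in other.rels)


def _fmt_dim(mm: int) -> str:
    return f"{mm / 10:g}"


def _size_surface(rng, size_mm: tuple, malformed_prob: float) -> str:
    d1, d2 = size_mm
    r = rng.random()
    if r < malformed_prob:
        return f"{d1}×{d2}m"  # unit typo seen in real reports; parsed as mm
    r = rng.random()
    if r < 0.45:
        return f"{d1}×{d2}mm"
    if r < 0.75:
        return f"{_fmt_dim(d1)}×{_fmt_dim(d2)}cm"
    if r < 0.90:
        return f"{d1}mm"
    return f"{_fmt_dim(d1)}cm"


def _location_surface(side: str, lobe: str, segment: Optional[str]) -> str:
    return f"{_SIDE_CHAR[side]}肺{_LOBE_CHAR[lobe]}叶{segment or ''}"


def _primary_piece(scenario: ScenarioSpec, config: GeneratorConfig, rng) -> _Piece:
    lex = config.lexicon
    t = scenario.primary_tumor
    p = _Piece()
    i_loc = p.ent(EntityType.LOCATION, _location_surface(t.side, t.lobe, t.segment))
    p.lit(_choice(rng, lex["cues"]["see"]))
    i_mass = p.ent(EntityType.MASS, _choice(rng, lex["entities"]["Mass"]["primary"]))
    p.rel(RelationType.AT, i_loc, i_mass)
    p.lit("，" + _choice(rng, lex["cues"]["size_lead"]))
    i_size = p.ent(
        EntityType.SIZE, _size_surface(rng, t.size_mm, config.malformed_unit_prob)
    )
    p.rel(RelationType.SIZE_OF, i_size, i_mass)
    if t.shape is not None:
        p.lit("，")
        p.rel(RelationType.RELATED, p.ent(EntityType.SHAPE, t.shape), i_mass)
    if t.density is not None:
        p.lit("，呈" if rng.random() < 0.5 else "，")
        p.rel(RelationType.RELATED, p.ent(EntityType.DENSITY, t.density), i_mass)
    if t.enhancement is not None:
        p.lit("，增强扫描" if rng.random() < 0.5 else "，")
        p.rel(
            RelationType.RELATED, p.ent(EntityType.ENHANCEMENT, t.enhancement), i_mass
        )
    invasion_lex = {
        "bronchus": (EntityType.BRONCHUS, lex["entities"]["Bronchus"]),
        "visceral_pleura": (EntityType.PLEURA, lex["entities"]["Pleura"]["invasion"]),
        "great_vessel": (EntityType.VESSEL, lex["entities"]["Vessel"]),
        "vertebral_body": (
            EntityType.VERTEBRAL_BODY,
            lex["entities"]["VertebralBody"],
        ),
    }
    for name in ("bronchus", "visceral_pleura", "great_vessel", "vertebral_body"):
        if name in scenario.invasions:
            etype, surfaces = invasion_lex[name]
            p.lit("，" if rng.random() < 0.7 else "，伴")
            p.rel(RelationType.RELATED, p.ent(etype, _choice(rng, surfaces)), i_mass)
    if scenario.pleural_nodules:
        p.lit("，")
        p.rel(
            RelationType.RELATED,
            p.ent(EntityType.PLEURA, _choice(rng, lex["entities"]["Pleura"]["nodule"])),
            i_mass,
        )
    return p


def _satellite_piece(sat: SatelliteSpec, config: GeneratorConfig, rng) -> _Piece:
    lex = config.lexicon
    p = _Piece()
    i_loc = p.ent(EntityType.LOCATION, _location_surface(sat.side, sat.lobe, None))
    p.lit(_choice(rng, lex["cues"]["see_again"]))
    i_mass = p.ent(EntityType.MASS, _choice(rng, lex["entities"]["Mass"]["satellite"]))
    p.rel(RelationType.AT, i_loc, i_mass)
    if sat.size_mm is not None:
        p.lit("，" + _choice(rng, lex["cues"]["size_lead"]))
        i_size = p.ent(
            EntityType.SIZE, _size_surface(rng, sat.size_mm, config.malformed_unit_prob)
        )
        p.rel(RelationType.SIZE_OF, i_size, i_mass)
    if sat.shape is not None:
        p.lit("，")
        p.rel(RelationType.RELATED, p.ent(EntityType.SHAPE, sat.shape), i_mass)
    return p


def _node_group_pieces(
    nodes: Sequence, config: GeneratorConfig, rng
) -> list[_Piece]:
    lex = config.lexicon
    pieces = []
    pos = [n for n in nodes if not n.negated]
    by_side: dict = {}
    for n in pos:
        by_side.setdefault((n.side, n.region), []).append(n)

    def _group_size(group) -> Optional[tuple]:
        sizes = [n.size_mm for n in group if n.size_mm is not None]
        return max(sizes) if sizes else None

    handled = set()
    for (side, region), group in sorted(
        by_side.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])
    ):
        if (side, region) in handled:
            continue
        loc_parts = None
        merged_group = list(group)
        if (
            region == "hilar"
            and side is not None
            and (side, "mediastinal") in by_side
            and rng.random() < 0.6
        ):
            med = by_side[(side, "mediastinal")]
            nums = "、".join(str(n.station) for n in sorted(med, key=lambda n: n.station))
            loc_parts = f"{_SIDE_CHAR[side]}肺门及纵隔{nums}组"
            merged_group += med
            handled.add((side, "mediastinal"))
        elif region == "hilar":
            loc_parts = f"{_SIDE_CHAR[side]}肺门" + ("区" if rng.random() < 0.3 else "")
        elif region == "mediastinal":
            nums = "、".join(
                str(n.station) for n in sorted(group, key=lambda n: n.station)
            )
            loc_parts = f"{_SIDE_CHAR[side]}侧纵隔{nums}组"
        elif region == "subcarinal":
            loc_parts = "隆突下" + ("7组" if rng.random() < 0.4 else "")
        else:  # supraclavicular
            loc_parts = (
                f"{_SIDE_CHAR[side]}锁骨上" if side and rng.random() < 0.7 else "锁骨上区"
            )
        handled.add((side, region))
        p = _Piece()
        i_loc = p.ent(EntityType.LOCATION, loc_parts)
        p.lit(_choice(rng, lex["cues"]["see"]))
        i_ln = p.ent(
            EntityType.LYMPH_NODE, _choice(rng, lex["entities"]["LymphNode"]["positive"])
        )
        p.rel(RelationType.AT, i_loc, i_ln)
        gsize = _group_size(merged_group)
        if gsize is not None:
            p.lit("，较大约" if rng.random() < 0.6 else "，大者约")
            i_size = p.ent(
                EntityType.SIZE, _size_surface(rng, gsize, config.malformed_unit_prob)
            )
            p.rel(RelationType.SIZE_OF, i_size, i_ln)
        pieces.append(p)

    for n in nodes:
        if not n.negated:
            continue
        region_word = {"mediastinal": "纵隔", "supraclavicular": "锁骨上区"}.get(
            n.region, "纵隔"
        )
        p = _Piece()
        i_loc = p.ent(EntityType.LOCATION, region_word)
        i_neg = p.ent(EntityType.NEGATION, _choice(rng, lex["entities"]["Negation"]))
        i_ln = p.ent(
            EntityType.LYMPH_NODE, _choice(rng, lex["entities"]["LymphNode"]["negated"])
        )
        p.rel(RelationType.AT, i_loc, i_ln)
        p.rel(RelationType.NEGATE, i_neg, i_ln)
        pieces.append(p)
    return pieces


def _effusion_piece(scenario: ScenarioSpec, config: GeneratorConfig, rng) -> Optional[_Piece]:
    lex = config.lexicon
    if scenario.effusion == "absent":
        return None
    p = _Piece()
    if scenario.effusion == "present":
        if rng.random() < 0.5:
            p.lit(_choice(rng, ("可见", "提示")))
        p.ent(EntityType.EFFUSION, _choice(rng, lex["entities"]["Effusion"]["present"]))
    else:
        i_neg = p.ent(EntityType.NEGATION, _choice(rng, lex["entities"]["Negation"]))
        i_eff = p.ent(
            EntityType.EFFUSION, _choice(rng, lex["entities"]["Effusion"]["negated"])
        )
        p.rel(RelationType.NEGATE, i_neg, i_eff)
    return p


def _paop_piece(scenario: ScenarioSpec, config: GeneratorConfig, rng) -> Optional[_Piece]:
    if scenario.paop != "present_hilar":
        return None
    lex = config.lexicon
    side = scenario.primary_tumor.side if rng.random() < 0.7 else _choice(rng, ("left", "right"))
    p = _Piece()
    i_loc = p.ent(EntityType.LOCATION, f"{_SIDE_CHAR[side]}肺门")
    p.lit(_choice(rng, ("见", "旁见", "可见")))
    i_paop = p.ent(EntityType.PAOP, _choice(rng, lex["entities"]["PAOP"]))
    p.rel(RelationType.AT, i_loc, i_paop)
    return p


def _negated_mass_piece(config: GeneratorConfig, rng) -> _Piece:
    lex = config.lexicon
    p = _Piece()
    i_loc = p.ent(EntityType.LOCATION, _choice(rng, lex["location"]["remainder"]))
    i_neg = p.ent(EntityType.NEGATION, _choice(rng, lex["entities"]["Negation"]))
    i_mass = p.ent(EntityType.MASS, _choice(rng, lex["entities"]["Mass"]["negated"]))
    p.rel(RelationType.AT, i_loc, i_mass)
    p.rel(RelationType.NEGATE, i_neg, i_mass)
    return p


def _negated_pleura_piece(config: GeneratorConfig, rng) -> _Piece:
    lex = config.lexicon
    p = _Piece()
    i_neg = p.ent(EntityType.NEGATION, _choice(rng, lex["entities"]["Negation"]))
    i_pl = p.ent(EntityType.PLEURA, _choice(rng, lex["entities"]["Pleura"]["negated"]))
    p.rel(RelationType.NEGATE, i_neg, i_pl)
    return p


def render_report(
    scenario: ScenarioSpec,
    config: GeneratorConfig,
    rng: np.random.Generator,
    doc_id: str = "synth-0",
) -> Document:
    """Render one scenario into a report with gold mentions and relations."""
    pieces: list[_Piece] = [_primary_piece(scenario, config, rng)]
    tail: list[_Piece] = []
    for sat in scenario.satellite_nodules:
        tail.append(_satellite_piece(sat, config, rng))
    tail.extend(_node_group_pieces(scenario.nodes, config, rng))
    paop = _paop_piece(scenario, config, rng)
    if paop is not None:
        tail.append(paop)
    if scenario.negated_remainder_mass:
        tail.append(_negated_mass_piece(config, rng))
    if scenario.negated_pleura:
        tail.append(_negated_pleura_piece(config, rng))
    effusion = _effusion_piece(scenario, config, rng)
    if tail:
        order = rng.permutation(len(tail))
        tail = [tail[i] for i in order]
    if effusion is not None:
        if tail and rng.random() < config.merge_prob:
            host = tail[int(rng.integers(0, len(tail)))]
            host.absorb(effusion)
        elif rng.random() < config.merge_prob:
            pieces[0].absorb(effusion)
        else:
            tail.append(effusion)
            if len(tail) > 1:
                order = rng.permutation(len(tail))
                tail = [tail[i] for i in order]
    pieces.extend(tail)

    sentences: list[Optional[_Piece]] = list(pieces)
    n_distract = int(np.ceil(config.distractor_rate * len(pieces)))
    pool = list(config.lexicon["distractors"])
    for _ in range(n_distract):
        if not pool:
            break
        d = pool.pop(int(rng.integers(0, len(pool))))
        dp = _Piece()
        dp.lit(d)
        pos = int(rng.integers(0, len(sentences) + 1))
        sentences.insert(pos, dp)

    # assemble document text and global annotations
    text_parts: list[str] = []
    offset = 0
    ent_records: list[tuple] = []  # (start, end, etype)
    rel_records: list[tuple] = []  # (rtype, ent_index, ent_index)
    for piece in sentences:
        base = len(ent_records)
        text_parts.append(piece.text + "。")
        ent_records.extend((s + offset, e + offset, t) for t, s, e in piece.ents)
        rel_records.extend((r, i + base, j + base) for r, i, j in piece.rels)
        offset += len(piece.text) + 1
    text = "".join(text_parts)
    report = Report(doc_id=doc_id, text=text)

    order = sorted(range(len(ent_records)), key=lambda k: ent_records[k][:2])
    id_of = {orig: f"T{rank + 1}" for rank, orig in enumerate(order)}
    mentions = [
        EntityMention(
            mention_id=id_of[k],
            etype=ent_records[k][2],
            start=ent_records[k][0],
            end=ent_records[k][1],
            surface=text[ent_records[k][0] : ent_records[k][1]],
        )
        for k in order
    ]
    relations = [
        RelationMention(rtype, id_of[i], id_of[j]) for rtype, i, j in rel_records
    ]
    doc = Document(report=report, mentions=mentions, relations=relations)
    _check_rendered(doc, config.relation_map)
    return doc


def _check_rendered(doc: Document, relation_map: Optional[RelationMap]) -> None:
    by_id = {m.mention_id: m for m in doc.mentions}
    for rel in doc.relations:
        m1, m2 = by_id[rel.arg1], by_id[rel.arg2]
        expected = admissible_relation(m1.etype, m2.etype, relation_map)
        if rel.rtype is not expected:
            raise AssertionError(
                f"renderer produced inadmissible relation {rel.rtype} for "
                f"({m1.etype}, {m2.etype})"
            )


@dataclass
class GeneratedReport:
    document: Document
    scenario: ScenarioSpec
    answers: AnswerSet


def generate_corpus(config: GeneratorConfig) -> list[GeneratedReport]:
    """Generate ``config.n_reports`` annotated reports with oracle answers."""
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_reports):
        scenario = sample_scenario(config, rng)
        doc = render_report(
            scenario, config, rng, doc_id=f"{config.doc_id_prefix}-{i:04d}"
        )
        out.append(
            GeneratedReport(
                document=doc, scenario=scenario, answers=oracle_answers(scenario)
            )
        )
    return out
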