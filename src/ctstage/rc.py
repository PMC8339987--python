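"""Relation classification with an attention Bi-LSTM over entity-marked text.

Candidate pairs are all same-sentence mention pairs.  Each instance is the
sentence with ``<e1>...</e1>``/``<e2>...</e2>`` markers around the two
mentions; when the relation-sign constraint (RSC) is enabled, the single
admissible relation tag for the pair's entity types is prepended as the first
token (e.g. ``At<e1>左肺门及纵隔4、5组</e1>见<e2>肿大淋巴结</e2>...``).  At
prediction time the admissibility constraint is enforced as a hard mask:
predictions outside {admissible tag, NoRelation} are coerced to NoRelation,
and pairs whose types admit no relation are labeled NoRelation without
invoking the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn
from .corpus import Document, EntityMention, RelationMention
from .errors import DegenerateDataError, InsufficientDataError
from .schema import RelationMap, RelationType, admissible_relation

__all__ = [
    "RcConfig",
    "RcInstance",
    "enumerate_pairs",
    "build_instance",
    "instances_from_document",
    "RcModel",
    "train_rc",
    "predict_relation",
    "predict_relations",
]

RC_LABELS = (
    RelationType.AT,
    RelationType.SIZE_OF,
    RelationType.RELATED,
    RelationType.NEGATE,
    RelationType.NO_RELATION,
)
_MARKERS = ("<e1>", "</e1>", "<e2>", "</e2>")
_TAG_TOKENS = tuple(r.value for r in RC_LABELS)


@dataclass(frozen=True)
class RcInstance:
    marked_text: str  # tag (when enabled) + sentence with entity markers
    admissible: RelationType  # the pair's single admissible relation
    rsc_tag: Optional[str]  # prepended tag, None when RSC disabled
    label: Optional[RelationType] = None  # gold label (training only)


@dataclass
class RcConfig:
    embedding_dim: int = 100
    hidden_units: int = 128
    attention_dim: int = 64
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stopping_patience: int = 5
    seed: int = 0
    rsc_enabled: bool = True
    grad_clip: float = 5.0

    def __post_init__(self):
        if min(self.embedding_dim, self.hidden_units, self.attention_dim) <= 0:
            raise ValueError("dimensions must be positive")


def enumerate_pairs(mentions: Sequence[EntityMention]) -> list[tuple]:
    """All C(n, 2) unordered pairs; e1 is the earlier mention by start offset."""
    ms = sorted(mentions, key=lambda m: (m.start, m.end, m.mention_id))
    return [(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))]


def build_instance(
    sentence: str,
    sentence_start: int,
    pair: tuple,
    rsc_enabled: bool = True,
    relation_map: Optional[RelationMap] = None,
    label: Optional[RelationType] = None,
) -> RcInstance:
    """Insert entity markers (and the RSC tag when enabled) for one pair."""
    m1, m2 = sorted(pair, key=lambda m: (m.start, m.end))
    if m2.start < m1.end:
        raise ValueError(
            f"overlapping pair {m1.mention_id}/{m2.mention_id}: markers would cross"
        )
    s1, e1 = m1.start - sentence_start, m1.end - sentence_start
    s2, e2 = m2.start - sentence_start, m2.end - sentence_start
    if not (0 <= s1 and e2 <= len(sentence)):
        raise ValueError("pair does not lie within the sentence")
    marked = (
        sentence[:s1]
        + "<e1>"
        + sentence[s1:e1]
        + "</e1>"
        + sentence[e1:s2]
        + "<e2>"
        + sentence[s2:e2]
        + "</e2>"
        + sentence[e2:]
    )
    adm = admissible_relation(m1.etype, m2.etype, relation_map)
    tag = adm.value if rsc_enabled else None
    if tag is not None:
        marked = tag + marked
    return RcInstance(marked_text=marked, admissible=adm, rsc_tag=tag, label=label)


def tokenize_marked(instance: RcInstance) -> list[str]:
    """Atomic tag + marker tokens; every other character is its own token."""
    text = instance.marked_text
    tokens: list[str] = []
    if instance.rsc_tag is not None:
        tokens.append(instance.rsc_tag)
        text = text[len(instance.rsc_tag) :]
    i = 0
    while i < len(text):
        for marker in _MARKERS:
            if text.startswith(marker, i):
                tokens.append(marker)
                i += len(marker)
                break
        else:
            tokens.append(text[i])
            i += 1
    return tokens


def instances_from_document(
    doc: Document,
    rsc_enabled: bool = True,
    relation_map: Optional[RelationMap] = None,
    include_edgeless: bool = False,
) -> list[RcInstance]:
    """Labeled instances for all same-sentence pairs of a gold document.

    Pairs whose entity types admit no relation are auto-labeled NoRelation and
    excluded unless ``include_edgeless``.
    """
    gold = {
        frozenset((r.arg1, r.arg2)): r.rtype for r in doc.relations
    }
    out = []
    for si, (s, _e) in enumerate(doc.report.sentence_spans):
        sentence = doc.report.sentence_text(si)
        for m1, m2 in enumerate_pairs(doc.mentions_in_sentence(si)):
            adm = admissible_relation(m1.etype, m2.etype, relation_map)
            if adm is RelationType.NO_RELATION and not include_edgeless:
                continue
            label = gold.get(
                frozenset((m1.mention_id, m2.mention_id)), RelationType.NO_RELATION
            )
            out.append(
                build_instance(
                    sentence, s, (m1, m2), rsc_enabled, relation_map, label=label
                )
            )
    return out


class RcModel:
    """Attention Bi-LSTM relation classifier."""

    def __init__(self, config: RcConfig, vocab: dict):
        self.config = config
        self.vocab = dict(vocab)
        self.labels = RC_LABELS
        rng = np.random.default_rng(config.seed)
        d, h, a = config.embedding_dim, config.hidden_units, config.attention_dim
        C = len(self.labels)
        V = max(self.vocab.values(), default=0) + 1
        self.params = {
            "E": nn.Param(rng.normal(0, 0.1, size=(V, d))),
            "W_f": nn.Param(nn.glorot(rng, d, 4 * h, (d, 4 * h))),
            "U_f": nn.Param(nn.glorot(rng, h, 4 * h, (h, 4 * h))),
            "b_f": nn.Param(np.zeros(4 * h)),
            "W_r": nn.Param(nn.glorot(rng, d, 4 * h, (d, 4 * h))),
            "U_r": nn.Param(nn.glorot(rng, h, 4 * h, (h, 4 * h))),
            "b_r": nn.Param(np.zeros(4 * h)),
            "att_W": nn.Param(nn.glorot(rng, 2 * h, a, (2 * h, a))),
            "att_v": nn.Param(nn.glorot(rng, a, 1, (a, 1))),
            "out_W": nn.Param(nn.glorot(rng, 2 * h, C, (2 * h, C))),
            "out_b": nn.Param(np.zeros(C)),
        }

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    def logits(
        self, token_ids: np.ndarray, drop_rng: Optional[np.random.Generator] = None
    ) -> nn.Tensor:
        cfg = self.config
        h = cfg.hidden_units
        x = nn.embedding(self.params["E"], token_ids)
        x = nn.dropout(x, cfg.dropout_rate, drop_rng)
        fwd = nn.lstm_run(x, self.params["W_f"], self.params["U_f"], self.params["b_f"], h)
        bwd = nn.lstm_run(
            x, self.params["W_r"], self.params["U_r"], self.params["b_r"], h, reverse=True
        )
        H = nn.concat([fwd, bwd], axis=-1)  # (B, T, 2h)
        scores = (H @ self.params["att_W"]).tanh() @ self.params["att_v"]  # (B, T, 1)
        B, T, _ = scores.shape
        alpha_flat = scores.reshape(B, T)
        alpha = alpha_flat - alpha_flat.logsumexp(axis=1, keepdims=True)
        weights = alpha.reshape(B, T, 1)
        context = (H * _exp(weights)).sum(axis=1)  # (B, 2h)
        context = nn.dropout(context, cfg.dropout_rate, drop_rng)
        return context @ self.params["out_W"] + self.params["out_b"]

    def token_ids(self, instance: RcInstance) -> np.ndarray:
        return np.asarray(
            [self.vocab.get(tok, 0) for tok in tokenize_marked(instance)]
        )

    def save(self, path) -> None:
        meta = json.dumps(
            {"config": asdict(self.config), "vocab": self.vocab}, ensure_ascii=False
        )
        np.savez(path, __meta__=np.array(meta), **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, path) -> "RcModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(RcConfig(**meta["config"]), meta["vocab"])
        for k in model.params:
            model.params[k].data = data[k]
        return model


def _exp(x: nn.Tensor) -> nn.Tensor:
    # exp(x) = sigmoid-free composite: use exp via logsumexp-free primitive
    out_data = np.exp(x.data)

    def bw(g):
        return ((x, g * out_data),)

    return nn.Tensor(out_data, _parents=(x,), _bw=bw)


def _build_vocab(instances: Sequence[RcInstance]) -> dict:
    tokens = set()
    for inst in instances:
        tokens.update(tokenize_marked(inst))
    tokens.update(_MARKERS)
    tokens.update(_TAG_TOKENS)
    return {tok: i + 1 for i, tok in enumerate(sorted(tokens))}  # 0 = UNK


def train_rc(
    instances_train: Sequence[RcInstance],
    instances_val: Sequence[RcInstance],
    config: RcConfig,
    verbose: bool = False,
) -> tuple[RcModel, list[float]]:
    """Train the classifier with early stopping on validation macro-F1."""
    from .evaluate import rc_metrics

    if not instances_train:
        raise InsufficientDataError("no training instances")
    classes = {inst.label for inst in instances_train}
    if len(classes) < 2:
        raise DegenerateDataError("training data contains a single relation class")

    vocab = _build_vocab(instances_train)
    model = RcModel(config, vocab)
    label_index = {lab: i for i, lab in enumerate(model.labels)}

    X = [model.token_ids(inst) for inst in instances_train]
    y = np.asarray([label_index[inst.label] for inst in instances_train])
    lengths = [len(x) for x in X]

    params = model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)

    best_f1 = -1.0
    best_state = None
    bad = 0
    history: list[float] = []
    for epoch in range(config.max_epochs):
        for batch in _rc_batches(lengths, config.batch_size, rng):
            xb = np.stack([X[i] for i in batch])
            yb = y[batch]
            logits = model.logits(xb, drop_rng=drop_rng)
            B = len(batch)
            logp = logits - logits.logsumexp(axis=1, keepdims=True)
            nll = -(logp[np.arange(B), yb].sum()) * (1.0 / B)
            if not np.isfinite(nll.data):
                raise DegenerateDataError(f"non-finite RC loss at epoch {epoch}")
            opt.zero_grad()
            nll.backward()
            nn.clip_gradients(params, config.grad_clip)
            opt.step()
        preds = [predict_relation(model, inst) for inst in instances_val]
        golds = [inst.label for inst in instances_val]
        f1 = rc_metrics(golds, preds).macro.f1 if instances_val else 0.0
        history.append(f1)
        if verbose:
            print(f"[rc] epoch {epoch}: val macro-F1 {f1:.2f}")
        if f1 > best_f1 + 1e-12:
            best_f1 = f1
            best_state = {k: p.data.copy() for k, p in model.params.items()}
            bad = 0
        else:
            bad += 1
            if bad >= config.early_stopping_patience:
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, history


def _rc_batches(lengths, batch_size, rng):
    by_len: dict[int, list[int]] = {}
    for i, ln in enumerate(lengths):
        by_len.setdefault(ln, []).append(i)
    chunks = []
    for ln in sorted(by_len):
        idx = np.asarray(by_len[ln])
        for j in range(0, len(idx), batch_size):
            chunks.append(idx[j : j + batch_size])
    order = rng.permutation(len(chunks))
    return [chunks[i] for i in order]


def predict_relation(model: RcModel, instance: RcInstance) -> RelationType:
    """Predict one of the five labels, honoring the admissibility constraint."""
    if instance.admissible is RelationType.NO_RELATION:
        return RelationType.NO_RELATION  # no edge: skip the model entirely
    logits = model.logits(np.asarray([model.token_ids(instance)])).data[0]
    pred = model.labels[int(np.argmax(logits))]
    if model.config.rsc_enabled and pred not in (
        instance.admissible,
        RelationType.NO_RELATION,
    ):
        return RelationType.NO_RELATION  # hard relation-sign constraint
    return pred


def predict_relations(
    model: RcModel,
    doc: Document,
    relation_map: Optional[RelationMap] = None,
) -> list[RelationMention]:
    """Classify every same-sentence pair of ``doc.mentions``."""
    out: list[RelationMention] = []
    rsc = model.config.rsc_enabled
    for si, (s, _e) in enumerate(doc.report.sentence_spans):
        sentence = doc.report.sentence_text(si)
        for m1, m2 in enumerate_pairs(doc.mentions_in_sentence(si)):
            adm = admissible_relation(m1.etype, m2.etype, relation_map)
            if adm is RelationType.NO_RELATION:
                continue
            inst = build_instance(sentence, s, (m1, m2), rsc, relation_map)
            pred = predict_relation(model, inst)
            if pred is not RelationType.NO_RELATION:
                out.append(RelationMention(pred, m1.mention_id, m2.mention_id))
    return out
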