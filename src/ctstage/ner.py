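"""Character-level sequence taggers: Bi-LSTM-CRF (core) and ID-CNN-CRF.

Characters are the token unit; each character carries a character embedding
plus a word-segmentation-position embedding (first/middle/last/single within
its segmented word).  Emission scores feed a from-scratch linear-chain CRF
(:mod:`ctstage.crf`); decoding is constrained to valid BIO transitions.

The default segmenter is a greedy longest-match over the generator lexicon
(perfect segmentation for synthetic text); any callable mapping a sentence to
a list of segments can be plugged in for real clinical text.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .corpus import BioSequence, Document, EntityMention, Report, from_bio, to_bio
from .crf import CrfParams, bio_transition_masks, crf_batch_nll_grad, viterbi_decode
from .errors import DegenerateDataError, DivergenceError, InsufficientDataError
from .schema import EntityType
from .synthetic import default_lexicon

__all__ = [
    "NerConfig",
    "NerFeatures",
    "LexiconSegmenter",
    "default_segmenter",
    "featurize",
    "bio_labels",
    "TaggerModel",
    "train_tagger",
    "predict_entities",
]

SEG_TAGS = ("single", "first", "middle", "last")
_SEG_ID = {t: i for i, t in enumerate(SEG_TAGS)}
UNK_ID = 0


def bio_labels() -> tuple:
    """The 29 BIO labels: O plus B/I for each of the 14 entity types."""
    labels = ["O"]
    for etype in EntityType:
        labels.append(f"B-{etype.value}")
        labels.append(f"I-{etype.value}")
    return tuple(labels)


@dataclass(frozen=True)
class NerFeatures:
    char_ids: tuple
    seg_ids: tuple

    def __post_init__(self):
        if len(self.char_ids) != len(self.seg_ids):
            raise ValueError("char and seg feature lengths differ")


class LexiconSegmenter:
    """Greedy longest-match word segmentation over a fixed word list."""

    def __init__(self, words: Sequence[str], max_len: int = 12):
        self.words = frozenset(w for w in words if len(w) > 1)
        self.max_len = min(max_len, max((len(w) for w in self.words), default=1))

    def __call__(self, sentence: str) -> list[str]:
        out = []
        i = 0
        n = len(sentence)
        while i < n:
            match = None
            for k in range(min(self.max_len, n - i), 1, -1):
                if sentence[i : i + k] in self.words:
                    match = sentence[i : i + k]
                    break
            if match is None:
                out.append(sentence[i])
                i += 1
            else:
                out.append(match)
                i += len(match)
        return out


def _lexicon_words(lexicon: dict) -> list[str]:
    words: list[str] = []

    def collect(node):
        if isinstance(node, str):
            words.append(node)
        elif isinstance(node, list):
            for item in node:
                collect(item)
        elif isinstance(node, dict):
            for item in node.values():
                collect(item)

    collect(lexicon.get("entities", {}))
    collect(lexicon.get("location", {}))
    collect(lexicon.get("cues", {}))
    return sorted(set(words))


_DEFAULT_SEGMENTER: Optional[LexiconSegmenter] = None


def default_segmenter() -> LexiconSegmenter:
    global _DEFAULT_SEGMENTER
    if _DEFAULT_SEGMENTER is None:
        _DEFAULT_SEGMENTER = LexiconSegmenter(_lexicon_words(default_lexicon()))
    return _DEFAULT_SEGMENTER


def seg_tags_for(sentence: str, segmenter: Callable[[str], list]) -> list[str]:
    tags: list[str] = []
    covered = 0
    for word in segmenter(sentence):
        k = len(word)
        covered += k
        if k == 1:
            tags.append("single")
        else:
            tags.append("first")
            tags.extend(["middle"] * (k - 2))
            tags.append("last")
    if covered != len(sentence):
        raise ValueError("segmenter output does not cover the sentence")
    return tags


def featurize(
    sentence: str,
    segmenter: Optional[Callable[[str], list]] = None,
    vocab: Optional[dict] = None,
) -> NerFeatures:
    """One (char id, segmentation-position id) pair per character.

    Characters missing from ``vocab`` map to the unknown index; when ``vocab``
    is None a sentence-local index is used (tests / inspection only).
    """
    if not sentence:
        raise ValueError("sentence must be non-empty")
    segmenter = segmenter or default_segmenter()
    if vocab is None:
        vocab = {}
        for ch in sentence:
            vocab.setdefault(ch, len(vocab) + 1)
    char_ids = tuple(vocab.get(ch, UNK_ID) for ch in sentence)
    seg_ids = tuple(_SEG_ID[t] for t in seg_tags_for(sentence, segmenter))
    return NerFeatures(char_ids=char_ids, seg_ids=seg_ids)


@dataclass
class NerConfig:
    char_embedding_dim: int = 100
    seg_embedding_dim: int = 20
    hidden_units: int = 128  # per direction
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stopping_patience: int = 5
    seed: int = 0
    dilation_widths: tuple = (1, 1, 2)  # ID-CNN dilations per block
    block_repeats: int = 4
    grad_clip: float = 5.0

    def __post_init__(self):
        if min(self.char_embedding_dim, self.seg_embedding_dim, self.hidden_units) <= 0:
            raise ValueError("dimensions must be positive")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


class TaggerModel:
    """A trained sequence tagger (architecture + parameters + vocab)."""

    def __init__(
        self,
        config: NerConfig,
        arch: str,
        vocab: dict,
        seg_words: Sequence[str],
        pretrained_char: Optional[np.ndarray] = None,
    ):
        if arch not in ("bilstm_crf", "idcnn_crf"):
            raise ValueError(f"unknown arch {arch!r}")
        self.config = config
        self.arch = arch
        self.vocab = dict(vocab)
        self.labels = bio_labels()
        self.seg_words = tuple(seg_words)
        self.segmenter = LexiconSegmenter(self.seg_words)
        self._trans_mask, self._start_mask = bio_transition_masks(self.labels)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, nn.Param] = {}
        self._init_params(rng, pretrained_char)

    # -- parameters ----------------------------------------------------------
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = nn.Param(array)

    def _init_params(self, rng, pretrained_char) -> None:
        cfg = self.config
        V = max(self.vocab.values(), default=0) + 1
        dc, ds, h = cfg.char_embedding_dim, cfg.seg_embedding_dim, cfg.hidden_units
        L = len(self.labels)
        if pretrained_char is not None:
            if pretrained_char.shape != (V, dc):
                raise ValueError("pretrained embedding table has wrong shape")
            self._add("E_char", pretrained_char.astype(np.float64).copy())
        else:
            self._add("E_char", rng.normal(0, 0.1, size=(V, dc)))
        self._add("E_seg", rng.normal(0, 0.1, size=(len(SEG_TAGS), ds)))
        D = dc + ds
        if self.arch == "bilstm_crf":
            for direction in ("f", "r"):
                self._add(f"W_{direction}", nn.glorot(rng, D, 4 * h, (D, 4 * h)))
                self._add(f"U_{direction}", nn.glorot(rng, h, 4 * h, (h, 4 * h)))
                self._add(f"b_{direction}", np.zeros(4 * h))
            self._add("out_W", nn.glorot(rng, 2 * h, L, (2 * h, L)))
        else:
            self._add("in_W", nn.glorot(rng, D, h, (D, h)))
            self._add("in_b", np.zeros(h))
            for k, _d in enumerate(cfg.dilation_widths):
                for side in ("l", "m", "r"):
                    self._add(f"conv{k}_{side}", nn.glorot(rng, h, h, (h, h)))
                self._add(f"conv{k}_b", np.zeros(h))
            self._add("out_W", nn.glorot(rng, h, L, (h, L)))
        self._add("out_b", np.zeros(L))
        self._add("trans", np.zeros((L, L)))
        self._add("start", np.zeros(L))
        self._add("stop", np.zeros(L))

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    # -- forward -------------------------------------------------------------
    def emissions(
        self,
        char_ids: np.ndarray,
        seg_ids: np.ndarray,
        drop_rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        cfg = self.config
        x = nn.concat(
            [
                nn.embedding(self.params["E_char"], char_ids),
                nn.embedding(self.params["E_seg"], seg_ids),
            ],
            axis=-1,
        )
        x = nn.dropout(x, cfg.dropout_rate, drop_rng)
        if self.arch == "bilstm_crf":
            h = cfg.hidden_units
            fwd = nn.lstm_run(
                x, self.params["W_f"], self.params["U_f"], self.params["b_f"], h
            )
            bwd = nn.lstm_run(
                x,
                self.params["W_r"],
                self.params["U_r"],
                self.params["b_r"],
                h,
                reverse=True,
            )
            feats = nn.dropout(nn.concat([fwd, bwd], axis=-1), cfg.dropout_rate, drop_rng)
        else:
            feats = (x @ self.params["in_W"] + self.params["in_b"]).relu()
            for _ in range(cfg.block_repeats):
                for k, d in enumerate(cfg.dilation_widths):
                    left = _shift(feats, d)
                    right = _shift(feats, -d)
                    feats = (
                        left @ self.params[f"conv{k}_l"]
                        + feats @ self.params[f"conv{k}_m"]
                        + right @ self.params[f"conv{k}_r"]
                        + self.params[f"conv{k}_b"]
                    ).relu()
            feats = nn.dropout(feats, cfg.dropout_rate, drop_rng)
        return feats @ self.params["out_W"] + self.params["out_b"]

    def crf_params(self, constrained: bool = False) -> CrfParams:
        trans = self.params["trans"].data
        start = self.params["start"].data
        if constrained:
            trans = trans + self._trans_mask
            start = start + self._start_mask
        return CrfParams(
            transitions=trans,
            start=start,
            stop=self.params["stop"].data,
            label_set=self.labels,
        )

    def decode(self, sentence: str) -> BioSequence:
        feats = featurize(sentence, self.segmenter, self.vocab)
        em = self.emissions(
            np.asarray([feats.char_ids]), np.asarray([feats.seg_ids])
        ).data[0]
        path, _ = viterbi_decode(em, self.crf_params(constrained=True))
        return BioSequence(
            tokens=tuple(sentence), labels=tuple(self.labels[i] for i in path)
        )

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps(
            {
                "arch": self.arch,
                "config": asdict(self.config),
                "vocab": self.vocab,
                "seg_words": list(self.seg_words),
            },
            ensure_ascii=False,
        )
        arrays = {k: p.data for k, p in self.params.items()}
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TaggerModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg_dict = dict(meta["config"])
        cfg_dict["dilation_widths"] = tuple(cfg_dict["dilation_widths"])
        model = cls(NerConfig(**cfg_dict), meta["arch"], meta["vocab"], meta["seg_words"])
        for k in model.params:
            model.params[k].data = data[k]
        return model


def _shift(x: nn.Tensor, offset: int) -> nn.Tensor:
    """Shift (B, T, H) along T by ``offset`` with zero padding."""
    B, T, H = x.shape
    d = abs(offset)
    if d == 0 or d >= T:
        return x * nn.Tensor(np.zeros(1)) if d >= T else x
    zeros = nn.Tensor(np.zeros((B, d, H)))
    if offset > 0:  # value at t comes from t-d
        return nn.concat([zeros, x[:, : T - d, :]], axis=1)
    return nn.concat([x[:, d:, :], zeros], axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _doc_sentences(doc: Document) -> list[tuple[str, tuple]]:
    out = []
    for i in range(len(doc.report.sentence_spans)):
        bio = to_bio(doc.report, doc.mentions, i)
        if bio.tokens:
            out.append((doc.report.sentence_text(i), bio.labels))
    return out


def _build_vocab(sentences: Sequence[tuple]) -> dict:
    chars = sorted({ch for text, _ in sentences for ch in text})
    return {ch: i + 1 for i, ch in enumerate(chars)}  # 0 reserved for UNK


def _batches(lengths: Sequence[int], batch_size: int, rng) -> list[np.ndarray]:
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


def train_tagger(
    corpus_train: Sequence[Document],
    corpus_val: Sequence[Document],
    config: NerConfig,
    arch: str = "bilstm_crf",
    segmenter_words: Optional[Sequence[str]] = None,
    pretrained_char: Optional[np.ndarray] = None,
    verbose: bool = False,
) -> tuple[TaggerModel, list[float]]:
    """Train a tagger with early stopping on validation exact micro-F1.

    Returns ``(model, history)`` where ``history`` is the validation micro-F1
    trajectory (one entry per epoch).  Fully deterministic for a fixed seed.
    """
    from .evaluate import ner_metrics  # local import to avoid a cycle

    if not corpus_train:
        raise InsufficientDataError("empty training corpus")
    train_sents = [s for doc in corpus_train for s in _doc_sentences(doc)]
    if not train_sents:
        raise InsufficientDataError("training corpus has no sentences")
    if all(all(l == "O" for l in labels) for _, labels in train_sents):
        raise DegenerateDataError("training corpus contains no entity mentions")

    seg_words = (
        tuple(segmenter_words)
        if segmenter_words is not None
        else tuple(_lexicon_words(default_lexicon()))
    )
    vocab = _build_vocab(train_sents)
    model = TaggerModel(config, arch, vocab, seg_words, pretrained_char)
    label_index = {lab: i for i, lab in enumerate(model.labels)}

    feats = [featurize(text, model.segmenter, vocab) for text, _ in train_sents]
    X_char = [np.asarray(f.char_ids) for f in feats]
    X_seg = [np.asarray(f.seg_ids) for f in feats]
    Y = [np.asarray([label_index[l] for l in labels]) for _, labels in train_sents]
    lengths = [len(x) for x in X_char]

    params = model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)

    best_f1 = -1.0
    best_state = None
    bad_epochs = 0
    history: list[float] = []
    for epoch in range(config.max_epochs):
        for batch in _batches(lengths, config.batch_size, rng):
            cb = np.stack([X_char[i] for i in batch])
            sb = np.stack([X_seg[i] for i in batch])
            yb = np.stack([Y[i] for i in batch])
            em = model.emissions(cb, sb, drop_rng=drop_rng)
            nll, d_em, d_tr, d_st, d_sp = crf_batch_nll_grad(
                em.data, yb, model.crf_params()
            )
            if not np.isfinite(nll):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            B = len(batch)
            opt.zero_grad()
            em.backward(d_em / B)
            model.params["trans"].grad = d_tr / B
            model.params["start"].grad = d_st / B
            model.params["stop"].grad = d_sp / B
            nn.clip_gradients(params, config.grad_clip)
            opt.step()
        f1 = _validation_f1(model, corpus_val, ner_metrics)
        history.append(f1)
        if verbose:
            print(f"[ner {arch}] epoch {epoch}: val exact micro-F1 {f1:.2f}")
        if f1 > best_f1 + 1e-12:
            best_f1 = f1
            best_state = {k: p.data.copy() for k, p in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience:
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, history


def _validation_f1(model: TaggerModel, corpus_val, ner_metrics) -> float:
    gold, pred = {}, {}
    for doc in corpus_val:
        gold[doc.report.doc_id] = doc.mentions
        pred[doc.report.doc_id] = predict_entities(model, doc.report)
    if not gold:
        return 0.0
    return ner_metrics(gold, pred, scheme="exact").micro.f1


def predict_entities(model: TaggerModel, report: Report) -> list[EntityMention]:
    """Decode every sentence and return document-offset entity mentions."""
    mentions: list[EntityMention] = []
    counter = 1
    for i, (s, _e) in enumerate(report.sentence_spans):
        sentence = report.sentence_text(i)
        if not sentence:
            continue
        bio = model.decode(sentence)
        for etype, ls, le in from_bio(bio):
            mentions.append(
                EntityMention(
                    mention_id=f"T{counter}",
                    etype=etype,
                    start=s + ls,
                    end=s + le,
                    surface=sentence[ls:le],
                )
            )
            counter += 1
    return mentions
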