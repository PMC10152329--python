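"""Multilabel resource classification and query-intent classification.

Resources belong to one or more of five categories (financial help,
education, services, core knowledge, other).  The classifier emits five
sigmoid probabilities; membership is decided by a single threshold tuned on
the validation split by macro-F1 grid search over {0.0, 0.1, ..., 1.0}.

The reference backbone is a linear bag-of-words scorer trained with
binary-cross-entropy loss under AdamW (linear warmup, cosine decay, gradient
clipping) — the full optimization recipe of the transformer configuration,
applied to a desk-scale model.  A ``transformer`` backbone value carries the
published hyperparameters but is not runnable here.

The intent classifier maps free text to one of the ten challenging-behavior
categories by scoring matches of the challenging-behavior vocabulary and
taking a softmax; ties resolve to the lowest category index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus import StopList, preprocess_text
from .lexicon import BEHAVIOR_CATEGORIES, CompiledLexicon

logger = logging.getLogger(__name__)

CATEGORIES = ("financial_help", "education", "services", "core_knowledge", "other")

THRESHOLD_GRID = tuple(round(0.1 * i, 1) for i in range(11))  # 0.0 .. 1.0


@dataclass(frozen=True)
class LabeledDocument:
    doc_id: str
    text: str
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("labels must be non-empty")
        unknown = set(self.labels) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {unknown}")


#: AdamW base learning rate / batch size per backbone: the transformer
#: fine-tuning recipe uses 3e-4 and batches of 64; the desk-scale linear
#: bag-of-words model trains from scratch in few steps and needs a larger
#: step size and smaller batches (more optimizer steps per epoch).
BACKBONE_LR = {"transformer": 3e-4, "linear_bow": 0.2}
BACKBONE_BATCH = {"transformer": 64, "linear_bow": 16}


@dataclass(frozen=True)
class ClassifierConfig:
    backbone: str = "linear_bow"
    dropout: float = 0.3
    lr: float | None = None  # None -> BACKBONE_LR[backbone]
    beta1: float = 0.9
    beta2: float = 0.95
    eps: float = 1e-8
    weight_decay: float = 0.01
    batch_size: int | None = None  # None -> BACKBONE_BATCH[backbone]
    grad_clip_norm: float = 1.0
    epochs: int = 20
    loss: str = "binary_cross_entropy"
    seed: int = 0

    @property
    def resolved_lr(self) -> float:
        return BACKBONE_LR[self.backbone] if self.lr is None else self.lr

    @property
    def resolved_batch_size(self) -> int:
        return BACKBONE_BATCH[self.backbone] if self.batch_size is None else self.batch_size


@dataclass
class MultilabelModel:
    vocab: dict[str, int]
    weights: np.ndarray  # (V + 1) x 5, last row = bias
    stops: StopList
    threshold: float = 0.5
    config: ClassifierConfig | None = None

    def _features(self, text: str) -> np.ndarray:
        x = np.zeros(len(self.vocab) + 1)
        for tok in preprocess_text(text, self.stops):
            j = self.vocab.get(tok)
            if j is not None:
                x[j] += 1.0
        x[-1] = 1.0  # bias
        return x

    def predict_proba(self, text: str) -> np.ndarray:
        z = self._features(text) @ self.weights
        return 1.0 / (1.0 + np.exp(-z))


def split_dataset(
    labeled: Sequence[LabeledDocument],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[LabeledDocument], list[LabeledDocument], list[LabeledDocument]]:
    """Iterative-stratification split (train/val/test).

    Documents are assigned label by label, rarest label first, each going to
    the split with the greatest remaining demand for that label — the
    standard heuristic for multilabel stratified splitting.  Deterministic
    for a fixed seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    docs = list(labeled)
    order = rng.permutation(len(docs))
    docs = [docs[i] for i in order]

    n = len(docs)
    desired_total = [r * n for r in ratios]
    desired_label: dict[str, list[float]] = {}
    label_counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    for d in docs:
        for lab in d.labels:
            label_counts[lab] += 1
    for c in CATEGORIES:
        if 0 < label_counts[c] < 3:
            logger.warning("category %r has only %d members; best-effort split", c, label_counts[c])
        desired_label[c] = [r * label_counts[c] for r in ratios]

    splits: tuple[list[LabeledDocument], ...] = ([], [], [])
    remaining = set(range(len(docs)))
    while remaining:
        # label with fewest remaining unassigned examples (and ≥1)
        remaining_counts = {c: 0 for c in CATEGORIES}
        for i in remaining:
            for lab in docs[i].labels:
                remaining_counts[lab] += 1
        candidates = [c for c in CATEGORIES if remaining_counts[c] > 0]
        lab = min(candidates, key=lambda c: (remaining_counts[c], c))
        for i in sorted(i for i in remaining if lab in docs[i].labels):
            # split with greatest demand for this label; ties -> greatest
            # total demand, then lowest split index
            s = max(
                range(3),
                key=lambda k: (desired_label[lab][k], desired_total[k], -k),
            )
            splits[s].append(docs[i])
            remaining.discard(i)
            desired_total[s] -= 1
            for l2 in docs[i].labels:
                desired_label[l2][s] -= 1
    train, val, test = splits
    key = lambda d: d.doc_id
    return sorted(train, key=key), sorted(val, key=key), sorted(test, key=key)


def macro_f1(
    pred: Sequence[set[str] | frozenset[str]],
    truth: Sequence[set[str] | frozenset[str]],
    categories: Sequence[str] = CATEGORIES,
) -> float:
    """Unweighted mean of per-category F1.  A category with no true and no
    predicted positives contributes 0."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth must align")
    f1s = []
    for c in categories:
        tp = sum(1 for p, t in zip(pred, truth) if c in p and c in t)
        fp = sum(1 for p, t in zip(pred, truth) if c in p and c not in t)
        fn = sum(1 for p, t in zip(pred, truth) if c not in p and c in t)
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def _label_matrix(docs: Sequence[LabeledDocument]) -> np.ndarray:
    y = np.zeros((len(docs), len(CATEGORIES)))
    for i, d in enumerate(docs):
        for j, c in enumerate(CATEGORIES):
            if c in d.labels:
                y[i, j] = 1.0
    return y


def _lr_schedule(step: int, total: int, lr: float) -> float:
    """Linear warmup over the first 10% of steps, cosine decay to lr/10."""
    warmup = max(1, total // 10)
    if step < warmup:
        return lr * (step + 1) / warmup
    t = (step - warmup) / max(1, total - warmup)
    return lr / 10 + (lr - lr / 10) * 0.5 * (1 + np.cos(np.pi * t))


def train_multilabel(
    train: Sequence[LabeledDocument],
    val: Sequence[LabeledDocument],
    cfg: ClassifierConfig = ClassifierConfig(),
    stops: StopList | None = None,
) -> MultilabelModel:
    """Train the linear bag-of-words multilabel scorer.

    After each epoch the model is scored on the validation split (macro F1
    at threshold 0.5); the best epoch's weights are returned.  Threshold
    tuning is a separate, later step (:func:`select_threshold`).
    """
    if cfg.backbone != "linear_bow":
        raise NotImplementedError(
            "only the linear_bow backbone is runnable in this build"
        )
    if cfg.epochs < 1:
        raise ValueError("epochs must be >= 1 (no checkpoint otherwise)")
    if not train or not val:
        raise ValueError("train and val must be non-empty")
    stops = stops or StopList.default()

    vocab: dict[str, int] = {}
    token_docs = []
    for d in train:
        toks = preprocess_text(d.text, stops)
        token_docs.append(toks)
        for t in toks:
            vocab.setdefault(t, len(vocab))
    V = len(vocab)
    y = _label_matrix(train)
    if np.all(y == y[0]):
        logger.warning("degenerate training set: every document has identical labels")
    X = np.zeros((len(train), V + 1))
    for i, toks in enumerate(token_docs):
        for t in toks:
            X[i, vocab[t]] += 1.0
    X[:, -1] = 1.0

    rng = np.random.default_rng(cfg.seed)
    W = np.zeros((V + 1, len(CATEGORIES)))
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    batch_size = cfg.resolved_batch_size
    n_batches = int(np.ceil(len(train) / batch_size))
    total_steps = cfg.epochs * n_batches
    step = 0
    # class-balanced BCE: positives of rare categories are up-weighted by
    # the (capped) negative/positive ratio so skewed label profiles do not
    # collapse the rare sigmoid outputs to zero
    pos = y.sum(axis=0)
    pos_weight = np.clip((len(train) - pos) / np.maximum(pos, 1.0), 1.0, 20.0)

    model = MultilabelModel(vocab=vocab, weights=W, stops=stops, config=cfg)
    best = (-1.0, None)
    truth_val = [set(d.labels) for d in val]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train))
        for b in range(n_batches):
            idx = perm[b * batch_size : (b + 1) * batch_size]
            xb, yb = X[idx], y[idx]
            z = xb @ W
            p = 1.0 / (1.0 + np.exp(-z))
            scale = yb * pos_weight + (1.0 - yb)
            g = xb.T @ ((p - yb) * scale) / len(idx)  # weighted BCE gradient
            norm = float(np.linalg.norm(g))
            if norm > cfg.grad_clip_norm:
                g *= cfg.grad_clip_norm / norm
            lr_t = _lr_schedule(step, total_steps, cfg.resolved_lr)
            m = cfg.beta1 * m + (1 - cfg.beta1) * g
            v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
            mhat = m / (1 - cfg.beta1 ** (step + 1))
            vhat = v / (1 - cfg.beta2 ** (step + 1))
            W = W - lr_t * (mhat / (np.sqrt(vhat) + cfg.eps) + cfg.weight_decay * W)
            step += 1
        model.weights = W
        pred = [predict_categories(model, d.text, threshold=0.5) for d in val]
        score = macro_f1(pred, truth_val)
        if score > best[0]:
            best = (score, W.copy())
    model.weights = best[1]
    return model


def select_threshold(
    model: MultilabelModel, val: Sequence[LabeledDocument]
) -> float:
    """Macro-F1 grid search over the 11 thresholds 0.0..1.0 (step 0.1);
    ties resolve to the lowest threshold.  Sets and returns the threshold."""
    probs = [model.predict_proba(d.text) for d in val]
    truth = [set(d.labels) for d in val]
    best_t, best_f1 = THRESHOLD_GRID[0], -1.0
    for t in THRESHOLD_GRID:
        pred = [
            {c for j, c in enumerate(CATEGORIES) if p[j] > t} for p in probs
        ]
        f1 = macro_f1(pred, truth)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    model.threshold = best_t
    return best_t


def predict_categories(
    model: MultilabelModel, text: str, threshold: float | None = None
) -> set[str]:
    """Categories whose probability strictly exceeds the threshold."""
    t = model.threshold if threshold is None else threshold
    p = model.predict_proba(text)
    return {c for j, c in enumerate(CATEGORIES) if p[j] > t}


@dataclass
class IntentModel:
    """Ten-way challenging-behavior intent scorer.

    The default scorer counts challenging-behavior lexicon matches per
    category in the query and softmaxes the counts; any scorer with the same
    text -> 10-distribution contract can be substituted.
    """

    scorer: Callable[[str], np.ndarray]
    categories: tuple[str, ...] = BEHAVIOR_CATEGORIES

    @classmethod
    def from_lexicon(cls, lex: CompiledLexicon, stops: StopList) -> "IntentModel":
        from .lexicon import match_entities
        from .corpus import Document, preprocess

        def scorer(text: str) -> np.ndarray:
            counts = np.zeros(len(BEHAVIOR_CATEGORIES))
            ts = preprocess(Document(doc_id="_q", url="_q", text=text), stops)
            for m in match_entities(ts, lex):
                if m.vocab == "BEHAVIOR" and m.behavior_category:
                    counts[BEHAVIOR_CATEGORIES.index(m.behavior_category)] += 1.0
            e = np.exp(counts - counts.max())
            return e / e.sum()

        return cls(scorer=scorer)


def classify_intent(model: IntentModel, text: str) -> str:
    """Argmax behavior category; ties resolve to the lowest category index."""
    if not text:
        raise ValueError("text must be non-empty")
    dist = np.asarray(model.scorer(text))
    return model.categories[int(np.argmax(dist))]
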