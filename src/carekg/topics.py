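"""LDA topic modeling and the hierarchical topic-model (HTM) recursion.

HTM fits LDA on the whole (sub)corpus, assigns every document to its
dominant topic, and re-fits LDA on any topic whose document count exceeds a
threshold.  Recursion stops when every topic is at or below the threshold,
when a topic absorbs its node's entire document set (no progress), or at a
depth cap.  Only leaf topics enter the knowledge graph; their doc-topic
weights (theta) become belongsToTopic edges, topic-word weights (phi) become
describedBy edges, and the product theta @ phi yields containsNgram weights.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .corpus import TokenStream


@dataclass(frozen=True)
class LDAConfig:
    """Hyperparameters of each LDA fit (scikit-learn online variational
    Bayes): 10 iterations, online learning, decay 0.7, batch 128, vocabulary
    capped at 50,000 features."""

    max_iter: int = 10
    learning: str = "online"
    learning_decay: float = 0.7
    batch_size: int = 128
    max_features: int = 50_000
    seed: int = 0

    def with_seed(self, seed: int) -> "LDAConfig":
        return LDAConfig(
            max_iter=self.max_iter,
            learning=self.learning,
            learning_decay=self.learning_decay,
            batch_size=self.batch_size,
            max_features=self.max_features,
            seed=seed,
        )


@dataclass
class CountMatrix:
    docs: list[str]
    vocab: list[str]
    counts: sparse.csr_matrix  # docs x vocab, raw token counts
    max_features: int


@dataclass
class TopicModel:
    K: int
    theta: np.ndarray  # docs x K, rows sum to 1
    phi: np.ndarray  # K x vocab, rows sum to 1


@dataclass
class HTMNode:
    node_id: str
    doc_ids: list[str]
    model: TopicModel | None
    vocab: list[str]
    assignments: dict[str, int]  # doc_id -> dominant topic index in this node
    children: dict[int, "HTMNode"] = field(default_factory=dict)
    is_leaf_topic: dict[int, bool] = field(default_factory=dict)
    no_progress: bool = False


@dataclass
class LeafTopic:
    label: str  # "T<node>.<index>"
    node_id: str
    topic_index: int
    doc_ids: list[str]  # docs whose dominant topic this is
    theta: np.ndarray  # len(node docs) x 1? -> per node-doc weight for topic
    node_doc_ids: list[str]  # all docs of the node (theta rows align to this)
    phi_row: np.ndarray
    vocab: list[str]


def build_count_matrix(
    streams: Sequence[TokenStream], max_features: int = 50_000
) -> CountMatrix:
    """Count vector per document over the ``max_features`` most frequent
    unigrams; frequency ties break lexicographically."""
    if not streams:
        raise ValueError("empty corpus")
    totals: dict[str, int] = {}
    for ts in streams:
        for tok in ts.tokens:
            totals[tok] = totals.get(tok, 0) + 1
    vocab = sorted(totals, key=lambda w: (-totals[w], w))[:max_features]
    index = {w: j for j, w in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, ts in enumerate(streams):
        local: dict[int, int] = {}
        for tok in ts.tokens:
            j = index.get(tok)
            if j is not None:
                local[j] = local.get(j, 0) + 1
        for j, c in local.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    counts = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(streams), len(vocab)), dtype=np.float64
    )
    return CountMatrix(
        docs=[ts.doc_id for ts in streams],
        vocab=vocab,
        counts=counts,
        max_features=max_features,
    )


def fit_lda(cm: CountMatrix, K: int, cfg: LDAConfig) -> TopicModel:
    """Fit LDA and return row-normalized theta (doc-topic) and phi
    (topic-word); deterministic for a fixed seed."""
    n_docs = len(cm.docs)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n_docs:
        raise ValueError(f"K={K} exceeds number of documents ({n_docs})")
    lda = LatentDirichletAllocation(
        n_components=K,
        max_iter=cfg.max_iter,
        learning_method="online" if cfg.learning == "online" else "batch",
        learning_decay=cfg.learning_decay,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
    )
    theta = lda.fit_transform(cm.counts)
    theta = theta / theta.sum(axis=1, keepdims=True)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(K=K, theta=theta, phi=phi)


def dominant_topic(theta_row: np.ndarray) -> int:
    """Argmax topic; ties go to the lowest index (np.argmax's rule)."""
    return int(np.argmax(theta_row))


def _child_k(n_docs: int, threshold: int) -> int:
    return max(2, math.ceil(n_docs / threshold))


def hierarchical_topic_model(
    streams: Sequence[TokenStream],
    K0: int,
    threshold: int,
    cfg: LDAConfig,
    max_depth: int = 10,
) -> HTMNode:
    """Recursive LDA.  Child nodes use K = max(2, ceil(n_docs/threshold))
    topics so each leaf holds about ``threshold`` documents."""
    if K0 < 2:
        raise ValueError("K0 must be >= 2")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    by_id = {ts.doc_id: ts for ts in streams}

    def build(doc_ids: list[str], node_id: str, K: int, depth: int) -> HTMNode:
        node_streams = [by_id[d] for d in doc_ids]
        cm = build_count_matrix(node_streams, cfg.max_features)
        # stable per-node seed (string hash randomization must not leak in)
        node_tag = zlib.crc32(node_id.encode("utf-8"))
        seed = int(
            np.random.SeedSequence((cfg.seed, depth, node_tag)).generate_state(1)[0]
            % (2**31)
        )
        model = fit_lda(cm, K, cfg.with_seed(seed))
        assignments = {
            d: dominant_topic(model.theta[i]) for i, d in enumerate(doc_ids)
        }
        node = HTMNode(
            node_id=node_id,
            doc_ids=list(doc_ids),
            model=model,
            vocab=cm.vocab,
            assignments=assignments,
        )
        members: dict[int, list[str]] = {t: [] for t in range(K)}
        for d, t in assignments.items():
            members[t].append(d)
        for t, docs_t in members.items():
            recurse = (
                len(docs_t) > threshold
                and depth < max_depth
                and len(docs_t) < len(doc_ids)  # progress was made
                and len(docs_t) >= 2
            )
            if len(docs_t) > threshold and len(docs_t) == len(doc_ids):
                node.no_progress = True
            if recurse:
                node.is_leaf_topic[t] = False
                node.children[t] = build(
                    docs_t,
                    f"{node_id}.{t}",
                    _child_k(len(docs_t), threshold),
                    depth + 1,
                )
            else:
                node.is_leaf_topic[t] = True
        return node

    return build([ts.doc_id for ts in streams], "T0", K0, 1)


def iter_nodes(root: HTMNode) -> Iterator[HTMNode]:
    yield root
    for child in root.children.values():
        yield from iter_nodes(child)


def leaf_topics(root: HTMNode) -> list[LeafTopic]:
    """Every leaf-flagged topic with its member docs and weight vectors.

    By construction the member doc sets of all leaf topics partition the
    corpus (each doc sits in exactly one leaf, via dominant assignment)."""
    leaves: list[LeafTopic] = []
    for node in iter_nodes(root):
        assert node.model is not None
        members: dict[int, list[str]] = {t: [] for t in range(node.model.K)}
        for d, t in node.assignments.items():
            members[t].append(d)
        for t, flag in sorted(node.is_leaf_topic.items()):
            if not flag:
                continue
            leaves.append(
                LeafTopic(
                    label=f"{node.node_id}.{t}",
                    node_id=node.node_id,
                    topic_index=t,
                    doc_ids=members[t],
                    theta=node.model.theta[:, t],
                    node_doc_ids=node.doc_ids,
                    phi_row=node.model.phi[t],
                    vocab=node.vocab,
                )
            )
    return leaves


def contains_ngram_weights(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Document-word weights: the matrix product theta @ phi.  Rows stay
    stochastic because both factors are row-stochastic."""
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if theta.ndim != 2 or phi.ndim != 2 or theta.shape[1] != phi.shape[0]:
        raise ValueError(
            f"shape mismatch: theta {theta.shape} cannot multiply phi {phi.shape}"
        )
    return theta @ phi
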