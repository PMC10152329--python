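"""Free-text resource retrieval with OWA aggregation.

A query is parsed into criteria — controlled-vocabulary entities, an
inferred challenging-behavior category, and unigrams present in the topic
vocabulary.  Every resource connected to at least one criterion node becomes
a candidate; its criterion vector holds the connecting edge weights (0 for
absent edges).  The vector is aggregated with Yager's ordered weighted
averaging operator: values are sorted in descending order and dotted with a
weight vector derived from a regular-increasing-monotone (RIM) linguistic
quantifier, w_i = Q(i/n) - Q((i-1)/n).  MOST (piecewise-linear, a=0.3,
b=0.8) is the default quantifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import IntentModel, classify_intent
from .corpus import Document, StopList, preprocess
from .kg import KnowledgeGraph, entity_node_id
from .lexicon import CompiledLexicon, EntityKey, match_entities

logger = logging.getLogger(__name__)

#: OWA weight vectors are plain numpy arrays summing to 1
OWAWeights = np.ndarray


@dataclass(frozen=True)
class RIMQuantifier:
    """Non-decreasing Q on [0,1] with Q(0)=0 and Q(1)=1.

    ``most`` and ``some`` are piecewise linear between a and b; ``all`` is
    the step at 1 (minimum); ``at_least_n`` steps at n/len; ``identity`` is
    Q(x)=x (arithmetic mean).
    """

    kind: str = "most"
    a: float = 0.3
    b: float = 0.8
    n: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("most", "some", "all", "at_least_n", "identity"):
            raise ValueError(f"unknown quantifier {self.kind!r}")
        if self.kind in ("most", "some") and not (0 <= self.a < self.b <= 1):
            raise ValueError("require 0 <= a < b <= 1")

    @classmethod
    def some(cls, a: float = 0.0, b: float = 0.5) -> "RIMQuantifier":
        return cls(kind="some", a=a, b=b)

    def __call__(self, x: float, length: int | None = None) -> float:
        if x <= 0:
            return 0.0
        if x >= 1:
            return 1.0
        if self.kind in ("most", "some"):
            if x <= self.a:
                return 0.0
            if x >= self.b:
                return 1.0
            return (x - self.a) / (self.b - self.a)
        if self.kind == "identity":
            return x
        if self.kind == "all":
            return 0.0  # jumps to 1 only at x = 1
        # at_least_n: step at n/length (clamped so Q(1) = 1)
        if length is None:
            raise ValueError("at_least_n needs the vector length")
        cut = min(self.n, length) / length
        return 1.0 if x >= cut else 0.0


@dataclass
class QueryTerms:
    entities: list[EntityKey] = field(default_factory=list)
    behavior_category: str | None = None
    unigrams: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.entities or self.behavior_category or self.unigrams)


@dataclass
class RankedResult:
    rows: list[dict]  # resource, doc_id, score, weights, categories, url
    criteria: list[tuple[str, str]]  # (kind, node_id)
    notice: str | None = None


def owa_weights(q: RIMQuantifier, n: int) -> np.ndarray:
    """w_i = Q(i/n) - Q((i-1)/n); telescopes to sum 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    qs = np.array([q(i / n, length=n) for i in range(n + 1)])
    return np.diff(qs)


def owa_aggregate(w: np.ndarray, values: Sequence[float]) -> float:
    """Yager OWA: dot the weights with the values sorted descending."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != values.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {values.shape}")
    return float(np.sort(values)[::-1] @ w)


def parse_query(
    text: str,
    lexicon: CompiledLexicon,
    topic_vocab: set[str],
    intent_model: IntentModel | None,
    stops: StopList | None = None,
) -> QueryTerms:
    """Extract entities, topic-vocabulary unigrams, and the intent category
    from free text."""
    stops = stops or StopList.default()
    terms = QueryTerms()
    if not text.strip():
        return terms
    ts = preprocess(Document(doc_id="_query", url="_query", text=text), stops)
    seen: set[EntityKey] = set()
    for m in match_entities(ts, lexicon):
        if m.key not in seen:
            seen.add(m.key)
            terms.entities.append(m.key)
    seen_u: set[str] = set()
    for tok in ts.tokens:
        if tok in topic_vocab and tok not in seen_u:
            seen_u.add(tok)
            terms.unigrams.append(tok)
    if intent_model is not None:
        terms.behavior_category = classify_intent(intent_model, text)
    return terms


def _criterion_nodes(kg: KnowledgeGraph, terms: QueryTerms) -> list[tuple[str, str]]:
    """(kind, node_id) per criterion, dropping terms without a KG node."""
    criteria: list[tuple[str, str]] = []
    g = kg.graph
    for key in terms.entities:
        nid = entity_node_id(key)
        if nid in g:
            criteria.append(("entity", nid))
        else:
            logger.info("query entity %r has no graph node; dropped", key)
    if terms.behavior_category:
        nid = f"ChallengingBehavior:{terms.behavior_category}"
        if nid in g:
            criteria.append(("behavior", nid))
        else:
            logger.info("behavior category %r has no graph node; dropped",
                        terms.behavior_category)
    for u in terms.unigrams:
        nid = f"Unigram:{u}"
        if nid in g:
            criteria.append(("unigram", nid))
        else:
            logger.info("query unigram %r has no graph node; dropped", u)
    return criteria


_CRITERION_REL = {"entity": "CONTAINS", "behavior": "CONTAINS", "unigram": "containsNgram"}


def retrieve_candidates(
    kg: KnowledgeGraph, terms: QueryTerms
) -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Resources adjacent to >=1 criterion node, with one weight slot per
    criterion (0 where the edge is absent)."""
    criteria = _criterion_nodes(kg, terms)
    vectors: dict[str, np.ndarray] = {}
    for slot, (kind, nid) in enumerate(criteria):
        rel = _CRITERION_REL[kind]
        for src, weight in kg.in_edges(nid, rel):
            if not src.startswith("Resource:"):
                continue
            vec = vectors.setdefault(src, np.zeros(len(criteria)))
            vec[slot] = weight if weight is not None else 0.0
    return vectors, criteria


def rank_resources(
    kg: KnowledgeGraph,
    text: str,
    lexicon: CompiledLexicon,
    topic_vocab: set[str],
    intent_model: IntentModel | None = None,
    quantifier: RIMQuantifier = RIMQuantifier(),
    top_n: int = 10,
    stops: StopList | None = None,
) -> RankedResult:
    """parse -> retrieve -> OWA-aggregate -> sort descending -> truncate.

    Ties in score break by ascending doc_id.  Each row reports the
    resource's category labels alongside its score and criterion weights.
    """
    terms = parse_query(text, lexicon, topic_vocab, intent_model, stops)
    if terms.is_empty():
        return RankedResult(rows=[], criteria=[], notice="no query terms matched")
    vectors, criteria = retrieve_candidates(kg, terms)
    if not criteria:
        return RankedResult(rows=[], criteria=[], notice="no criterion has a graph node")
    w = owa_weights(quantifier, len(criteria))
    scored = []
    for res, vec in vectors.items():
        doc_id = res.split(":", 1)[1]
        scored.append((owa_aggregate(w, vec), doc_id, res, vec))
    scored.sort(key=lambda r: (-r[0], r[1]))
    rows = []
    for score, doc_id, res, vec in scored[:top_n]:
        cats = sorted(
            dst.split(":", 1)[1]
            for dst, _ in kg.out_edges(res, "CONTAINS")
            if dst.startswith("Category:")
        )
        rows.append(
            {
                "resource": res,
                "doc_id": doc_id,
                "url": kg.graph.nodes[res].get("url"),
                "score": score,
                "weights": vec.tolist(),
                "categories": cats,
            }
        )
    return RankedResult(rows=rows, criteria=criteria)
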