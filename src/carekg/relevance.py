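"""Pivoted-unique-normalized entity relevance weights.

The weight of an entity in a document is its log-damped term frequency
divided by the pivoted unique normalization factor:

    relevance(tf, dl) = (1 + log tf) / ((1 - slope) * pivot + slope * dl)

where ``tf`` is the entity's frequency in the document, ``dl`` the number of
DISTINCT entities in the document (the "unique" document length), and
``pivot`` the collection average of ``dl``.  At ``dl == pivot`` the
normalization factor equals the pivot, so average-length documents are
neither penalized nor rewarded; longer documents are penalized, shorter
rewarded, with strength controlled by ``slope`` (default 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .lexicon import EntityFrequencyTable


@dataclass(frozen=True)
class RelevanceParams:
    slope: float = 0.2
    pivot: float = 1.0
    log_base: str = "natural"  # or "ten"

    def __post_init__(self) -> None:
        if not 0.0 <= self.slope < 1.0:
            raise ValueError("slope must be in [0, 1)")
        if self.pivot <= 0:
            raise ValueError("pivot must be positive")
        if self.log_base not in ("natural", "ten"):
            raise ValueError("log_base must be 'natural' or 'ten'")


@dataclass(frozen=True)
class RelevanceScore:
    doc_id: str
    canonical: str
    vocab: str
    weight: float


def compute_pivot(freq: EntityFrequencyTable) -> float:
    """Arithmetic mean of distinct-entity counts over ALL documents of the
    collection, zero-entity documents included."""
    counts = freq.distinct_entities
    if not counts or not any(counts.values()):
        raise ValueError("corpus has no entity mentions; pivot undefined")
    return sum(counts.values()) / len(counts)


def entity_relevance(tf: int, dl: int, params: RelevanceParams) -> float:
    """Evaluate the relevance weight for one (document, entity) pair."""
    if tf < 1:
        raise ValueError("tf must be >= 1 (absent entities get no edge)")
    if dl < 1:
        raise ValueError("dl must be >= 1")
    log = math.log if params.log_base == "natural" else math.log10
    denom = (1.0 - params.slope) * params.pivot + params.slope * dl
    return (1.0 + log(tf)) / denom


def score_table(
    freq: EntityFrequencyTable, params: RelevanceParams
) -> list[RelevanceScore]:
    """Relevance weight for every (document, entity) pair in the table."""
    scores = []
    for (doc_id, canonical, vocab), tf in sorted(freq.tf.items()):
        dl = freq.distinct_entities[doc_id]
        scores.append(
            RelevanceScore(
                doc_id=doc_id,
                canonical=canonical,
                vocab=vocab,
                weight=entity_relevance(tf, dl, params),
            )
        )
    return scores
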