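"""End-to-end annotation pipeline: corpus -> annotations -> knowledge graph.

Single entry point used by the CLI, the examples, and the acceptance
script.  Each stage is the corresponding module's public operation; the
pipeline only wires them together and collects a manifest (pivot, slope,
seeds, thresholds, sparsification floor) for reproducibility.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

from .classify import (
    ClassifierConfig,
    IntentModel,
    LabeledDocument,
    MultilabelModel,
    select_threshold,
    split_dataset,
    train_multilabel,
)
from .corpus import Document, StopList, preprocess_corpus
from .kg import KnowledgeGraph, build_graph
from .lexicon import (
    CompiledLexicon,
    LexiconEntry,
    compile_lexicon,
    count_frequencies,
    cooccurrences,
    match_entities,
)
from .locations import Gazetteer, LocationWeights, detect_locations, location_weights
from .relevance import RelevanceParams, compute_pivot, score_table
from .topics import LDAConfig, hierarchical_topic_model, leaf_topics


@dataclass
class PipelineConfig:
    slope: float = 0.2
    log_base: str = "natural"
    K0: int = 10  # initial topic count (200/300 at full corpus scale)
    topic_threshold: int = 300
    lda: LDAConfig = field(default_factory=LDAConfig)
    weight_floor: float = 1e-3
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    kg: KnowledgeGraph
    pivot: float
    streams: list
    mentions: list
    freq: object
    leaves: list
    topic_vocab: set[str]
    lexicon: CompiledLexicon
    intent_model: IntentModel
    classifier: MultilabelModel | None
    stops: StopList


def run_pipeline(
    docs: Sequence[Document],
    lexicon_entries: Sequence[LexiconEntry],
    gazetteer: Gazetteer | None = None,
    labeled: Sequence[LabeledDocument] | None = None,
    cfg: PipelineConfig | None = None,
    stops: StopList | None = None,
) -> PipelineResult:
    """Annotate ``docs`` and assemble the weighted knowledge graph."""
    cfg = cfg or PipelineConfig()
    stops = stops or StopList.default()

    # NER
    lex = compile_lexicon(lexicon_entries, stops)
    streams = preprocess_corpus(docs, stops)
    mentions = [m for ts in streams for m in match_entities(ts, lex)]
    freq = count_frequencies(mentions, doc_ids=[d.doc_id for d in docs])
    cooccur = cooccurrences(mentions)

    # pivoted-unique-normalized relevance
    pivot = compute_pivot(freq)
    params = RelevanceParams(slope=cfg.slope, pivot=pivot, log_base=cfg.log_base)
    scores = score_table(freq, params)

    # hierarchical topic model (leaf topics only)
    lda_cfg = cfg.lda.with_seed(cfg.seed)
    root = hierarchical_topic_model(streams, cfg.K0, cfg.topic_threshold, lda_cfg)
    leaves = leaf_topics(root)
    topic_vocab = {
        leaf.vocab[j]
        for leaf in leaves
        for j in range(len(leaf.vocab))
        if leaf.phi_row[j] >= cfg.weight_floor
    }

    # classification
    classifier = None
    categories: dict[str, dict[str, float]] = {}
    if labeled:
        train, val, test = split_dataset(labeled, seed=cfg.seed)
        classifier = train_multilabel(train, val, cfg.classifier, stops=stops)
        select_threshold(classifier, val)
        for d in docs:
            probs = classifier.predict_proba(d.text)
            accepted = {
                c: float(p)
                for c, p in zip(
                    ("financial_help", "education", "services", "core_knowledge", "other"),
                    probs,
                )
                if p > classifier.threshold
            }
            if accepted:
                categories[d.doc_id] = accepted

    # locations
    loc_weights: list[LocationWeights] = []
    if gazetteer is not None:
        for d in docs:
            resolved = detect_locations(d, gazetteer, stops)
            if resolved:
                loc_weights.append(location_weights(d.doc_id, resolved))

    manifest = {
        "pivot": pivot,
        "slope": cfg.slope,
        "log_base": cfg.log_base,
        "K0": cfg.K0,
        "topic_threshold": cfg.topic_threshold,
        "weight_floor": cfg.weight_floor,
        "seed": cfg.seed,
        "classifier_threshold": classifier.threshold if classifier else None,
        "built": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    kg = build_graph(
        docs=docs,
        mentions=mentions,
        relevance_scores=scores,
        cooccur=cooccur,
        leaves=leaves,
        categories=categories,
        location_weights=loc_weights,
        weight_floor=cfg.weight_floor,
        manifest=manifest,
    )
    intent_model = IntentModel.from_lexicon(lex, stops)
    return PipelineResult(
        kg=kg,
        pivot=pivot,
        streams=streams,
        mentions=mentions,
        freq=freq,
        leaves=leaves,
        topic_vocab=topic_vocab,
        lexicon=lex,
        intent_model=intent_model,
        classifier=classifier,
        stops=stops,
    )
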