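"""Controlled-vocabulary lexicons and dictionary-based entity recognition.

Lexicon surface forms are compiled through the same preprocessing pipeline as
the documents, so matching happens in lemma space.  Extraction is a
deterministic longest-match, left-to-right scan with consumed spans — the
behaviour of standard rule-based phrase matchers.  Distinct vocabularies may
contribute entries for the same lemma sequence; such a collision emits one
mention per colliding entry at the same span.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .corpus import StopList, TokenStream, preprocess_text

logger = logging.getLogger(__name__)

VOCABULARIES = ("HPO", "UMLS", "ERIC", "AIRS", "AGE", "LOCATION", "BEHAVIOR")

#: the ten challenging-behavior categories, in canonical (tie-break) order
BEHAVIOR_CATEGORIES = (
    "sleep issues",
    "sensory issues",
    "hyperactivity",
    "inattention",
    "repetitive behavior",
    "speech and language development",
    "adaptive behavior",
    "cognitive development",
    "social skills",
    "behavioral concerns",
)

#: entity key used throughout: (canonical term, vocabulary label)
EntityKey = tuple[str, str]


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical: str
    vocab: str
    concept_id: str | None = None
    behavior_category: str | None = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty surface form")
        if self.vocab not in VOCABULARIES:
            raise ValueError(f"unknown vocabulary {self.vocab!r}")
        if (self.vocab == "BEHAVIOR") != (self.behavior_category is not None):
            raise ValueError("behavior_category present iff vocab == BEHAVIOR")
        if self.behavior_category is not None and self.behavior_category not in BEHAVIOR_CATEGORIES:
            raise ValueError(f"unknown behavior category {self.behavior_category!r}")

    @property
    def key(self) -> EntityKey:
        return (self.canonical, self.vocab)


@dataclass
class CompiledLexicon:
    patterns: dict[tuple[str, ...], list[LexiconEntry]]
    max_pattern_length: int


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    canonical: str
    vocab: str
    token_span: tuple[int, int]
    concept_id: str | None = None
    behavior_category: str | None = None

    @property
    def key(self) -> EntityKey:
        return (self.canonical, self.vocab)


@dataclass
class EntityFrequencyTable:
    """Per-document term frequencies and distinct-entity counts.

    ``distinct_entities`` covers every document of the collection, including
    documents without a single mention (those enter the pivot average at 0).
    """

    tf: dict[tuple[str, str, str], int]  # (doc_id, canonical, vocab) -> count
    distinct_entities: dict[str, int]

    def doc_tf(self, doc_id: str) -> dict[EntityKey, int]:
        return {
            (canon, vocab): n
            for (d, canon, vocab), n in self.tf.items()
            if d == doc_id
        }


@dataclass
class CooccurrenceTable:
    counts: dict[frozenset[EntityKey], int]

    def get(self, a: EntityKey, b: EntityKey) -> int:
        return self.counts.get(frozenset((a, b)), 0)


def load_lexicon_csv(path: str | Path) -> list[LexiconEntry]:
    """Read a lexicon table (columns: surface, canonical, vocab,
    optional concept_id / behavior_category)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            LexiconEntry(
                surface=row.surface,
                canonical=row.canonical,
                vocab=row.vocab,
                concept_id=getattr(row, "concept_id", "") or None,
                behavior_category=getattr(row, "behavior_category", "") or None,
            )
        )
    return entries


def compile_lexicon(
    entries: Iterable[LexiconEntry], stops: StopList
) -> CompiledLexicon:
    """Preprocess every surface form and index entries by lemma sequence.

    An entry whose surface reduces to no tokens (e.g. a pure stop word) is
    dropped with a warning.
    """
    patterns: dict[tuple[str, ...], list[LexiconEntry]] = defaultdict(list)
    for entry in entries:
        toks = tuple(preprocess_text(entry.surface, stops))
        if not toks:
            logger.warning(
                "lexicon surface %r (%s) reduces to empty token sequence; dropped",
                entry.surface,
                entry.vocab,
            )
            continue
        # surfaces of the same entity that collapse to one lemma sequence
        # (e.g. "child"/"children") are one pattern entry; genuinely
        # different entities sharing a lemma sequence are all retained
        if any(e.key == entry.key for e in patterns[toks]):
            continue
        patterns[toks].append(entry)
    if not patterns:
        raise ValueError("no lexicon entry survived preprocessing")
    return CompiledLexicon(
        patterns=dict(patterns),
        max_pattern_length=max(len(p) for p in patterns),
    )


def match_entities(ts: TokenStream, lex: CompiledLexicon) -> list[EntityMention]:
    """Longest-match, left-to-right, non-overlapping phrase matching."""
    tokens = ts.tokens
    n = len(tokens)
    mentions: list[EntityMention] = []
    i = 0
    while i < n:
        matched = False
        for length in range(min(lex.max_pattern_length, n - i), 0, -1):
            entries = lex.patterns.get(tuple(tokens[i : i + length]))
            if entries:
                for e in entries:
                    mentions.append(
                        EntityMention(
                            doc_id=ts.doc_id,
                            canonical=e.canonical,
                            vocab=e.vocab,
                            concept_id=e.concept_id,
                            behavior_category=e.behavior_category,
                            token_span=(i, i + length),
                        )
                    )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def count_frequencies(
    mentions: Iterable[EntityMention],
    doc_ids: Iterable[str] | None = None,
) -> EntityFrequencyTable:
    """Term frequencies per (document, entity); distinct entities per doc.

    ``doc_ids`` fixes the document universe so that mention-free documents
    appear with distinct count 0 (they participate in the pivot average).
    """
    tf: Counter[tuple[str, str, str]] = Counter()
    for m in mentions:
        tf[(m.doc_id, m.canonical, m.vocab)] += 1
    distinct: dict[str, int] = {d: 0 for d in doc_ids} if doc_ids is not None else {}
    per_doc: defaultdict[str, set[EntityKey]] = defaultdict(set)
    for (d, canon, vocab) in tf:
        per_doc[d].add((canon, vocab))
    for d, keys in per_doc.items():
        distinct[d] = len(keys)
    return EntityFrequencyTable(tf=dict(tf), distinct_entities=distinct)


def cooccurrences(
    mentions: Iterable[EntityMention], scope: str = "document"
) -> CooccurrenceTable:
    """Count, per unordered entity pair, the number of documents containing
    both — once per document regardless of mention multiplicity."""
    if scope != "document":
        raise ValueError("only document-level co-occurrence is defined")
    per_doc: defaultdict[str, set[EntityKey]] = defaultdict(set)
    for m in mentions:
        per_doc[m.doc_id].add(m.key)
    counts: Counter[frozenset[EntityKey]] = Counter()
    for keys in per_doc.values():
        ordered = sorted(keys)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                counts[frozenset((a, b))] += 1
    return CooccurrenceTable(counts=dict(counts))


def group_by_doc(mentions: Iterable[EntityMention]) -> dict[str, list[EntityMention]]:
    grouped: defaultdict[str, list[EntityMention]] = defaultdict(list)
    for m in mentions:
        grouped[m.doc_id].append(m)
    return dict(grouped)
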