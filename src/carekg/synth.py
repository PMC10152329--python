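"""Synthetic study fixtures: lexicons, gazetteer, corpus, labels.

The generator emulates the statistical structure the pipeline assumes:
documents are drawn from planted topic mixtures over disjoint topic
vocabularies; controlled-vocabulary surface forms (including inflected
variants, so the lemmatization path is exercised) are injected at a
configured rate; category marker tokens encode planted multilabel
assignments; postal codes and place names encode planted locations.  All
planted quantities are recorded as ground truth, and every artifact is a
deterministic function of (config, seed).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._lemma import lemmatize
from .classify import CATEGORIES, LabeledDocument
from .corpus import Document, StopList
from .lexicon import BEHAVIOR_CATEGORIES, LexiconEntry

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: default planted locations: (Canadian FSA, city, province)
DEFAULT_LOCATION_POOL = (
    ("T6G", "Edmonton", "Alberta"),
    ("T2P", "Calgary", "Alberta"),
    ("V5K", "Vancouver", "British Columbia"),
    ("M5V", "Toronto", "Ontario"),
)

#: lemma-stable marker token per category (appended to documents that carry
#: the label, so a linear bag-of-words model can separate the categories)
DEFAULT_CATEGORY_MARKERS = {
    "financial_help": "finmark",
    "education": "edumark",
    "services": "servmark",
    "core_knowledge": "coremark",
    "other": "othermark",
}

#: class-imbalance profile of the hand-labeled study data
#: (financial_help, education, services, core_knowledge, other) over 2158
LABEL_PROFILE = {
    "financial_help": 116 / 2158,
    "education": 420 / 2158,
    "services": 1419 / 2158,
    "core_knowledge": 1024 / 2158,
    "other": 143 / 2158,
}


@dataclass(frozen=True)
class SynthConfig:
    n_docs: int = 300
    n_topics_planted: int = 3
    vocab_per_topic: int = 15
    n_entities_per_vocab: int = 10
    vocab_overlap: int = 2  # canonical terms shared HPO/UMLS (etc.)
    entity_injection_rate: float = 0.05  # expected mentions / doc / entity
    doc_length_mean: float = 60.0  # negative binomial, dispersion 5
    doc_length_dispersion: float = 5.0
    topic_alpha: float = 0.1  # Dirichlet concentration of doc mixtures
    location_rate: float = 0.3  # fraction of docs with planted locations
    marker_repeats: int = 3
    label_noise: float = 0.0
    category_marker_map: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MARKERS))
    location_pool: tuple = DEFAULT_LOCATION_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_docs", "n_topics_planted", "vocab_per_topic", "n_entities_per_vocab"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vocab_overlap > self.n_entities_per_vocab:
            raise ValueError("vocab_overlap cannot exceed n_entities_per_vocab")


@dataclass
class GroundTruth:
    topic_mixtures: dict[str, list[float]] = field(default_factory=dict)
    entity_counts: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    labels: dict[str, frozenset[str]] = field(default_factory=dict)
    locations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    topic_vocab: list[list[str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "topic_mixtures": self.topic_mixtures,
                "entity_counts": {
                    d: {f"{c}|{v}": n for (c, v), n in counts.items()}
                    for d, counts in self.entity_counts.items()
                },
                "labels": {d: sorted(l) for d, l in self.labels.items()},
                "locations": {d: locs for d, locs in self.locations.items()},
                "topic_vocab": self.topic_vocab,
            },
            indent=2,
        )


def _pseudo_word(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


def _word_pool(rng: np.random.Generator, n: int, taken: set[str], stops: StopList) -> list[str]:
    """n distinct pseudo-words that are lemma fixed points, collision-free in
    lemma space, and not stop words."""
    out: list[str] = []
    while len(out) < n:
        w = _pseudo_word(rng)
        if w in taken or w in stops or lemmatize(w) != w:
            continue
        # guard against another word lemmatizing onto this one later
        taken.add(w)
        taken.add(w + "s")
        out.append(w)
    return out


@dataclass
class SynthFixture:
    """Everything the pipeline consumes, plus ground truth."""

    documents: list[Document]
    lexicon_entries: list[LexiconEntry]
    gazetteer_rows: list[dict]
    labeled: list[LabeledDocument]
    truth: GroundTruth
    config: SynthConfig


def generate_lexicons(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[list[LexiconEntry], list[dict]]:
    """Synthetic HPO/UMLS/ERIC/AIRS/BEHAVIOR/AGE lexicons and gazetteer.

    ``cfg.vocab_overlap`` canonical terms are shared between HPO and UMLS so
    that IS_ASSOCIATED_WITH edges are exercised.  Every surface form
    survives compilation (none reduces to an empty token sequence).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    stops = StopList.default()
    taken: set[str] = set()
    entries: list[LexiconEntry] = []

    vocabs = ("HPO", "UMLS", "ERIC", "AIRS")
    shared = _word_pool(rng, cfg.vocab_overlap, taken, stops)
    for vi, vocab in enumerate(vocabs):
        n_own = cfg.n_entities_per_vocab - (cfg.vocab_overlap if vocab in ("HPO", "UMLS") else 0)
        words = _word_pool(rng, n_own, taken, stops)
        canon_words = (shared if vocab in ("HPO", "UMLS") else []) + words
        for i, wbase in enumerate(canon_words):
            canonical = wbase
            cid = f"{vocab[0]}{vi}{i:04d}"
            entries.append(LexiconEntry(surface=canonical, canonical=canonical, vocab=vocab, concept_id=cid))
            # inflected variant: plural surface resolving to the same lemma
            entries.append(LexiconEntry(surface=canonical + "s", canonical=canonical, vocab=vocab, concept_id=cid))
    for cat in BEHAVIOR_CATEGORIES:
        entries.append(
            LexiconEntry(surface=cat, canonical=cat, vocab="BEHAVIOR", behavior_category=cat)
        )
        w = _word_pool(rng, 1, taken, stops)[0]
        entries.append(
            LexiconEntry(surface=w, canonical=cat, vocab="BEHAVIOR", behavior_category=cat)
        )
    for canonical, surfaces in (
        ("child", ("child", "children", "kid")),
        ("teen", ("teen", "teenager", "adolescent")),
        ("adult", ("adult", "adults")),
    ):
        for s in surfaces:
            entries.append(LexiconEntry(surface=s, canonical=canonical, vocab="AGE"))

    gazetteer_rows = []
    seen_provinces: set[str] = set()
    for prefix, city, province in cfg.location_pool:
        gazetteer_rows.append(
            {"kind": "postal_prefix", "key": prefix, "city": city, "province": province}
        )
        gazetteer_rows.append(
            {"kind": "name", "key": city, "city": city, "province": province}
        )
        if province not in seen_provinces:
            seen_provinces.add(province)
            gazetteer_rows.append(
                {"kind": "name", "key": province, "city": "", "province": province}
            )
    return entries, gazetteer_rows


def generate_corpus(
    cfg: SynthConfig,
    entries: list[LexiconEntry],
    seed: int | None = None,
) -> tuple[list[Document], GroundTruth]:
    """Planted-structure corpus.

    Per document: a Dirichlet topic mixture over disjoint topic
    vocabularies; Poisson(``entity_injection_rate``) injected mentions per
    entity (surface forms, including plurals); ``marker_repeats`` category
    marker tokens per planted label; a postal code and place-name pair per
    planted location mention.
    """
    base = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng = np.random.default_rng(base)
    stops = StopList.default()
    taken = {e.surface for e in entries} | {e.canonical for e in entries}
    taken |= set(cfg.category_marker_map.values())

    topic_vocab = [
        _word_pool(rng, cfg.vocab_per_topic, taken, stops)
        for _ in range(cfg.n_topics_planted)
    ]

    # one entry per distinct (canonical, vocab); injection writes a surface
    by_key: dict[tuple[str, str], list[str]] = {}
    for e in entries:
        if e.vocab in ("HPO", "UMLS", "ERIC", "AIRS", "BEHAVIOR", "AGE"):
            by_key.setdefault((e.canonical, e.vocab), []).append(e.surface)
    canon_vocabs: dict[str, list[str]] = {}
    for canonical, vocab in by_key:
        canon_vocabs.setdefault(canonical, []).append(vocab)

    truth = GroundTruth(topic_vocab=topic_vocab)
    docs: list[Document] = []
    p_len = cfg.doc_length_dispersion / (cfg.doc_length_dispersion + cfg.doc_length_mean)
    label_probs = np.array([LABEL_PROFILE[c] for c in CATEGORIES])

    for i in range(cfg.n_docs):
        doc_id = f"doc{i:04d}"
        theta = rng.dirichlet([cfg.topic_alpha] * cfg.n_topics_planted)
        length = max(10, int(rng.negative_binomial(cfg.doc_length_dispersion, p_len)))
        topics = rng.choice(cfg.n_topics_planted, size=length, p=theta)
        words = [
            topic_vocab[t][rng.integers(len(topic_vocab[t]))] for t in topics
        ]

        entity_counts: dict[tuple[str, str], int] = {}
        injected: list[str] = []
        # inject once per canonical term: a shared canonical surface matches
        # under every vocabulary carrying it, so ground truth counts each
        # injection for all of them
        for canonical in sorted(canon_vocabs):
            surfaces = sorted(
                {s for v in canon_vocabs[canonical] for s in by_key[(canonical, v)]}
            )
            k = rng.poisson(cfg.entity_injection_rate)
            if k == 0:
                continue
            for _ in range(k):
                injected.append(surfaces[rng.integers(len(surfaces))])
            for v in canon_vocabs[canonical]:
                entity_counts[(canonical, v)] = entity_counts.get((canonical, v), 0) + k

        labels = {c for c, p in zip(CATEGORIES, label_probs) if rng.random() < p}
        if not labels:
            labels = {"services"}
        marker_tokens = []
        for c in sorted(labels):
            marker_tokens += [cfg.category_marker_map[c]] * cfg.marker_repeats

        loc_tokens: list[str] = []
        locations: list[tuple[str, str]] = []
        if rng.random() < cfg.location_rate:
            n_loc = int(rng.integers(1, 4))
            for _ in range(n_loc):
                prefix, city, province = cfg.location_pool[
                    rng.integers(len(cfg.location_pool))
                ]
                if rng.random() < 0.5:
                    loc_tokens.append(f"{prefix} {rng.integers(1,9)}A{rng.integers(1,9)}")
                else:
                    loc_tokens.append(city)
                locations.append((city, province))

        body = list(words)
        for chunk in injected + marker_tokens + loc_tokens:
            pos = int(rng.integers(len(body) + 1))
            body.insert(pos, chunk)
        text = " ".join(body)

        docs.append(
            Document(
                doc_id=doc_id,
                url=f"https://example.org/resources/{doc_id}",
                text=text,
                source="caregiver" if i % 2 == 0 else "inform_alberta",
            )
        )
        truth.topic_mixtures[doc_id] = theta.tolist()
        truth.entity_counts[doc_id] = entity_counts
        truth.labels[doc_id] = frozenset(labels)
        truth.locations[doc_id] = locations
    return docs, truth


def generate_labeled_set(
    cfg: SynthConfig,
    docs: list[Document],
    truth: GroundTruth,
    seed: int | None = None,
) -> list[LabeledDocument]:
    """Labeled documents from the planted assignments, with an optional
    label-noise rate (a noisy document swaps its label set for a random
    single label)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    labeled = []
    for d in docs:
        labels = truth.labels[d.doc_id]
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            labels = frozenset({CATEGORIES[rng.integers(len(CATEGORIES))]})
        labeled.append(LabeledDocument(doc_id=d.doc_id, text=d.text, labels=labels))
    return labeled


def generate_fixture(cfg: SynthConfig) -> SynthFixture:
    """Full fixture: lexicons, gazetteer, corpus, labels, ground truth."""
    ss = np.random.SeedSequence(cfg.seed)
    s_lex, s_corpus, s_labels = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    entries, gaz = generate_lexicons(cfg, seed=s_lex)
    docs, truth = generate_corpus(cfg, entries, seed=s_corpus)
    labeled = generate_labeled_set(cfg, docs, truth, seed=s_labels)
    return SynthFixture(
        documents=docs,
        lexicon_entries=entries,
        gazetteer_rows=gaz,
        labeled=labeled,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# file emission (CLI `carekg synth`)


def write_fixture(fix: SynthFixture, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    corpus_path = out / "corpus.jsonl"
    with corpus_path.open("w", encoding="utf-8") as fh:
        for d in fix.documents:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "url": d.url,
                        "text": d.text,
                        "source": d.source,
                        "resource_type": d.resource_type,
                    }
                )
                + "\n"
            )
    paths["corpus"] = corpus_path

    lex_path = out / "lexicon.csv"
    with lex_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["surface", "canonical", "vocab", "concept_id", "behavior_category"]
        )
        w.writeheader()
        for e in fix.lexicon_entries:
            w.writerow(
                {
                    "surface": e.surface,
                    "canonical": e.canonical,
                    "vocab": e.vocab,
                    "concept_id": e.concept_id or "",
                    "behavior_category": e.behavior_category or "",
                }
            )
    paths["lexicon"] = lex_path

    gaz_path = out / "gazetteer.csv"
    with gaz_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["kind", "key", "city", "province"])
        w.writeheader()
        for row in fix.gazetteer_rows:
            w.writerow(row)
    paths["gazetteer"] = gaz_path

    labels_path = out / "labels.csv"
    with labels_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["doc_id", "labels"])
        for ld in fix.labeled:
            w.writerow([ld.doc_id, "|".join(sorted(ld.labels))])
    paths["labels"] = labels_path

    truth_path = out / "ground_truth.json"
    truth_path.write_text(fix.truth.to_json())
    paths["ground_truth"] = truth_path
    return paths
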