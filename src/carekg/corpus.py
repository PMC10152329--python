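"""Corpus loading and text preprocessing.

Documents are cleaned web-resource texts, one record per URL.  Preprocessing
follows the annotation pipeline's five steps: strip punctuation, lowercase,
tokenize on whitespace, lemmatize, remove stop words.  Hyphens count as
punctuation, so hyphenated words split.  The resulting :class:`TokenStream`
keeps a character span into the original text for every surviving token, so
entity mentions can always be traced back to the source document.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._lemma import lemmatize

logger = logging.getLogger(__name__)

SOURCES = ("caregiver", "inform_alberta", "other")
RESOURCE_TYPES = ("webpage", "video", "pdf")


@dataclass(frozen=True)
class Document:
    """One cleaned resource text.

    ``parent_id`` links a scraped page back to its home-page resource and
    becomes a ``hasParent`` edge in the knowledge graph.
    """

    doc_id: str
    url: str
    text: str
    source: str = "other"
    parent_id: str | None = None
    resource_type: str = "webpage"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.resource_type not in RESOURCE_TYPES:
            raise ValueError(f"unknown resource_type {self.resource_type!r}")


@dataclass
class TokenStream:
    doc_id: str
    tokens: list[str]
    raw_token_offsets: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.tokens)


@dataclass
class StopList:
    """Standard English stop words plus configurable additions."""

    words: frozenset[str]

    @classmethod
    def default(cls, extra: Iterable[str] = ()) -> "StopList":
        words = frozenset(ENGLISH_STOP_WORDS) | {w.lower().strip() for w in extra}
        return cls(words=words)

    @classmethod
    def from_file(cls, path: str | Path) -> "StopList":
        extra = [
            line.strip()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        return cls.default(extra)

    def __contains__(self, word: str) -> bool:
        return word in self.words


def _doc_id_for(url: str) -> str:
    return hashlib.sha1(url.encode("utf-8")).hexdigest()[:16]


def _document_from_record(rec: dict, parent_ids: dict[str, str]) -> Document:
    url = rec["url"]
    doc_id = rec.get("doc_id") or _doc_id_for(url)
    parent = rec.get("parent_id")
    if parent is None and rec.get("parent_url"):
        parent = parent_ids.get(rec["parent_url"], _doc_id_for(rec["parent_url"]))
    return Document(
        doc_id=doc_id,
        url=url,
        text=rec["text"],
        source=rec.get("source", "other"),
        parent_id=parent,
        resource_type=rec.get("resource_type", "webpage"),
    )


def load_corpus(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Load a corpus from JSONL (one object per line) or a directory of .txt.

    Records with empty text are skipped (counted in a log message); malformed
    records are skipped with a per-record warning; duplicate doc_ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[dict] = []
    if format == "jsonl":
        for lineno, line in enumerate(
            path.read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                if "url" not in rec or "text" not in rec:
                    raise KeyError("record needs url and text")
            except (json.JSONDecodeError, KeyError) as exc:
                logger.warning("skipping malformed record at line %d: %s", lineno, exc)
                continue
            records.append(rec)
    elif format == "directory":
        for p in sorted(path.glob("*.txt")):
            records.append({"url": p.stem, "doc_id": p.stem, "text": p.read_text(encoding="utf-8")})
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    # pre-compute ids so parent_url references resolve regardless of order
    parent_ids = {r["url"]: (r.get("doc_id") or _doc_id_for(r["url"])) for r in records}

    docs: list[Document] = []
    seen: set[str] = set()
    n_empty = 0
    for rec in records:
        if not rec["text"].strip():
            n_empty += 1
            continue
        doc = _document_from_record(rec, parent_ids)
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r} (url {doc.url!r})")
        seen.add(doc.doc_id)
        docs.append(doc)
    if n_empty:
        logger.info("skipped %d record(s) with empty text", n_empty)
    return docs


def _is_punct(ch: str) -> bool:
    # everything that is neither alphanumeric nor whitespace is treated as
    # punctuation (covers Unicode P* and S* categories, incl. hyphens)
    return not (ch.isalnum() or ch.isspace())


_WORD_RE = re.compile(r"\S+")


def preprocess(doc: Document, stops: StopList) -> TokenStream:
    """Punctuation removal, lowercasing, tokenization, lemmatization, stops.

    Punctuation characters are replaced by spaces in place, so token spans
    index the original text.  A token is dropped when its surface form or its
    lemma is on the stop list; order of the survivors is preserved.
    """
    cleaned = "".join(" " if _is_punct(ch) else ch for ch in doc.text).lower()
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    for m in _WORD_RE.finditer(cleaned):
        surface = m.group()
        lemma = lemmatize(surface)
        if surface in stops or lemma in stops:
            continue
        tokens.append(lemma)
        offsets.append((m.start(), m.end()))
    return TokenStream(doc_id=doc.doc_id, tokens=tokens, raw_token_offsets=offsets)


def preprocess_text(text: str, stops: StopList) -> list[str]:
    """Preprocess a bare string (queries, lexicon surfaces)."""
    return preprocess(Document(doc_id="_", url="_", text=text), stops).tokens


def preprocess_corpus(docs: Sequence[Document], stops: StopList) -> list[TokenStream]:
    return [preprocess(d, stops) for d in docs]
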