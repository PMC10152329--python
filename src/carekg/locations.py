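"""Location detection: postal-code regexes plus an offline gazetteer.

Canadian postal codes resolve through their forward-sortation area (first
three characters); US ZIP codes through the full five digits.  Place-name
mentions resolve through a lemmatized name table.  Every resolved mention of
a document contributes to proportional weights: a city's weight is its share
of the document's city mentions, and likewise for provinces (a province
inferred from a city resolution counts once in the province pool).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus import Document, StopList, preprocess, preprocess_text

logger = logging.getLogger(__name__)

# letter-digit-letter [space] digit-letter-digit, case-insensitive
_CA_POSTAL = r"[A-Za-z]\d[A-Za-z] ?\d[A-Za-z]\d"
# 5 digits with optional -4 extension
_US_ZIP = r"\d{5}(?:-\d{4})?"
_POSTAL_RE = re.compile(
    rf"(?<![A-Za-z0-9])({_CA_POSTAL}|{_US_ZIP})(?![A-Za-z0-9-])"
)


@dataclass
class Gazetteer:
    """Offline postal-prefix and place-name lookup table."""

    postal_map: dict[str, tuple[str, str]]  # FSA or ZIP -> (city, province)
    name_map: dict[tuple[str, ...], tuple[str | None, str]]  # lemmas -> (city?, province)

    @classmethod
    def from_csv(cls, path: str | Path, stops: StopList) -> "Gazetteer":
        """Columns: kind {postal_prefix, zip, name}, key, city, province.
        Name keys are lemmatized with the corpus pipeline.  The first entry
        for a duplicate key wins (logged)."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        postal: dict[str, tuple[str, str]] = {}
        names: dict[tuple[str, ...], tuple[str | None, str]] = {}
        for row in df.itertuples(index=False):
            if row.kind in ("postal_prefix", "zip"):
                key = row.key.upper().replace(" ", "")
                if key in postal:
                    logger.warning("duplicate postal key %r; first entry wins", key)
                    continue
                postal[key] = (row.city, row.province)
            elif row.kind == "name":
                toks = tuple(preprocess_text(row.key, stops))
                if not toks:
                    logger.warning("gazetteer name %r reduces to nothing; dropped", row.key)
                    continue
                if toks in names:
                    logger.warning("duplicate gazetteer name %r; first entry wins", row.key)
                    continue
                names[toks] = (row.city or None, row.province)
            else:
                raise ValueError(f"unknown gazetteer kind {row.kind!r}")
        return cls(postal_map=postal, name_map=names)

    def city_province(self, city: str) -> str | None:
        for c, p in self.postal_map.values():
            if c == city:
                return p
        for c, p in self.name_map.values():
            if c == city:
                return p
        return None


@dataclass
class LocationWeights:
    doc_id: str
    city_weights: dict[str, float] = field(default_factory=dict)
    province_weights: dict[str, float] = field(default_factory=dict)
    city_province: dict[str, str] = field(default_factory=dict)


def extract_postal_codes(text: str) -> list[str]:
    """All Canadian-format postal codes and US ZIPs in the raw text."""
    return [m.group(1) for m in _POSTAL_RE.finditer(text)]


def resolve_location(
    code_or_name: str, gaz: Gazetteer, stops: StopList | None = None
) -> tuple[str | None, str] | None:
    """(city, province) for a postal code or place-name mention, or None."""
    squeezed = code_or_name.upper().replace(" ", "")
    if re.fullmatch(_CA_POSTAL.replace(" ?", ""), squeezed):
        hit = gaz.postal_map.get(squeezed[:3])
        if hit is None:
            logger.info("unresolvable postal code %r", code_or_name)
        return hit
    if re.fullmatch(r"\d{5}(?:-\d{4})?", squeezed):
        hit = gaz.postal_map.get(squeezed[:5])
        if hit is None:
            logger.info("unresolvable ZIP %r", code_or_name)
        return hit
    toks = tuple(preprocess_text(code_or_name, stops or StopList.default()))
    hit = gaz.name_map.get(toks)
    if hit is None:
        logger.info("unresolvable place mention %r", code_or_name)
    return hit


def detect_locations(
    doc: Document, gaz: Gazetteer, stops: StopList
) -> list[tuple[str | None, str]]:
    """Combine the postal-code channel (raw text) and the place-name channel
    (lemmatized longest match) into one resolved mention list."""
    resolved: list[tuple[str | None, str]] = []
    for code in extract_postal_codes(doc.text):
        hit = resolve_location(code, gaz, stops)
        if hit is not None:
            resolved.append(hit)
    tokens = preprocess(doc, stops).tokens
    max_len = max((len(k) for k in gaz.name_map), default=0)
    i = 0
    while i < len(tokens):
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            hit = gaz.name_map.get(tuple(tokens[i : i + length]))
            if hit is not None:
                resolved.append(hit)
                i += length
                break
        else:
            i += 1
    return resolved


def location_weights(
    doc_id: str, resolved: Sequence[tuple[str | None, str]]
) -> LocationWeights:
    """Proportional weights over the document's city and province mentions.

    City and province pools normalize independently; each sums to 1 when
    non-empty.  A document with no resolved locations yields empty weights.
    """
    cities = Counter(c for c, _ in resolved if c is not None)
    provinces = Counter(p for _, p in resolved)
    lw = LocationWeights(doc_id=doc_id)
    n_city = sum(cities.values())
    n_prov = sum(provinces.values())
    if n_city:
        lw.city_weights = {c: k / n_city for c, k in cities.items()}
    if n_prov:
        lw.province_weights = {p: k / n_prov for p, k in provinces.items()}
    for c, p in resolved:
        if c is not None:
            lw.city_province[c] = p
    return lw
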