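"""Typed, weighted knowledge-graph assembly, validation, and export.

Nodes are typed (Resource, the five vocabulary types, Topic, Unigram, City,
Province, Age, Category — 12 types); edges carry one of nine relations.
Weighted relations and the provenance of each weight:

==================  ======================================  =================
relation            endpoints                               weight
==================  ======================================  =================
CONTAINS            Resource -> vocab/Age/Category          pivoted-normalized
                                                            relevance (or
                                                            classifier prob.
                                                            for Category)
isLocatedIn         Resource -> City|Province               mention proportion
belongsToTopic      Resource -> Topic                       theta (leaf model)
describedBy         Topic -> Unigram                        phi
containsNgram       Resource -> Unigram                     theta @ phi
IS_ASSOCIATED_WITH  vocab <-> vocab (shared canonical)      n resources with
                                                            both detections
OCCURRED_TOGETHER   vocab/Age <-> vocab/Age                 doc co-occurrence
inProvince          City -> Province                        (none)
hasParent           Resource -> Resource                    (none)
==================  ======================================  =================

The graph is held in a :class:`networkx.MultiDiGraph`; undirected-by-meaning
relations (IS_ASSOCIATED_WITH, OCCURRED_TOGETHER) are stored once, endpoints
in sorted order.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .classify import CATEGORIES
from .corpus import Document
from .lexicon import (
    CooccurrenceTable,
    EntityKey,
    EntityMention,
)
from .locations import LocationWeights
from .relevance import RelevanceScore
from .topics import LeafTopic

logger = logging.getLogger(__name__)

NODE_TYPES = (
    "Resource",
    "HPO",
    "UMLS",
    "EricTerm",
    "AIRS",
    "ChallengingBehavior",
    "Topic",
    "Unigram",
    "Province",
    "City",
    "Age",
    "Category",
)

RELATIONS = (
    "hasParent",
    "isLocatedIn",
    "inProvince",
    "CONTAINS",
    "IS_ASSOCIATED_WITH",
    "OCCURRED_TOGETHER",
    "belongsToTopic",
    "describedBy",
    "containsNgram",
)

_VOCAB_NODE_TYPE = {
    "HPO": "HPO",
    "UMLS": "UMLS",
    "ERIC": "EricTerm",
    "AIRS": "AIRS",
    "BEHAVIOR": "ChallengingBehavior",
    "AGE": "Age",
}
_ENTITY_TYPES = tuple(_VOCAB_NODE_TYPE.values())

#: relation -> (legal source types, legal target types, weighted?)
SCHEMA: dict[str, tuple[tuple[str, ...], tuple[str, ...], bool]] = {
    "hasParent": (("Resource",), ("Resource",), False),
    "isLocatedIn": (("Resource",), ("City", "Province"), True),
    "inProvince": (("City",), ("Province",), False),
    "CONTAINS": (("Resource",), _ENTITY_TYPES + ("Category",), True),
    "IS_ASSOCIATED_WITH": (_ENTITY_TYPES, _ENTITY_TYPES, True),
    "OCCURRED_TOGETHER": (_ENTITY_TYPES, _ENTITY_TYPES, True),
    "belongsToTopic": (("Resource",), ("Topic",), True),
    "describedBy": (("Topic",), ("Unigram",), True),
    "containsNgram": (("Resource",), ("Unigram",), True),
}

AGE_SUBTYPES = ("child", "teen", "adult")


def entity_node_id(key: EntityKey) -> str:
    canonical, vocab = key
    return f"{_VOCAB_NODE_TYPE[vocab]}:{canonical}"


@dataclass
class KnowledgeGraph:
    graph: nx.MultiDiGraph
    manifest: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type
        ]

    def edge_weight(self, src: str, rel: str, dst: str) -> float | None:
        data = self.graph.get_edge_data(src, dst)
        if data:
            for attrs in data.values():
                if attrs["rel"] == rel:
                    return attrs.get("weight")
        # undirected-by-meaning relations may be stored the other way round
        if rel in ("IS_ASSOCIATED_WITH", "OCCURRED_TOGETHER"):
            data = self.graph.get_edge_data(dst, src)
            if data:
                for attrs in data.values():
                    if attrs["rel"] == rel:
                        return attrs.get("weight")
        return None

    def out_edges(self, src: str, rel: str) -> list[tuple[str, float | None]]:
        out = []
        for _, dst, attrs in self.graph.out_edges(src, data=True):
            if attrs["rel"] == rel:
                out.append((dst, attrs.get("weight")))
        return out

    def in_edges(self, dst: str, rel: str) -> list[tuple[str, float | None]]:
        out = []
        for src, _, attrs in self.graph.in_edges(dst, data=True):
            if attrs["rel"] == rel:
                out.append((src, attrs.get("weight")))
        return out


def _add_edge(
    g: nx.MultiDiGraph, src: str, rel: str, dst: str, weight: float | None
) -> None:
    if src not in g or dst not in g:
        missing = src if src not in g else dst
        raise ValueError(f"edge {src} -{rel}-> {dst} references absent node {missing}")
    g.add_edge(src, dst, rel=rel, weight=weight)


def build_graph(
    docs: Sequence[Document],
    mentions: Sequence[EntityMention],
    relevance_scores: Sequence[RelevanceScore],
    cooccur: CooccurrenceTable,
    leaves: Sequence[LeafTopic],
    categories: Mapping[str, Mapping[str, float]],
    location_weights: Sequence[LocationWeights],
    weight_floor: float = 1e-3,
    manifest: dict | None = None,
) -> KnowledgeGraph:
    """Assemble the knowledge graph from all upstream annotation tables.

    ``categories`` maps doc_id -> {category: classifier probability} for the
    categories the classifier accepted.  Topic-family edges (belongsToTopic,
    describedBy, containsNgram) are materialized only at or above
    ``weight_floor`` (set 0 to keep everything).
    """
    g = nx.MultiDiGraph()
    doc_ids = {d.doc_id for d in docs}

    for d in docs:
        g.add_node(
            f"Resource:{d.doc_id}",
            node_type="Resource",
            url=d.url,
            source=d.source,
            resource_type=d.resource_type,
        )
    for c in CATEGORIES:
        g.add_node(f"Category:{c}", node_type="Category", subtype=c)
    for a in AGE_SUBTYPES:
        g.add_node(f"Age:{a}", node_type="Age", subtype=a)

    # entity nodes from mentions
    concept_ids: dict[EntityKey, str | None] = {}
    for m in mentions:
        concept_ids.setdefault(m.key, m.concept_id)
    for key in sorted(concept_ids):
        canonical, vocab = key
        nid = entity_node_id(key)
        if nid in g:  # Age nodes pre-added
            continue
        props = {"node_type": _VOCAB_NODE_TYPE[vocab], "canonical": canonical}
        if concept_ids[key]:
            props["concept_id"] = concept_ids[key]
        g.add_node(nid, **props)

    # hasParent
    for d in docs:
        if d.parent_id and d.parent_id in doc_ids and d.parent_id != d.doc_id:
            _add_edge(g, f"Resource:{d.doc_id}", "hasParent", f"Resource:{d.parent_id}", None)

    # CONTAINS with pivoted-normalized relevance weights
    for s in relevance_scores:
        key = (s.canonical, s.vocab)
        if s.vocab == "AGE":
            dst = f"Age:{s.canonical}"
        else:
            dst = entity_node_id(key)
        _add_edge(g, f"Resource:{s.doc_id}", "CONTAINS", dst, s.weight)

    # classifier membership (CONTAINS-style edge to Category, weight = prob.)
    for doc_id, cat_probs in sorted(categories.items()):
        for c, p in sorted(cat_probs.items()):
            _add_edge(g, f"Resource:{doc_id}", "CONTAINS", f"Category:{c}", float(p))

    # IS_ASSOCIATED_WITH: same canonical term detected under several vocabs;
    # weight = number of resources where both detections occur
    per_doc_keys: defaultdict[str, set[EntityKey]] = defaultdict(set)
    for m in mentions:
        per_doc_keys[m.doc_id].add(m.key)
    by_canonical: defaultdict[str, set[str]] = defaultdict(set)
    for canonical, vocab in concept_ids:
        by_canonical[canonical].add(vocab)
    for canonical, vocabs in sorted(by_canonical.items()):
        for v1, v2 in _sorted_pairs(vocabs):
            n_docs = sum(
                1
                for keys in per_doc_keys.values()
                if (canonical, v1) in keys and (canonical, v2) in keys
            )
            a, b = sorted([entity_node_id((canonical, v1)), entity_node_id((canonical, v2))])
            _add_edge(g, a, "IS_ASSOCIATED_WITH", b, float(n_docs))

    # OCCURRED_TOGETHER with document co-occurrence counts
    for pair, count in sorted(cooccur.counts.items(), key=lambda kv: sorted(kv[0])):
        ka, kb = sorted(pair)
        a, b = sorted([entity_node_id(ka), entity_node_id(kb)])
        _add_edge(g, a, "OCCURRED_TOGETHER", b, float(count))

    # topic family
    for leaf in leaves:
        g.add_node(f"Topic:{leaf.label}", node_type="Topic", label=leaf.label)
    unigrams: set[str] = set()
    for leaf in leaves:
        for j, w in enumerate(leaf.phi_row):
            if w >= weight_floor:
                unigrams.add(leaf.vocab[j])
    # containsNgram rows (theta_row @ phi of the doc's home-node model) are
    # computed leaf-node-locally by the pipeline and passed in via leaves
    for u in sorted(unigrams):
        g.add_node(f"Unigram:{u}", node_type="Unigram", token=u)
    for leaf in leaves:
        theta_of = dict(zip(leaf.node_doc_ids, leaf.theta))
        for doc_id in leaf.node_doc_ids:
            w = float(theta_of[doc_id])
            if w >= weight_floor:
                _add_edge(g, f"Resource:{doc_id}", "belongsToTopic", f"Topic:{leaf.label}", w)
        for j, w in enumerate(leaf.phi_row):
            if w >= weight_floor:
                _add_edge(g, f"Topic:{leaf.label}", "describedBy", f"Unigram:{leaf.vocab[j]}", float(w))
    # containsNgram: for each document, theta @ phi of its home node's model
    # restricted to that node's leaf topics (a doc's home node is the node
    # where its dominant topic is a leaf; recursed topics contribute through
    # their child nodes instead)
    ngram_acc: defaultdict[tuple[str, str], float] = defaultdict(float)
    leaves_by_node: defaultdict[str, list[LeafTopic]] = defaultdict(list)
    for leaf in leaves:
        leaves_by_node[leaf.node_id].append(leaf)
    for node_leaves in leaves_by_node.values():
        home_docs = sorted({d for lf in node_leaves for d in lf.doc_ids})
        for leaf in node_leaves:
            theta_of = dict(zip(leaf.node_doc_ids, leaf.theta))
            for doc_id in home_docs:
                t = theta_of[doc_id]
                for j, w in enumerate(leaf.phi_row):
                    ngram_acc[(doc_id, leaf.vocab[j])] += float(t * w)
    for (doc_id, token), w in sorted(ngram_acc.items()):
        if w >= weight_floor and f"Unigram:{token}" in g:
            _add_edge(g, f"Resource:{doc_id}", "containsNgram", f"Unigram:{token}", w)

    # locations
    for lw in location_weights:
        for city, w in sorted(lw.city_weights.items()):
            if f"City:{city}" not in g:
                g.add_node(f"City:{city}", node_type="City", name=city)
            _add_edge(g, f"Resource:{lw.doc_id}", "isLocatedIn", f"City:{city}", w)
        for prov, w in sorted(lw.province_weights.items()):
            if f"Province:{prov}" not in g:
                g.add_node(f"Province:{prov}", node_type="Province", name=prov)
            _add_edge(g, f"Resource:{lw.doc_id}", "isLocatedIn", f"Province:{prov}", w)
    # inProvince, one edge per city
    seen_inprov: set[tuple[str, str]] = set()
    for lw in location_weights:
        for city, prov in sorted(lw.city_province.items()):
            if (city, prov) not in seen_inprov:
                if f"Province:{prov}" not in g:
                    g.add_node(f"Province:{prov}", node_type="Province", name=prov)
                _add_edge(g, f"City:{city}", "inProvince", f"Province:{prov}", None)
                seen_inprov.add((city, prov))

    kg = KnowledgeGraph(graph=g, manifest=dict(manifest or {}))
    kg.manifest.setdefault("weight_floor", weight_floor)
    violations = validate_schema(kg)
    if violations:
        raise ValueError(f"built graph violates schema: {violations[:5]}")
    return kg


def _sorted_pairs(items: Iterable[str]) -> list[tuple[str, str]]:
    ordered = sorted(items)
    return [(a, b) for i, a in enumerate(ordered) for b in ordered[i + 1 :]]


def validate_schema(kg: KnowledgeGraph) -> list[str]:
    """Endpoint-type legality, weight presence rules, dangling-edge check.
    Returns the violation list; empty means the graph conforms."""
    g = kg.graph
    violations: list[str] = []
    for n, d in g.nodes(data=True):
        if d.get("node_type") not in NODE_TYPES:
            violations.append(f"node {n}: unknown node_type {d.get('node_type')!r}")
    for src, dst, attrs in g.edges(data=True):
        rel = attrs.get("rel")
        if rel not in SCHEMA:
            violations.append(f"edge {src}->{dst}: unknown relation {rel!r}")
            continue
        src_types, dst_types, weighted = SCHEMA[rel]
        st = g.nodes[src].get("node_type")
        dt = g.nodes[dst].get("node_type")
        if st not in src_types:
            violations.append(f"{rel} edge {src}->{dst}: illegal source type {st}")
        if dt not in dst_types:
            violations.append(f"{rel} edge {src}->{dst}: illegal target type {dt}")
        has_w = attrs.get("weight") is not None
        if weighted and not has_w:
            violations.append(f"{rel} edge {src}->{dst}: missing weight")
        if not weighted and has_w:
            violations.append(f"{rel} edge {src}->{dst}: unexpected weight")
    return violations


# ---------------------------------------------------------------------------
# export / import


def export_graph(kg: KnowledgeGraph, out_dir: str | Path, format: str = "csv_bulk") -> list[Path]:
    """Write the graph as bulk-import CSVs (one nodes file per node type,
    one edges file per relation), N-Triples, or GraphML.

    In the N-Triples export every edge becomes one triple; weighted edges
    are additionally reified as an rdf:Statement carrying a ``weight``
    literal (the stated convention for representing edge properties in RDF).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "csv_bulk":
        g = kg.graph
        by_type: defaultdict[str, list[tuple[str, dict]]] = defaultdict(list)
        for n, d in g.nodes(data=True):
            by_type[d["node_type"]].append((n, d))
        for node_type, rows in sorted(by_type.items()):
            path = out_dir / f"nodes_{node_type}.csv"
            prop_keys = sorted({k for _, d in rows for k in d if k != "node_type"})
            with path.open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["node_id", "node_type", *prop_keys])
                for n, d in sorted(rows):
                    w.writerow([n, node_type, *[d.get(k, "") for k in prop_keys]])
            written.append(path)
        by_rel: defaultdict[str, list[tuple[str, str, float | None]]] = defaultdict(list)
        for src, dst, attrs in g.edges(data=True):
            by_rel[attrs["rel"]].append((src, dst, attrs.get("weight")))
        for rel, rows in sorted(by_rel.items()):
            path = out_dir / f"edges_{rel}.csv"
            with path.open("w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["src", "dst", "weight"])
                for src, dst, weight in sorted(rows, key=lambda r: (r[0], r[1])):
                    w.writerow([src, dst, "" if weight is None else repr(weight)])
            written.append(path)
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(kg.manifest, indent=2, default=str))
        written.append(manifest_path)
    elif format == "ntriples":
        written.append(_export_ntriples(kg, out_dir / "graph.nt"))
    elif format == "graphml":
        path = out_dir / "graph.graphml"
        g2 = nx.MultiDiGraph()
        for n, d in kg.graph.nodes(data=True):
            g2.add_node(n, **{k: v for k, v in d.items() if v is not None})
        for src, dst, attrs in kg.graph.edges(data=True):
            clean = {k: v for k, v in attrs.items() if v is not None}
            g2.add_edge(src, dst, **clean)
        nx.write_graphml(g2, path)
        written.append(path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return written


def _export_ntriples(kg: KnowledgeGraph, path: Path) -> Path:
    from rdflib import BNode, Graph, Literal, Namespace, RDF, URIRef
    from urllib.parse import quote

    NS = Namespace("http://carekg.example.org/")
    rg = Graph()
    for src, dst, attrs in kg.graph.edges(data=True):
        s = URIRef(NS[quote(src, safe="")])
        p = URIRef(NS[quote(attrs["rel"], safe="")])
        o = URIRef(NS[quote(dst, safe="")])
        rg.add((s, p, o))
        if attrs.get("weight") is not None:
            st = BNode()
            rg.add((st, RDF.type, RDF.Statement))
            rg.add((st, RDF.subject, s))
            rg.add((st, RDF.predicate, p))
            rg.add((st, RDF.object, o))
            rg.add((st, NS["weight"], Literal(float(attrs["weight"]))))
    rg.serialize(destination=str(path), format="nt")
    return path


def import_csv_bulk(in_dir: str | Path) -> KnowledgeGraph:
    """Round-trip reader for the csv_bulk export."""
    in_dir = Path(in_dir)
    g = nx.MultiDiGraph()
    for path in sorted(in_dir.glob("nodes_*.csv")):
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                node_id = row.pop("node_id")
                node_type = row.pop("node_type")
                props = {k: v for k, v in row.items() if v != ""}
                g.add_node(node_id, node_type=node_type, **props)
    for path in sorted(in_dir.glob("edges_*.csv")):
        rel = path.stem[len("edges_") :]
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                weight = float(row["weight"]) if row["weight"] != "" else None
                g.add_edge(row["src"], row["dst"], rel=rel, weight=weight)
    manifest_path = in_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return KnowledgeGraph(graph=g, manifest=manifest)
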