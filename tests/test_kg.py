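import math

import numpy as np
import pytest

from carekg.corpus import Document
from carekg.kg import (
    KnowledgeGraph,
    build_graph,
    export_graph,
    import_csv_bulk,
    validate_schema,
)
from carekg.lexicon import CooccurrenceTable, EntityMention
from carekg.relevance import RelevanceScore
from carekg.topics import LeafTopic

import networkx as nx


def _mention(doc, canonical, vocab, span=(0, 1)):
    return EntityMention(doc_id=doc, canonical=canonical, vocab=vocab, token_span=span)


def _empty_cooccur():
    return CooccurrenceTable(counts={})


class TestBuildGraph:
    def test_single_doc_contains_weight_matches_formula(self):
        # tf=2, dl=1, pivot=1, slope=0.2 -> (1 + ln 2) / 1
        docs = [Document(doc_id="d", url="u", text="x")]
        mentions = [_mention("d", "e", "HPO"), _mention("d", "e", "HPO", (2, 3))]
        scores = [RelevanceScore("d", "e", "HPO", (1 + math.log(2)) / 1.0)]
        kg = build_graph(docs, mentions, scores, _empty_cooccur(), [], {}, [])
        w = kg.edge_weight("Resource:d", "CONTAINS", "HPO:e")
        assert w == pytest.approx(1 + math.log(2))

    def test_shared_canonical_yields_association_edge(self):
        docs = [Document(doc_id="d", url="u", text="x")]
        mentions = [_mention("d", "autism", "HPO"), _mention("d", "autism", "ERIC")]
        kg = build_graph(docs, mentions, [], _empty_cooccur(), [], {}, [])
        w = kg.edge_weight("EricTerm:autism", "IS_ASSOCIATED_WITH", "HPO:autism")
        assert w == 1.0  # detected together in one resource

    def test_counts_match_enumeration_on_synthetic_docs(self):
        docs = [Document(doc_id=f"d{i}", url=f"u{i}", text="x") for i in range(5)]
        mentions, scores = [], []
        # each doc i mentions entities e0..e{i}
        for i in range(5):
            for j in range(i + 1):
                mentions.append(_mention(f"d{i}", f"e{j}", "UMLS"))
                scores.append(RelevanceScore(f"d{i}", f"e{j}", "UMLS", 0.5))
        from carekg.lexicon import cooccurrences

        kg = build_graph(docs, mentions, scores, cooccurrences(mentions), [], {}, [])
        # nodes: 5 resources + 5 entities + 5 categories + 3 ages
        assert kg.n_nodes == 5 + 5 + 5 + 3
        n_contains = sum(1 for *_, a in kg.graph.edges(data=True) if a["rel"] == "CONTAINS")
        assert n_contains == 15  # 1+2+3+4+5
        n_cooc = sum(1 for *_, a in kg.graph.edges(data=True) if a["rel"] == "OCCURRED_TOGETHER")
        assert n_cooc == 10  # C(5,2) pairs all co-occur in d4
        assert kg.edge_weight("UMLS:e0", "OCCURRED_TOGETHER", "UMLS:e1") == 4.0

    def test_dangling_edge_rejected(self):
        docs = [Document(doc_id="d", url="u", text="x")]
        scores = [RelevanceScore("ghost", "e", "HPO", 1.0)]
        mentions = [_mention("d", "e", "HPO")]
        with pytest.raises(ValueError, match="absent node"):
            build_graph(docs, mentions, scores, _empty_cooccur(), [], {}, [])

    def test_has_parent_edges(self):
        docs = [
            Document(doc_id="home", url="u", text="x"),
            Document(doc_id="page", url="u2", text="y", parent_id="home"),
        ]
        kg = build_graph(
            docs, [_mention("home", "e", "HPO")], [_dummy_score("home")],
            _empty_cooccur(), [], {}, [],
        )
        assert ("Resource:home", None) in [
            (d, w) for d, w in kg.out_edges("Resource:page", "hasParent")
        ]

    def test_topic_family_edges_with_floor(self):
        docs = [Document(doc_id="d0", url="u", text="x"), Document(doc_id="d1", url="u2", text="y")]
        leaf = LeafTopic(
            label="T0.0",
            node_id="T0",
            topic_index=0,
            doc_ids=["d0", "d1"],
            theta=np.array([0.9, 0.6]),
            node_doc_ids=["d0", "d1"],
            phi_row=np.array([0.7, 0.2999, 0.0001]),
            vocab=["alpha", "beta", "gamma"],
        )
        kg = build_graph(
            docs, [_mention("d0", "e", "HPO")], [_dummy_score("d0")], _empty_cooccur(),
            [leaf], {}, [], weight_floor=1e-3,
        )
        assert kg.edge_weight("Resource:d0", "belongsToTopic", "Topic:T0.0") == pytest.approx(0.9)
        assert kg.edge_weight("Topic:T0.0", "describedBy", "Unigram:alpha") == pytest.approx(0.7)
        assert "Unigram:gamma" not in kg.graph  # below the floor
        # containsNgram = theta * phi for the single leaf
        assert kg.edge_weight("Resource:d1", "containsNgram", "Unigram:alpha") == pytest.approx(0.6 * 0.7)


def _dummy_score(doc="d"):
    return RelevanceScore(doc, "e", "HPO", 1.0)


class TestValidateSchema:
    def test_legal_graph_passes(self, small_pipeline):
        assert validate_schema(small_pipeline.kg) == []

    def test_missing_weight_flagged(self):
        g = nx.MultiDiGraph()
        g.add_node("Resource:d", node_type="Resource")
        g.add_node("HPO:e", node_type="HPO")
        g.add_edge("Resource:d", "HPO:e", rel="CONTAINS", weight=None)
        assert len(validate_schema(KnowledgeGraph(graph=g))) == 1

    def test_illegal_endpoint_flagged(self):
        g = nx.MultiDiGraph()
        g.add_node("City:x", node_type="City")
        g.add_node("Topic:t", node_type="Topic")
        g.add_edge("City:x", "Topic:t", rel="belongsToTopic", weight=0.5)
        report = validate_schema(KnowledgeGraph(graph=g))
        assert any("illegal source" in v for v in report)


class TestExport:
    def test_csv_round_trip_exact(self, small_pipeline, tmp_path):
        kg = small_pipeline.kg
        export_graph(kg, tmp_path, format="csv_bulk")
        back = import_csv_bulk(tmp_path)
        assert back.n_nodes == kg.n_nodes
        assert back.n_edges == kg.n_edges

        def edge_multiset(k):
            return sorted(
                (s, d, a["rel"], a.get("weight"))
                for s, d, a in k.graph.edges(data=True)
            )

        assert edge_multiset(back) == edge_multiset(kg)
        assert sorted(back.graph.nodes) == sorted(kg.graph.nodes)

    def test_one_csv_per_node_type(self, small_pipeline, tmp_path):
        kg = small_pipeline.kg
        export_graph(kg, tmp_path / "e", format="csv_bulk")
        node_files = sorted(p.name for p in (tmp_path / "e").glob("nodes_*.csv"))
        types_present = {d["node_type"] for _, d in kg.graph.nodes(data=True)}
        assert len(node_files) == len(types_present)

    def test_ntriples_parses_back(self, small_pipeline, tmp_path):
        from rdflib import Graph

        paths = export_graph(small_pipeline.kg, tmp_path, format="ntriples")
        rg = Graph()
        rg.parse(paths[0], format="nt")
        assert len(rg) > small_pipeline.kg.n_edges  # reified weights add triples

    def test_graphml_export(self, small_pipeline, tmp_path):
        paths = export_graph(small_pipeline.kg, tmp_path, format="graphml")
        g = nx.read_graphml(paths[0])
        assert g.number_of_nodes() == small_pipeline.kg.n_nodes


class TestPipelineIntegration:
    def test_location_weights_sum_to_one_per_resource(self, small_pipeline):
        kg = small_pipeline.kg
        for res in kg.nodes_of_type("Resource"):
            city_w = [w for d, w in kg.out_edges(res, "isLocatedIn") if d.startswith("City:")]
            prov_w = [w for d, w in kg.out_edges(res, "isLocatedIn") if d.startswith("Province:")]
            if city_w:
                assert sum(city_w) == pytest.approx(1.0, abs=1e-9)
            if prov_w:
                assert sum(prov_w) == pytest.approx(1.0, abs=1e-9)

    def test_city_edge_implies_in_province_edge(self, small_pipeline):
        kg = small_pipeline.kg
        for res in kg.nodes_of_type("Resource"):
            for dst, _ in kg.out_edges(res, "isLocatedIn"):
                if dst.startswith("City:"):
                    assert kg.out_edges(dst, "inProvince"), dst

    def test_planted_tf_recovered(self, small_fixture, small_pipeline):
        truth = small_fixture.truth
        freq = small_pipeline.freq
        for doc_id, counts in truth.entity_counts.items():
            for (canonical, vocab), k in counts.items():
                assert freq.tf.get((doc_id, canonical, vocab)) == k
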