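import numpy as np
import pytest

from carekg.kg import KnowledgeGraph
from carekg.query import (
    RIMQuantifier,
    owa_aggregate,
    owa_weights,
    parse_query,
    rank_resources,
    retrieve_candidates,
    QueryTerms,
)

from .oracles import owa_oracle, rank_oracle

import networkx as nx


def _random_fixture_graph(rng, n_resources=6, n_entities=3, n_unigrams=2):
    """Small random graph with CONTAINS and containsNgram edges."""
    g = nx.MultiDiGraph()
    entities = [f"UMLS:e{j}" for j in range(n_entities)]
    unigrams = [f"Unigram:u{j}" for j in range(n_unigrams)]
    for e in entities:
        g.add_node(e, node_type="UMLS", canonical=e.split(":")[1])
    for u in unigrams:
        g.add_node(u, node_type="Unigram", token=u.split(":")[1])
    for i in range(n_resources):
        r = f"Resource:d{i:02d}"
        g.add_node(r, node_type="Resource", url=f"u{i}")
        for e in entities:
            if rng.random() < 0.7:
                g.add_edge(r, e, rel="CONTAINS", weight=float(rng.uniform(0.05, 1)))
        for u in unigrams:
            if rng.random() < 0.7:
                g.add_edge(r, u, rel="containsNgram", weight=float(rng.uniform(0.001, 0.2)))
    return KnowledgeGraph(graph=g)


class TestOWAWeights:
    def test_identity_uniform(self):
        w = owa_weights(RIMQuantifier(kind="identity"), 4)
        assert np.allclose(w, [0.25, 0.25, 0.25, 0.25])

    def test_most_hand_computed(self):
        # Q piecewise linear on (0.3, 0.8); at i/5: 0, .2, .6, 1, 1, 1
        w = owa_weights(RIMQuantifier(kind="most", a=0.3, b=0.8), 5)
        assert np.allclose(w, [0.0, 0.2, 0.4, 0.4, 0.0], atol=1e-12)

    def test_all_is_min_operator(self):
        w = owa_weights(RIMQuantifier(kind="all"), 4)
        assert np.allclose(w, [0, 0, 0, 1])

    def test_at_least_n(self):
        w = owa_weights(RIMQuantifier(kind="at_least_n", n=2), 4)
        assert np.allclose(w, [0, 1, 0, 0])

    @pytest.mark.parametrize(
        "q",
        [
            RIMQuantifier(kind="most"),
            RIMQuantifier.some(),
            RIMQuantifier(kind="all"),
            RIMQuantifier(kind="at_least_n", n=3),
            RIMQuantifier(kind="identity"),
        ],
        ids=["most", "some", "all", "at_least_3", "identity"],
    )
    def test_weights_sum_to_one_for_all_lengths(self, q):
        for n in range(1, 21):
            w = owa_weights(q, n)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= -1e-15).all()


class TestOWAAggregate:
    def test_equal_weights_is_mean(self):
        w = owa_weights(RIMQuantifier(kind="identity"), 3)
        assert owa_aggregate(w, [0.2, 0.4, 0.6]) == pytest.approx(0.4)

    def test_max_operator(self):
        assert owa_aggregate(np.array([1.0, 0, 0]), [0.1, 0.9, 0.5]) == pytest.approx(0.9)

    def test_hand_computed_most(self):
        w = np.array([0, 0.2, 0.4, 0.4, 0])
        v = [0.9, 0.5, 0.7, 0.1, 0.3]
        assert owa_aggregate(w, v) == pytest.approx(0.46)
        assert owa_aggregate(w, v) == pytest.approx(owa_oracle(w, v))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            owa_aggregate(np.array([0.5, 0.5]), [1.0, 2.0, 3.0])

    def test_bounded_monotone_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 12))
            q = [
                RIMQuantifier(kind="most"),
                RIMQuantifier.some(),
                RIMQuantifier(kind="all"),
                RIMQuantifier(kind="at_least_n", n=int(rng.integers(1, 6))),
                RIMQuantifier(kind="identity"),
            ][int(rng.integers(5))]
            w = owa_weights(q, n)
            v = rng.uniform(0, 1, size=n)
            agg = owa_aggregate(w, v)
            assert v.min() - 1e-12 <= agg <= v.max() + 1e-12
            # monotonicity: raise one value
            j = int(rng.integers(n))
            v2 = v.copy()
            v2[j] = min(1.0, v2[j] + rng.uniform(0, 0.5))
            assert owa_aggregate(w, v2) >= agg - 1e-12
            # idempotence
            c = float(rng.uniform(0, 1))
            assert owa_aggregate(w, np.full(n, c)) == pytest.approx(c)


class TestParseQuery:
    def test_aggression_query(self, stops, intent_lex):
        lex, intent = intent_lex
        terms = parse_query(
            "aggressive behavior and kicking and spitting",
            lex,
            topic_vocab={"aggressive", "behavior"},
            intent_model=intent,
            stops=stops,
        )
        assert ("spitting", "UMLS") in terms.entities
        assert terms.behavior_category == "behavioral concerns"
        assert set(terms.unigrams) == {"aggressive", "behavior"}

    def test_empty_string(self, stops, intent_lex):
        lex, intent = intent_lex
        terms = parse_query("", lex, set(), intent, stops)
        assert terms.is_empty()

    def test_exact_lexicon_surface(self, stops, intent_lex):
        lex, _ = intent_lex
        terms = parse_query("spitting", lex, set(), None, stops)
        assert terms.entities == [("spitting", "UMLS")]


@pytest.fixture(scope="module")
def intent_lex(stops):
    from carekg.classify import IntentModel
    from carekg.lexicon import LexiconEntry, compile_lexicon

    entries = [
        LexiconEntry(surface="spitting", canonical="spitting", vocab="UMLS"),
        LexiconEntry(
            surface="aggressive behavior",
            canonical="behavioral concerns",
            vocab="BEHAVIOR",
            behavior_category="behavioral concerns",
        ),
    ]
    lex = compile_lexicon(entries, stops)
    return lex, IntentModel.from_lexicon(lex, stops)


class TestRetrieve:
    def test_single_criterion_vectors(self):
        rng = np.random.default_rng(1)
        kg = _random_fixture_graph(rng)
        terms = QueryTerms(entities=[("e0", "UMLS")])
        vectors, criteria = retrieve_candidates(kg, terms)
        assert criteria == [("entity", "UMLS:e0")]
        for res, vec in vectors.items():
            assert vec.shape == (1,)
            assert vec[0] == kg.edge_weight(res, "CONTAINS", "UMLS:e0")

    def test_missing_edge_leaves_zero_slot(self):
        g = nx.MultiDiGraph()
        g.add_node("Resource:d0", node_type="Resource")
        g.add_node("UMLS:a", node_type="UMLS")
        g.add_node("UMLS:b", node_type="UMLS")
        g.add_edge("Resource:d0", "UMLS:a", rel="CONTAINS", weight=0.4)
        kg = KnowledgeGraph(graph=g)
        vectors, criteria = retrieve_candidates(
            kg, QueryTerms(entities=[("a", "UMLS"), ("b", "UMLS")])
        )
        assert np.allclose(vectors["Resource:d0"], [0.4, 0.0])

    def test_candidates_match_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        kg = _random_fixture_graph(rng, n_resources=10)
        terms = QueryTerms(entities=[("e0", "UMLS"), ("e1", "UMLS")], unigrams=["u0"])
        vectors, criteria = retrieve_candidates(kg, terms)
        expected = set()
        for s, d, a in kg.graph.edges(data=True):
            if d in ("UMLS:e0", "UMLS:e1") and a["rel"] == "CONTAINS":
                expected.add(s)
            if d == "Unigram:u0" and a["rel"] == "containsNgram":
                expected.add(s)
        assert set(vectors) == expected


class TestRank:
    def _rank_via_api(self, kg, terms, quantifier, stops):
        # rank through the library, bypassing text parsing
        vectors, criteria = retrieve_candidates(kg, terms)
        w = owa_weights(quantifier, len(criteria))
        scored = sorted(
            ((owa_aggregate(w, v), r.split(":", 1)[1]) for r, v in vectors.items()),
            key=lambda t: (-t[0], t[1]),
        )
        return scored, vectors, w

    def test_equals_brute_force_on_random_graphs(self, stops):
        rng = np.random.default_rng(3)
        for _ in range(50):
            kg = _random_fixture_graph(rng, n_resources=int(rng.integers(2, 9)))
            terms = QueryTerms(entities=[("e0", "UMLS"), ("e2", "UMLS")], unigrams=["u1"])
            q = RIMQuantifier(kind="most")
            scored, vectors, w = self._rank_via_api(kg, terms, q, stops)
            oracle = rank_oracle(
                {r.split(":", 1)[1]: v for r, v in vectors.items()}, w
            )
            assert [(pytest.approx(s), d) for s, d in oracle] == scored

    def test_single_criterion_reduces_to_weight_sort(self):
        rng = np.random.default_rng(4)
        kg = _random_fixture_graph(rng)
        terms = QueryTerms(entities=[("e1", "UMLS")])
        vectors, criteria = retrieve_candidates(kg, terms)
        w = owa_weights(RIMQuantifier(kind="most"), 1)
        scored = sorted(
            ((owa_aggregate(w, v), r) for r, v in vectors.items()),
            key=lambda t: (-t[0], t[1]),
        )
        weights_sorted = sorted(((v[0], r) for r, v in vectors.items()), key=lambda t: (-t[0], t[1]))
        assert [r for _, r in scored] == [r for _, r in weights_sorted]

    def test_identity_quantifier_equals_mean_ranking(self):
        rng = np.random.default_rng(5)
        kg = _random_fixture_graph(rng, n_resources=8)
        terms = QueryTerms(entities=[("e0", "UMLS"), ("e1", "UMLS"), ("e2", "UMLS")])
        vectors, _ = retrieve_candidates(kg, terms)
        w = owa_weights(RIMQuantifier(kind="identity"), 3)
        by_owa = sorted(vectors, key=lambda r: (-owa_aggregate(w, vectors[r]), r))
        by_mean = sorted(vectors, key=lambda r: (-float(np.mean(vectors[r])), r))
        assert by_owa == by_mean

    def test_end_to_end_rank_on_pipeline(self, small_pipeline):
        res = small_pipeline
        q_text = "sleep issues " + res.leaves[0].vocab[0]
        result = rank_resources(
            res.kg, q_text, res.lexicon, res.topic_vocab, res.intent_model, top_n=10
        )
        assert len(result.rows) <= 10
        scores = [r["score"] for r in result.rows]
        assert scores == sorted(scores, reverse=True)
        # every returned resource is adjacent to at least one criterion
        for row in result.rows:
            assert any(wv > 0 for wv in row["weights"])

    def test_unmatchable_query_gives_notice(self, small_pipeline):
        res = small_pipeline
        result = rank_resources(
            res.kg, "zzzz qqqq", res.lexicon, res.topic_vocab, None, top_n=5
        )
        assert result.rows == []
        assert result.notice is not None
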