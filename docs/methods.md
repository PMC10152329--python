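# Methods

This note documents the models and procedures implemented in `carekg`, the
parameters that matter, the numerical and design choices taken where the
design was open, and what the synthetic test corpus does and does not show
about real data.

## Corpus model and preprocessing

A corpus is a set of cleaned web-resource texts, one record per URL, with
optional source tag (`caregiver`, `inform_alberta`, `other`), resource type
(webpage/video/pdf) and a parent-page link. Scraping and boilerplate
removal are upstream of this package: the input contract is cleaned text.

Preprocessing applies five steps in order: punctuation removal (every
character that is neither alphanumeric nor whitespace is replaced by a
space, so hyphenated words split), lowercasing, whitespace tokenization,
lemmatization, stop-word removal. Lemmatization uses a small
dictionary-plus-suffix-rule English lemmatizer (irregular forms table;
-ies/-es/-s, -ing, -ed rules with stem-length guards and final-consonant
undoubling). It is deliberately conservative and idempotent; the same
instance processes documents, lexicon surface forms, gazetteer names and
queries, so all matching happens in one lemma space. The stop list is the
standard English list shipped with scikit-learn plus user-supplied
additions; a token is dropped if either its surface or its lemma is a stop
word. One consequence of treating hyphens as punctuation is that the token
count of a document can exceed its whitespace word count; invariants are
therefore stated against the punctuation-stripped text.

## Dictionary NER

Controlled-vocabulary lexicons (HPO, UMLS, ERIC, AIRS, plus
challenging-behavior and age term lists) are compiled into a single pattern
table keyed by lemma sequence. Matching is a longest-match, left-to-right
scan with consumed spans — deterministic, and the behaviour of common
rule-based matchers. Two policies worth noting:

- Surfaces of the *same* entity that collapse to one lemma sequence
  ("child", "children") are one pattern entry; *different* entities sharing
  a lemma sequence (the same canonical term in HPO and UMLS) are all
  retained, and a match emits one mention per entry. This is what makes
  cross-vocabulary `IS_ASSOCIATED_WITH` edges observable.
- Identical canonical terms under different vocabularies remain distinct
  entity keys; vocabulary is part of the key everywhere downstream.

Entity frequencies (tf) are counted per (document, canonical, vocabulary);
the distinct-entity count per document, including zero for mention-free
documents, is the document "length" dl used by the relevance formula.
Co-occurrence is counted at document scope: a pair of entities co-occurring
in a document counts once for that document regardless of mention
multiplicity, which matches the integer edge weights the graph carries.

## Pivoted-unique-normalized relevance

The `CONTAINS` edge weight is

    relevance(tf, dl) = (1 + log tf) / ((1 − slope) · pivot + slope · dl)

with slope 0.2 and pivot = the corpus mean of dl (zero-entity documents
included in the mean). The denominator grouping is fixed by the defining
property that dl = pivot yields a normalization factor equal to the pivot.
The logarithm is natural by default (configurable to base 10); both choices
preserve monotonicity (strictly increasing in tf, strictly decreasing in dl
for slope > 0) and the penalize/reward behaviour around the pivot. The
pivot is computed once per collection at build time and stored in the graph
manifest so incremental additions can reuse it. A known limitation of this
scheme is over-penalization of documents much longer than the corpus
average, whose entities can receive near-zero weights.

## Hierarchical topic modeling

Count matrices keep the `max_features` most frequent unigrams (ties broken
lexicographically) with raw counts. LDA is scikit-learn's online
variational Bayes with the fixed configuration: 10 maximum iterations,
learning decay 0.7, batch size 128, feature cap 50,000, explicit seed. θ
rows and φ rows are renormalized to sum to one.

The hierarchy fits LDA at the root with K₀ topics (200/300 at full corpus
scale; small corpora use proportionally smaller K₀), hard-assigns every
document to its dominant (argmax, lowest-index tie-break) topic, and
recurses on any topic with more than `threshold` documents (default 300).
Open choices were pinned as follows:

- **Child topic count**: K_child = max(2, ceil(n_docs / threshold)), so
  expected leaf size ≈ threshold and the recursion provably makes progress
  in expectation; recorded in the manifest.
- **No-progress rule**: if a topic absorbs its node's entire document set,
  it is flagged a leaf and not recursed — this is what terminates on
  degenerate corpora (e.g. many identical documents).
- **Depth cap** 10 as a last-resort bound.

Only leaf topics enter the graph. A document's *home node* is the node
where its dominant topic is leaf-flagged; its `belongsToTopic` weights are
the home-node-local θ values, `describedBy` weights are φ rows, and
`containsNgram` weights are the θ·φ product over the home node's leaf
topics. Edges below a configurable floor (default 1e-3, settable to 0) are
not materialized: dense θ·φ products at full corpus scale are infeasible
and almost all mass sits in a sparse head.

## Document classification

Five categories (financial help, education, services, core knowledge,
other), multilabel. The train/validation/test split is 80/10/10 by
iterative stratification (rarest-label-first assignment to the split with
greatest remaining demand); sizes are approximate by a few documents
because per-label balance takes priority. The training protocol is: train
for 20 epochs, evaluate macro F1 on validation at threshold 0.5 after each
epoch, keep the best epoch's weights, then tune the final threshold by
macro-F1 grid search over exactly the 11 values 0.0–1.0 in steps of 0.1
(ties to the lowest threshold). Macro F1 averages per-category F1 equally;
a category with neither true nor predicted positives contributes 0 —
conservative and deterministic.

The reference backbone is a linear bag-of-words scorer with one sigmoid per
category, trained with class-balanced binary cross entropy (positives of a
category up-weighted by the capped negative/positive ratio — necessary
under the heavily skewed label profile) under AdamW with linear warmup,
cosine decay to a tenth of the base rate, and gradient-norm clipping at
1.0. The published transformer fine-tuning configuration (6-layer MiniLM
head, dropout 0.3, lr 3e-4, β₁ 0.9, β₂ 0.95, ε 1e-8, weight decay 0.01,
batch 64) is preserved verbatim in `ClassifierConfig` for the
`transformer` backbone value; no transformer runtime ships here, so that
backbone raises. Learning rate and batch size resolve per backbone: the
linear model trains from scratch in few steps and uses 0.2 / 16.

The query-intent model maps free text to one of ten challenging-behavior
categories (sleep issues … behavioral concerns, in fixed order). The
default implementation scores challenging-behavior lexicon matches per
category and softmaxes the counts; argmax with lowest-index tie-break. Any
scorer honouring the text → 10-distribution contract can be substituted.

## Location detection

Postal codes are extracted from raw (pre-tokenization) text: Canadian
letter-digit-letter [space] digit-letter-digit, and 5-digit US ZIP with
optional −4 extension, both boundary-guarded. Canadian codes resolve
through their forward sortation area (first three characters) in an offline
gazetteer CSV — a deliberate replacement of the original online geocoding
dependency, at FSA granularity which suffices for city/province. Place
names resolve through a lemmatized name table with longest-match scanning.
Both channels combine into one mention list; city weights and province
weights are normalized independently (a province inferred from a city
resolution counts once in each pool) and each sums to 1 per document when
non-empty. No false-positive filtering beyond gazetteer membership is
applied; homonymous names take the first table entry, logged.

## Knowledge graph

Twelve node types (Resource, HPO, UMLS, EricTerm, AIRS,
ChallengingBehavior, Topic, Unigram, City, Province, Age, Category) and
nine relations. Weight provenance is one-to-one: `CONTAINS` ← relevance
formula (or classifier probability for Category membership), `isLocatedIn`
← mention proportions, `belongsToTopic`/`describedBy`/`containsNgram` ←
θ/φ/θ·φ, `OCCURRED_TOGETHER` ← document co-occurrence counts,
`IS_ASSOCIATED_WITH` ← the number of resources in which the shared
canonical term is detected under both vocabularies (chosen as a
deterministic, testable relevancy proxy; no formula is prescribed for it).
`inProvince` and `hasParent` are unweighted. `describedBy` carries the φ
weight — the schema treats it as the weighted topic-word relation
throughout. Document text is not stored in the graph; exports are
accompanied by the corpus file keyed by doc_id.

`validate_schema` checks endpoint-type legality per relation, the weight
presence rules, and dangling edges; `build_graph` refuses to emit a
non-conforming graph. Exports: bulk-import CSVs (one node file per type,
one edge file per relation; weights written as full-precision `repr` so the
round trip is exact), N-Triples (weighted edges reified as `rdf:Statement`
with a `weight` literal), and GraphML.

## Query ranking

A query is parsed into criteria: distinct matched entities, the inferred
behavior category, and query tokens present in the leaf-topic vocabulary.
Terms without a graph node are dropped with a notice. Every resource
adjacent to at least one criterion node is a candidate; its criterion
vector holds the connecting edge weights with 0 for absent edges — keeping
n fixed across candidates makes vectors comparable, and under MOST softly
penalizes partial matches. Weight families stay on their native scales by
default (an optional per-family min-max rescaling exists but is off). OWA
weights come from a RIM quantifier Q (Q(0)=0, Q(1)=1, non-decreasing):
MOST and SOME are piecewise linear with (a, b) = (0.3, 0.8) and (0.0, 0.5)
— classical parameters, exposed in config — ALL is the step at 1 (the
minimum operator), AT-LEAST-n the step at n/len, identity the arithmetic
mean. Values are sorted descending and dotted with the weights. Ties in the
final score break by ascending doc_id for determinism.

## Synthetic study corpus

The generator emulates exactly the statistical structure the pipeline
assumes: per-document Dirichlet(0.1) mixtures over disjoint planted topic
vocabularies (default 3 topics × 15 pseudo-words); entity surface forms
injected at a Poisson rate (0.05 expected mentions per document per entity,
i.e. ≈2.5 mentions per document over the default lexicon), with plural
inflections so the lemmatization path is exercised end to end; two
canonical terms shared between HPO and UMLS to exercise cross-vocabulary
association; category marker tokens (3 repeats per planted label) encoding
a label profile with the skew of the hand-labeled study data (services ≫
core knowledge ≫ education ≫ other ≫ financial help); and postal codes
plus place names encoding planted locations in 30% of documents. Document
lengths are negative binomial with mean 60 and dispersion 5. All pseudo-words
are lemma fixed points and collision-checked, so planted counts round-trip
exactly through the matcher. Every artifact is a deterministic function of
(config, seed).

Default scales: 300 documents for topic-recovery and graph-integrity runs,
500 for classifier runs (rare categories need enough held-out positives
for macro F1 to be meaningful). These are desk scales chosen so a full
pipeline run takes seconds on one CPU.

What passing tests show — and do not: the synthetic corpus is separable by
construction (marker tokens, disjoint topic vocabularies, noise-free
labels), so classifier and topic-recovery results certify the *protocol
and implementation*, not real-data performance; real corpora with
overlapping vocabulary, label noise and boilerplate artifacts will score
far lower. Likewise the gazetteer is small and unambiguous, so location
results do not speak to the false-positive problem of real web text.

## Known limitations

- The lemmatizer is heuristic; rare inflections can produce non-word stems
  (harmless for matching, since both sides pass through the same rules).
- Pivoted unique normalization over-penalizes documents far longer than
  the corpus average.
- `IS_ASSOCIATED_WITH` requires exact canonical-string equality across
  vocabularies; no concept-level linking is attempted.
- The intent classifier is lexicon-based; verbose queries that avoid
  vocabulary phrases fall back to the first category by tie-break.
- Cross-subset topic models (caregiver vs. directory sources) are
  independent fits; one pivot per build is the default scope.
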