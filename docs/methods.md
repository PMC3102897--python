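# Methods

This note documents the models and procedures `condl` implements, the
defaults that matter, and the choices made where the underlying method
left the design open.

## Scope and inputs

The package consumes *pre-parsed* text: one record per sentence with
tokens, labelled dependency edges (a tree or forest over the tokens) and
pre-resolved gene-mention token spans. Running a named-entity tagger or
a syntactic parser is deliberately out of scope; the corpus format
(JSON lines) is the interface to whatever upstream tagging/parsing stack
produced the parses. Gene dictionaries are 2-column TSV
(symbol, synonym), interaction keywords one per line, and concept terms
a flat file with `|#|`-separated synonyms plus an optional 3-column TSV
side file for `is_a` parents and `has_quality` annotations.

## Gene normalization and candidate selection

Surfaces are mapped to approved symbols by case-folded exact lookup. A
synonym that would map to two symbols after case folding is dropped at
dictionary load (with a warning), so every hit is unambiguous. A
sentence becomes a *candidate* when it has at least two distinct
normalized symbols and at least one interaction keyword; all C(k, 2)
unordered pairs of its k distinct symbols are enumerated. Keyword
matching is case-insensitive whole-token matching that also considers
hyphen-split subtokens, so "BCG-induced" matches the keyword "induced" —
hyphenated verb compounds are pervasive in this literature and the
worked example depends on this behaviour.

Context tags drive network layering: `generic_vaccine` when any of the
generic concept-word variants {vaccine, vaccines, vaccination,
vaccinated, vaccinating} occurs as a (sub)token, and `vo_term:<id>` per
specific term match. Only sentence-level context is used for layer
tagging. Terms whose label itself contains the generic word are excluded
from specific matching, since the generic word is queried separately and
such terms add no specific-concept signal.

## Term matching

Synonym matching is case-insensitive with word boundaries at
non-alphanumeric characters; names shorter than 3 characters are
matched case-sensitively to limit false hits from short acronyms. On
overlapping candidate matches the longest wins; identical spans for
distinct terms are all kept; output order is (span start, term id).
These policies are package defaults — reasonable tagger practice — not
properties inherited from any particular ontology.

## Shortest dependency paths

For each gene pair the unique tree path between the two mention heads is
rendered as the alternating sequence *label, word, label, …, label*; the
gene endpoint tokens are never part of the sequence. The head of a
multi-token mention is the span token whose parent lies outside the
span (ties: rightmost). Edges are traversed direction-agnostically and
keep their label; no direction markers are added to path elements. The
path is canonically oriented by sentence order of the two heads so that
the same pair always yields the same sequence regardless of argument
order. Mentions in disconnected parse fragments yield a no-path signal
and the pair is skipped with a logged warning.

## Edit kernel and SVM

Edit distance between paths is classical sequence edit distance on path
elements with exact string equality — whole-element insert, delete and
substitute operations at configurable costs (defaults 1/1/1, under which
the distance is a metric). The similarity is the standard edit-kernel
transform

    sim(p, q) = exp(-gamma * d(p, q)),   gamma > 0  (default 0.5)

which is a documented default: the transform is the conventional
construction for edit-distance kernels, and gamma is a free parameter
with no canonical value. Edit-distance kernels are not guaranteed
positive semidefinite; a configurable ridge (default 0.01) is added to
the Gram-matrix diagonal to keep the solver well-conditioned, and
indefiniteness is otherwise tolerated, as SMO-style solvers do. The
ridge is a training-time regularizer only — classification of a new path
uses raw similarities to the support paths.

Classification is a soft-margin SVM over the precomputed Gram matrix
(scikit-learn's SVC, SMO tolerance 1e-6 so refits on reordered data
agree). The stored model is self-describing: kernel configuration,
support paths, dual coefficients and bias; the decision value is the
bias plus the coefficient-weighted sum of kernel similarities, positive
meaning "interacting", with an exact zero resolving to
"not-interacting". Precision/recall/F1 are computable for any labeled
path set, but no benchmark-corpus figures are claimed: those depend on
external corpora and an unrecoverable kernel parameterization.

## Layered networks and centralities

Networks are undirected and unweighted; repeated extractions of a pair
accumulate as edge evidence but never weight centrality. The three
layers keep, respectively: all classified-positive pairs; pairs from
sentences tagged `generic_vaccine`; pairs from sentences tagged
`generic_vaccine` *or* any `vo_term:*`. By construction the edge sets
nest. Each network is restricted to the seed gene and the nodes
reachable from it, because the object of study is the seed-centred
neighborhood; stray components are dropped.

Centralities:

- **degree** — raw neighbor count (no normalization);
- **eigenvector** — dominant (Perron) eigenvector of the adjacency
  matrix, power iteration per connected component, L2-normalized,
  tolerance 1e-10, at most 10,000 iterations (non-convergence is an
  error carrying the residual context); isolated nodes score 0;
- **closeness** — within-component closeness with Wasserman–Faust
  scaling `(n_c - 1)/(n - 1)` for disconnected graphs (a documented
  default; on connected graphs it is the plain inverse mean distance);
- **betweenness** — Brandes accumulation of pair-dependency fractions
  over unordered pairs, unnormalized by default.

Ranks are competition ranks ("1224"): tied scores share the best rank.
The seed gene is excluded from ranking — it is trivially rank 1 in its
own neighborhood. The "top-k by any metric" selection takes the union
over the four metrics of genes with rank ≤ k; with competition ranking
every gene tied at the cut-off is included, so no gene is dropped
arbitrarily. Degree, eigenvector, closeness and betweenness are
delegated to networkx behind this interface and are cross-checked in the
test suite against independent brute-force oracles (dense
eigendecomposition, all-pairs BFS, exhaustive shortest-path
enumeration) on random graphs.

## Association networks and communities

A gene and a concept are *associated* when at least one abstract
contains a whole-token occurrence of a synonym of each (the same
matcher as sentence-level term matching, applied to title+abstract
text). The association table induces the concept–concept network: one
node per concept in the table, an edge exactly when two concepts share
at least one central gene, with the shared-gene set as the edge
attribute.

Modularity is Q = Σ_c (e_c/m − (d_c/2m)²). Community detection is
agglomerative greedy maximization: every node starts as its own
community and the connected pair with the largest gain
ΔQ = m_ab/m − 2(d_a/2m)(d_b/2m) is merged repeatedly. Three choices are
deliberate:

- only connected pairs are merge candidates — for a disconnected pair
  m_ab = 0 makes the gain strictly non-positive, so this is an
  optimization, not a restriction (asserted by test);
- ties on ΔQ break deterministically by the pair whose
  (lexicographically smallest member, then other member) sorts first —
  determinism is required for reproducible partitions;
- merging continues to a single community and the returned partition is
  the one at the maximum-Q point of the whole merge history, rather than
  stopping at the first non-improving merge; on dense networks the
  first merges can be non-improving bookkeeping steps and stopping early
  would return near-singleton partitions.

The incremental ΔQ bookkeeping is testable against from-scratch
modularity recomputation at every recorded merge. Concept-network
centrality reuses the gene-network metrics without seed exclusion.

## Packaged fixtures

The package ships machine-readable transcriptions of the curated result
tables (32 centrality-selected genes with per-metric top-20 flags and
their literature PMIDs; 28 vaccines with categories and associated gene
lists), the worked-example sentence with a dependency parse, a default
interaction-keyword list, and a small demonstration gene dictionary.
Files are integrity-checked against embedded SHA-256 digests at load,
and loaders enforce the tables' invariants (row counts, count/list
consistency, gene-set containment). The worked-example parse is a tree
consistent with the three published shortest paths and with the
statement that the remaining three pairs are non-interacting; the full
original parse is not recoverable from the published figure, so the
packaged tree is a faithful reconstruction, not a transcription.

## Synthetic corpora

The generator emulates the *structure* of a parsed literature sample,
not its language. Defaults: 20 documents, 5 planted gene–gene
interactions, 30% decoy sentences. Sentences are instantiated from
three dependency templates — subject–verb–object, a conjunction chain
mirroring the worked example (which also plants a known non-interacting
sibling pair), and a nominalised prepositional chain — with interaction
keywords drawn from the packaged list. Decoys contain two genes but no
keyword, so candidate selection must remove them. Planted pairs always
form a connected graph containing the seed gene, so the seed-restricted
generic network can equal the planted edge set exactly. Interaction
sentences carry no concept context, the generic word, or a specific
vaccine token with probabilities 0.4/0.3/0.3, exercising all three
layers. Per-document "abstracts" (concatenated sentence texts) plus
dedicated co-occurrence abstracts give exact expected association
tables by bookkeeping rather than by re-matching.

Everything is driven by one integer seed (`random.Random`); equal seeds
give byte-identical corpora. What passing synthetic tests shows is that
the machinery is correct under the stated conditions; it does not show
robustness to real-language phenomena (anaphora, nested mentions,
parser errors, ambiguous gene names), which the generator deliberately
does not model.

## Problem sizes and verification

The oracle-backed suites run at sizes where exhaustive computation is
exact and fast: random graphs of ≤ 12 nodes for the four centralities
(100 graphs), ≤ 8 nodes for modularity against the pairwise double sum,
all 4,140 partitions of 8 nodes for the planted-two-clique optimum, 500
random path pairs (length ≤ 6) against exhaustive edit-script recursion
and 1,000 random triples for the metric axioms. The curated-table chain
(28 vaccines) and the synthetic end-to-end run (20 documents) are
desk-scale by nature. Corpus-scale results — network sizes over millions
of abstracts — are corpus- and tagger-dependent and are out of scope.

## Known limitations

- Gene mention spans must be pre-resolved to token spans upstream; the
  package does not re-tokenize multi-word names.
- Structural subsumption covers only genus-plus-qualities definitions;
  no OWL parsing or general DL reasoning.
- The edit kernel's gamma and the SVM's C are data-set parameters; the
  defaults (0.5, 1.0) are sensible for the template-scale paths used
  here, not universal constants.
- Abstract-level association treats any co-occurrence as evidence; no
  frequency weighting or significance testing is applied.
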