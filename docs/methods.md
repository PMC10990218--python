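# Methods

This note records the model implemented by `lda2net`, the choices made where
the design was genuinely open, and what the synthetic testbed does and does
not demonstrate.

## Model and assumptions

The enrichment is a deterministic post-processing step on top of any
row-stochastic topic model. Its inputs are the bigram-by-document count
table `S` (ordered adjacent word pairs, collected after stopword removal so
that content words separated only by stopwords still form a bigram), the
topic-word matrix `M` and the document-topic matrix `Q`. For topic `k` the
directed edge weight of an observed bigram `(w_i, w_j)` is

```
e^k_ij = ( Σ_d S[b,d] · Q[d,k] ) · M[k,i] · M[k,j]
```

and each topic's adjacency is normalized by its grand total so all entries
sum to 1. No generative assumption is made about word order: the bigram
component is purely observational, which is the point — the topic model
supplies the *paradigmatic* evidence (which words belong to the topic), the
bigram counts supply the *syntagmatic* evidence (how those words are
arranged), and the product keeps only associations supported by both. Key
structural consequences, all enforced and tested:

* support containment — `A^k` is nonzero only at observed bigrams;
* direction preservation — `(w_i, w_j)` and `(w_j, w_i)` are independent;
* scale equivariance — rescaling a topic's document proportions rescales the
  unnormalized network and leaves the normalized one unchanged;
* degenerate topics (no positive edge weight) yield an empty network with a
  warning rather than an error, so one bad topic cannot abort a run.

Normalization happens **before** centrality computation. The alternative
order is observationally equivalent for every ratio-based statistic
(centralities, communities, labels are invariant to a global scale); only
the absolute weights reported in exported tables depend on it, and reporting
normalized weights makes topics comparable.

Self-loop bigrams (immediately repeated words) are retained: nothing in the
method excludes them, and every downstream metric tolerates them (they are
ignored where the definition requires it, e.g. clustering and walktrap).

## Text preparation

Cleaning is configurable but defaults to: removal of section headers (runs
of ≥ 2 consecutive all-caps words at string start or after sentence
punctuation), Arabic numerals, Roman numerals, stopwords, and non-acronym
tokens shorter than 3 characters; lower-casing of everything except
acronyms. Decisions worth recording:

* **Acronyms** are tokens that are all-uppercase after stripping digits, of
  length ≥ 2. They keep their case and bypass the length rule — otherwise
  ubiquitous biomedical terms like *CI*, *RR* or *RNA* would be destroyed.
* **Roman numerals** are only matched over the alphabet {I, V, X} (phase and
  section numbering: II, IV, XII…). Wider Roman alphabets collide with real
  acronyms — *CI*, *MI*, *DC* are all valid numerals.
* **Stopwords** default to the Snowball English list (embedded, public
  domain, ~175 function words). Larger information-retrieval lists were
  rejected because they remove content words (e.g. "found").
* **Vocabulary threshold**: a word is kept if it occurs at least once per
  million tokens (`min_rate = 1e-6`); documents are kept if they contain at
  least ten vocabulary tokens (`min_doc_words = 10`). Both configurable.
* The bigram vocabulary is stored in lexicographic order, which makes it —
  and therefore every downstream artifact — invariant to document ordering.

## Topic-model adapter

Estimation is delegated: the bundled backend is scikit-learn's batch
variational LDA (seeded, hence reproducible), but any estimator that
produces row-stochastic `M` and `Q` can be loaded from CSV (including
log-probability exports, via `log=True`). Rows off unit sum by ≤ 1e-6 are
renormalized; anything worse, or any negative entry, is rejected. The number
of topics `K` is a user parameter — selecting it is a topic-modeling
concern, outside the enrichment's contract.

## Network statistics

* **Shortest-path metrics** (node/edge betweenness) use cost = 1/weight:
  edge weights are tie strengths, so a heavier edge must be a shorter
  distance. Unit costs are available via `weighted_paths=False`. Betweenness
  is unnormalized (path counts) and follows edge direction.
* **PageRank** is weighted and iterated to tolerance 1e-12 so that results
  match an independent power-iteration oracle to 1e-6.
* **Barrat clustering coefficient** and **modularity** are defined for
  undirected graphs; the network is symmetrized by summing reciprocal edge
  weights. The Barrat sum runs over ordered neighbor pairs (each triangle
  counts twice), which makes it reduce exactly to the unweighted local
  clustering coefficient under uniform weights. The global coefficient
  averages over nodes with degree ≥ 2.
* **Percentile filtering** keeps nodes whose topic-word probability is at or
  above the (100 − node_pct)th percentile and edges likewise by weight, then
  drops dangling edges and isolates. Ties at the cut are all kept, so
  retained counts may slightly exceed the nominal fraction.

## Subtopics and labels

Walktrap (4-step weighted random walks, bottom-up merging) runs on the
symmetrized graph with self-loops removed and isolated words set aside; the
dendrogram is cut at maximum modularity. The algorithm is deterministic, so
partitions are reproducible without a seed.

Label walks of length `l` (words) start at a node drawn proportionally to
weighted out-degree and step proportionally to the edge betweenness computed
*within the community subgraph* (the normalization in the step rule runs
over that subgraph's edges). When every outgoing edge of the current word
has zero betweenness — possible e.g. for a node whose only outgoing edge is
a self-loop — edge weights substitute. A walk halts at a word with no
outgoing edges; halted walks are discarded by default (`short_walk_rule`)
because a truncated n-gram is not a label of the requested length, but they
can be kept. Revisits are allowed. Candidates are ranked by sampling count
with lexicographic tie-break; the default budget is 1000 walks per length.
The topic-level label is the top candidate of the largest community (size
ties go to the lower community index): sampling on the whole topic network
spreads mass over many near-uniform candidates.

## Information gauging and the topic portfolio

The Jensen–Shannon divergence uses the standard symmetric form
`½·KL(P‖M) + ½·KL(Q‖M)`, `M = (P+Q)/2`, with base-2 logarithms (range
[0, 1], `0·log 0 = 0`). Per topic it is evaluated between the counts-weight
and probs-weight vectors restricted to the observed bigram vocabulary and
renormalized there — counts as the data distribution, probs as the model.
Restricting to observed bigrams is deliberate: counts-weights are zero
everywhere else, so any larger common support would fix part of the
divergence by construction.

Topic profiles are (mean, variance) of the topic's document proportions
(population formulas, divide by the number of documents), the JSD above, and
the global Barrat coefficient. Partition modularity is carried in the
summary table but excluded from the default clustering feature set, which is
`(mean, variance, jsd, bcc)`. Features are z-scored, then Gaussian mixtures
are fitted over all four covariance families (full, tied, diagonal,
spherical) and component counts 1…min(9, n−1), selecting by BIC with 3
initializations per fit. Component variances are floored at `reg_covar =
1e-3` — on unit-variance features this is small, but it prevents components
from collapsing onto duplicated points and gaming the BIC comparison (with
the default 1e-6 floor, a pure noise cloud can spuriously "prefer" many
point-mass components).

## Synthetic testbed

The generator plants, per topic, a cyclic first-order Markov chain over a
disjoint signature vocabulary (default: 3 topics × 15 words, unit transition
weights). Documents draw a topic mixture from a sparse Dirichlet
(concentration 0.1 per topic), then per token draw a topic from the mixture
and advance that topic's chain; with probability `noise_rate = 0.1` an
off-chain noise word is emitted instead, and sentence breaks are inserted at
random (probability 0.08 per token) so cleaned documents contain several
token runs. This plants exactly the structure the enrichment claims to
expose — bag-of-words-recoverable mixtures whose within-topic word order is
invisible to the topic model but present in the bigrams.

What it does **not** emulate: realistic vocabulary sizes or Zipfian
frequencies, topic overlap in vocabulary, section structure, multilingual
noise, or corpus scale. Passing tests demonstrate the machinery is correct
and that planted syntagmatic structure is recovered under mild noise; they
do not certify interpretability gains on any particular real corpus.

## Verification strategy and problem sizes

Every non-trivial computation is checked against an independent oracle:
counts-weights against a triple loop; betweenness against exhaustive
shortest-path enumeration; PageRank against power iteration; Barrat against
the unweighted coefficient and hand-evaluated weighted cases; modularity
against its definitional sum; label shares against exact dynamic-programming
walk enumeration (total variation < 0.02 at 50 000 walks); JSD against
scipy's Jensen–Shannon distance; walktrap and the GMM against planted
partitions (adjusted Rand index 1). The standard end-to-end check uses 3
planted topics, 500 documents of ~80 tokens, noise 0.1, across 5 seeds, and
requires the top-10 edges of each matched topic to hit planted chain edges
with precision ≥ 0.8; the orchestrated-pipeline check uses 120 documents.
These sizes were chosen as the smallest at which the statistical claims are
stable across seeds.

## Known limitations

* Tokenization is whitespace/punctuation based: no lemmatization,
  part-of-speech tagging or language detection; multilingual corpora will
  produce language-specific topics rather than being filtered.
* The acronym and section-header heuristics are regular expressions; unusual
  typography (e.g. mixed-case acronyms like "AAs") is lower-cased.
* Betweenness-based steps make label sampling O(E·V) per community for the
  betweenness precomputation; very large filtered communities may warrant
  percentile filtering first.
* The GMM portfolio needs enough topics to be meaningful; with fewer than ~10
  topics BIC will usually and correctly select one component.
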