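# Methods

## Pipeline model

`litnet` treats a literature corpus as evidence of association between
biomedical entities: a paper that mentions two entities contributes one
unit of co-occurrence evidence to their relation. The pipeline is a chain
of deterministic transforms:

1. documents → mentions (dictionary NER),
2. mentions → document-level paper-entity relations,
3. relations → bipartite paper-entity graph → weighted co-occurrence graph,
4. centrality ranking on the bipartite graph,
5. top-*k* seeds + strongest same-type neighbours → six entity-specific
   subnetworks,
6. subnetwork characterization and salient-pair reports.

Co-occurrence is evidence of *association*, not interaction; the pipeline
is a screening instrument, and its outputs are ranked hypotheses.

## Entity extraction

**Sentence splitting** is rule-based: a `. ! ?` run followed by whitespace
ends a sentence unless the next character is lowercase, the preceding word
is a known abbreviation (`et al.`, `Fig.`, `e.g.` …), or the preceding
word is a single uppercase letter (so `E. coli` survives). **Tokenization**
is Penn-Treebank-flavoured; intra-word hyphens, slashes and decimals are
kept inside one token (`p53-mediated`, `5-FU/leucovorin`, `5.2`). This is
safe because matching operates on *normalized* n-grams and normalization
maps `-` to a space, so the single token `Beta-Catenin` still hits the
two-word dictionary key `beta catenin`.

**Normalization** (shared by dictionary keys and query n-grams):
NFKC fold, dash-punctuation → `-`, casefold, recompose, strip `+ * ; _`,
`-` → space, collapse whitespace. It is idempotent and invariant under
case changes of the input; the casefold+recompose step is what keeps keys
stable for characters whose uppercase form changes composition (ß, ǰ).

**Lemmatization** is a deterministic rule table for English noun plurals
plus a small irregular list. It is deliberately weak: lemmas are consulted
only when the surface n-gram misses the dictionary, which prevents an
aggressive lemmatizer from manufacturing false positives. Verbs and
adjectives are untouched because dictionary entries are nominal.

**Matching** is left-to-right greedy longest match per type lexicon, with
the window bounded by the lexicon's longest key (in normalized tokens);
spans never overlap within one type. A string present in several type
dictionaries yields one mention per type by default (the downstream
networks are type-filtered, so double counting cannot leak across
reports); an optional `precedence` order lets earlier types claim
overlapping spans instead. Granularity is document-level: repeated
mentions inside one paper collapse to one relation, and consequently edge
weights count *papers*, never mention pairs.

## Ranking

PageRank is computed by in-package power iteration on the undirected
heterogeneous graph (each edge is two directed links; isolated nodes are
dangling and teleport uniformly), damping 0.85, L1 tolerance 1e-8, at most
200 iterations, with a convergence flag on the result. These are the
classical defaults; all are configurable. Betweenness is exact Brandes
(networkx), unweighted shortest paths, unnormalized, each unordered pair
counted once — only ranks are consumed downstream, so normalization is a
fixed convention rather than a modelling choice. Papers participate in
score flow but are excluded from rankings; ranking on the entity-only
projection instead is possible by building the co-occurrence graph first
and ranking that, but the heterogeneous graph is the default because it
lets prolific papers transfer importance between the entities they
co-mention. Ties break by (score desc, name asc) to keep reports stable.

## Subnetworks and pairs

"Highly co-occurring" neighbours are operationalized as: per seed, the top
`per_seed` (default 5) same-type neighbours with weight ≥ `min_weight`
(default 2), unioned over the `k` = 10 seeds. Both knobs are reported in
each network's metadata, because published node counts for such
subnetworks are not reproducible without knowing the original threshold.
Isolated seeds are retained — the node set reflects the selection, not
connectivity. Pair reports bin edges at < 100 / 100–999 / ≥ 1000
co-mentions, binning each network separately; small corpora simply leave
the heavy bins empty.

## Indicator panel

Average degree 2E/N; weighted degree 2·Σw/N; density 2E/(N(N−1)); average
path length is the mean over *connected* ordered pairs only (imputing a
penalty for disconnected pairs would make fragmented subnetworks look
artificially long-pathed, and isolated seeds are expected); clustering is
the unweighted local coefficient with degree-<2 nodes contributing 0;
communities come from deterministic Clauset–Newman–Moore greedy modularity
maximization on edge weights, with Q evaluated on the returned partition.
Determinism was preferred over randomized Louvain because modularity
values are algorithm-dependent anyway and a deterministic partition makes
byte-for-byte reproducible reports possible; the `seed` parameter is
reserved for randomized variants. Values are held at full precision and
rounded only in reports (degrees 2 d.p., density 3 d.p.).

## Synthetic corpus generator

The generator emulates the structural features the pipeline is designed to
detect, with exact ground truth:

* papers are split round-robin into `n_communities` (default 2) equal
  communities of 30 papers each (default `n_docs` = 60);
* each community carries its own entities (4 diseases, 3 drugs, 3 genes by
  default) with per-entity document frequency drawn uniformly from 4–8 —
  roughly 2–3 entities per abstract, a realistic mention density for short
  biomedical abstracts, and dense enough that each community's paper graph
  is essentially one connected component;
* an optional **hub** entity is planted in 3× as many documents (24) of
  community 0 as any ordinary entity's maximum (8), guaranteeing it the
  top PageRank;
* an optional **bridge** entity is planted in 4 documents of every
  community and is the *only* cross-community entity, so every
  cross-community shortest path passes through it and it dominates
  betweenness — provided no hub is planted alongside it. A planted hub is
  itself a strong intra-community broker and can out-score the bridge, so
  the two recovery claims are each stated for their own construction (hub
  battery: default config; bridge battery: `plant_hub=False`). With the
  default densities both recoveries held on 300/300 generator seeds when
  the construction was frozen, and the shipped batteries assert them
  per-seed over 20 seeds.
* filler text is drawn from a fixed list of ordinary discourse words
  disjoint from every entity surface form, so extraction on synthetic
  corpora is exact by construction (precision = recall = 1) and any
  deviation indicates a pipeline defect, not noise;
* surface forms include capitalization variants and hyphenated renderings
  (`Pontifexin-Bridge`) to exercise normalization in situ.

What the generator does **not** emulate: ambiguous entity names, partial
or misspelled mentions, abbreviations needing expansion, negated contexts,
cross-type name collisions, and realistic skew in document length or
entity frequency (Zipfian tails). Passing the recovery batteries therefore
demonstrates the correctness of the mechanics (matching, projection,
centrality, selection) under clean conditions, not NER accuracy on real
abstracts — on real corpora extraction quality is bounded by dictionary
coverage.

## Problem sizes

The default study conditions are desk-scale by design: 60-document
corpora, 20–25 entities, 20-seed recovery batteries; the full test suite
runs in a few seconds and the acceptance script in under a minute. All
operations are corpus-size-agnostic (the XML reader is streaming; graph
construction is linear in relations plus Σ C(k_p, 2) for the projection).

## Known limitations

* Dictionary NER cannot resolve ambiguity; a term listed in two type
  dictionaries is reported for both types unless a precedence is set.
* Co-occurrence weights are raw counts; no significance correction (PMI,
  hypergeometric) is applied, so frequent entities accumulate heavy edges
  by exposure alone. Rank-based reading of the outputs is advised.
* The modularity and community-count indicators depend on the detection
  algorithm; they are comparable across networks analysed by this package
  but not directly against numbers produced by other algorithms.
* Average path length excludes disconnected pairs; comparing it across
  networks with very different fragmentation can mislead.
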