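# Methods

This note documents the models and procedures `ddsn` implements, the
parameters that matter, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Tripartite graph and projection

The pipeline's primitive object is a directed tripartite graph
G = (Vm ∪ Vg ∪ Vd, Eg ∪ Ed): drug→gene interaction edges (Eg) and
gene→disease association edges (Ed) over pairwise-disjoint vertex sets.
Disjointness is enforced at construction — an identifier appearing both
as a drug and as a gene is an error, not a silent merge. Edges are
deduplicated on ingest (the projection counts *sets* of diseases, so
duplicated association rows must not inflate weights).

The drug–drug similarity network (DDSN) is the projection onto the drug
layer: with R(i) the set of diseases reachable from drug *i* through any
drug→gene→disease path, the weight of the undirected edge {i, j} is
|R(i) ∩ R(j)|, and pairs with weight below `min_weight` (default 1) get
no edge. Two conventions matter:

* **Diseases, not paths.** Several genes connecting the same drug to the
  same disease contribute that disease once. The weight is a count of
  shared indications-by-mechanism, not of mechanistic redundancy.
* **Isolated drugs stay.** Drugs with no reachable diseases remain as
  isolated DDSN nodes; the community-level connectivity filter, not the
  projection, decides their fate. This keeps the exclusion accounting
  explicit and auditable.

Drugs sharing genes but no diseases are *not* similar under this
definition; gene overlap matters only through the disease layer.

A deliberately naive oracle (`oracle_project`, exhaustive per-pair
per-disease path enumeration, guarded to |Vm|·|Vd| ≤ 10⁶) exists purely
for testing; the test suite checks exact agreement with the fast
set-intersection projection on batches of random graphs.

## Community detection

The detector is agglomerative clustering on *vertex similarity* with a
modularity-selected dendrogram cut. It is a faithful, open
re-implementation of the "vertex similarity + dendrogram" family of
hierarchical community methods, with every unspecified degree of freedom
pinned down and documented; it does not attempt to bit-reproduce any
proprietary implementation, and cluster boundaries on real data may
differ from other tools in the family.

* **Vertex similarity** is the structural-equivalence cosine: for a drug
  pair (i, j), the profiles compared are the weighted adjacency rows
  restricted to the *other* nodes, plus one shared coordinate carrying
  the mutual edge weight A_ij. Algebraically
  s(i, j) = ((A Aᵀ)_ij + A_ij²) / (‖A_i‖‖A_j‖). The measure is 1 for
  identical neighbourhoods with identical weights, 0 for pairs with
  neither a common neighbour nor a mutual edge, and rewards a strong
  mutual edge even without shared neighbours (the role a degree-valued
  self-entry plays in related formulations, but without breaking the two
  boundary cases above). Isolated nodes have similarity 0 to everything.
* **Linkage** is average (Lance–Williams update), and merges never cross
  connected components, so the dendrogram respects the graph topology.
* **Cut criterion**: every prefix of the merge sequence is a candidate
  partition; the one maximizing weighted Newman–Girvan modularity
  Q = (1/2m) Σ [A_ij − k_i k_j / 2m] δ(c_i, c_j) is returned (earliest
  prefix on ties). Q is tracked incrementally along the merge sequence
  (ΔQ = w(A,B)/m − K_A K_B/2m² per merge); the equivalence of the
  incremental and direct computations — and of ours and networkx's — is
  exercised in the tests. Whether the original family of tools cuts on
  weighted modularity, unweighted modularity or another criterion is not
  determinable; weighted modularity is this package's documented choice,
  consistent with treating edge weight as similarity strength throughout.
* **Determinism.** Merge ties and size-ordering ties break on the
  lexicographically smallest member set; the largest-component tie goes
  to the component containing the smallest drug id. The `seed` parameter
  exists for interface stability only — the algorithm has no residual
  randomness.
* **Degenerate inputs.** An edgeless network yields all-singleton
  communities with Q = 0 (modularity of the null graph is defined as 0
  here); an empty network is a precondition error.

Complexity is O(n²) memory and roughly O(n³) time in the worst case via
numpy-vectorized matrix updates — ample for networks of a few thousand
drugs, far above the desk-scale problem sizes used in the tests
(≤ 200 nodes, chosen so the whole suite runs in seconds).

**Filtering** removes communities with no member in the largest connected
component (when `require_main_component`, default on) and communities
smaller than `min_size` (default 8, matching the analysis convention the
package reproduces); survivors are renumbered by descending size and the
excluded communities are retained with their reason (`disconnected` /
`too-small`) for reporting.

## ATC labeling and candidate calling

ATC codes follow the WHO positional syntax (letter, 2 digits, letter,
letter, 2 digits; truncations of length 1/3/4/5 valid); codes are
uppercased on ingest and validated per row.

* **Histograms** count, per ATC prefix at a level, the number of member
  drugs carrying that prefix — each drug at most once per distinct
  prefix, regardless of how many of its codes share it. Levels 2–4 are
  computed restricted to the community's level-1 label.
* **Dominant code / label**: the histogram key with maximal count;
  lexicographic tie-break with a logged warning. A community whose
  members carry no ATC codes is reported unlabeled and contributes only
  candidates.
* **Matched vs candidate**: a drug is matched if *any* of its codes sits
  under the label letter (the permissive reading for multi-ATC drugs);
  all other members — including drugs with no codes — are repositioning
  candidates. Matched and candidate sets partition the community.
* **Top level-4 codes** are selected by *dense* rank over count levels:
  the codes carrying the k (default 3) highest distinct counts are all
  returned, so ties expand the list rather than being truncated
  arbitrarily. Each selected code maps to its known target set; unknown
  codes map to the empty set with a warning.

## Accuracy arithmetic

Per-community accuracy rows are aggregated through *reconstructed integer
counts*: n_pred = nearest-int(size·pct_predominant/100), likewise
n_conf; per-row accuracy is 100·(n_pred+n_conf)/size, and the weighted
totals are 100·Σn/Σsize. The total accuracy is the sum of the two
*rounded* weighted percentages, and the candidate percentage is its
complement to 100. All percentages are presented to one decimal, rounded
half away from zero. Rounding conventions differ in the last ulp across
software; the suite asserts per-row accuracies only where all common
conventions agree, while the weighted totals are insensitive to the
choice on the reference rows.

## Literature queries and evidence

Query construction is a pure function of (drug term, category terms,
filters): drug and primary category name as `[MeSH Terms]` clauses joined
by AND, category synonyms OR-ed in as `[Title/Abstract]`, and one
AND-joined group of publication-type filters (defaults `clinicaltrial`,
`classicalarticle` — the configurable stand-ins for "research articles
and clinical trials"). Which PubMed filter tags best capture that intent
is configuration, not semantics. Live E-utilities access sits behind a
`QueryFetcher` protocol (`EntrezFetcher` requires biopython and network);
nothing in the pipeline or tests touches the network.

Expert screening of retrieved literature is *not* automated: evidence
enters as externally supplied records with a `confirmed` flag, and
`apply_validation` only ever promotes candidates to
literature-confirmed — statuses never demote, and db-matched hints ignore
evidence with a logged warning.

## Synthetic data: what it emulates, what it does not

The generator plants `n_clusters` drug communities. Each community owns
`genes_per_cluster` genes, each gene `diseases_per_gene` private diseases
(no disease is shared across communities). Drugs link to own-community
genes with probability `p_within` and to foreign genes with `p_between`,
independently. Every drug draws 1–2 level-4 ATC codes from its
community's weighted profile; a deterministic
nearest-int(`mislabel_fraction`·size) lexicographically-first subset per
community instead draws from a *foreign* community's profile — these are
the planted repositioning candidates. Each level-4 code maps to one
distinct synthetic target.

Closed-form expected projected weights follow from the Bernoulli scheme
(each gene shared by a same-community pair with probability p_within²,
contributing its d private diseases):

* within: g·d·(p_within² + (n−1)·p_between²)
* between: g·d·(2·p_within·p_between + (n−2)·p_between²)

and the tests check Monte-Carlo agreement within three standard errors.

Defaults (12 communities × 16 drugs, mislabel fraction 0.25, p_within
0.6, p_between 0.02, 8 genes/community, 3 diseases/gene, seed 0) mirror
the reference analysis at desk scale: 12 surviving communities and a
candidate fraction near one quarter. Recovery benchmarks use 4
communities × 12 drugs over 20 seeds — comfortably inside the separable
regime (p_between ≪ p_within, communities ≥ 10 drugs) — and assert mean
adjusted Rand index ≥ 0.9 against the planted truth.

What the generator does **not** emulate: the heavy-tailed degree
distributions of real drug–target and gene–disease data, shared diseases
across communities, correlated gene modules, polypharmacology beyond the
Bernoulli noise, or incomplete/biased ATC annotation. Passing recovery
tests therefore demonstrates correctness of the machinery under the
stated statistical assumptions, not performance on DrugBank/DisGeNET —
real-data community structure is far noisier, and reference accuracies
obtained on those sources depend on their specific content and
curation. A drug that draws no gene links at all (probability
(1−p_within)^g·(1−p_between)^((n−1)g), negligible at the defaults but not
at extreme parameters) is absent from the drug–gene table and hence from
the DDSN; the truth tables still list it, and comparisons restrict to
drugs present in the network.

## Known limitations

* Community detection is O(n³); beyond ~10⁴ drugs a sparse or sampled
  variant would be needed.
* The modularity criterion inherits modularity's resolution limit; very
  small true communities attached to large ones may not be separated.
* ATC level-5 (substance) analysis, DDD handling, and alternative
  similarity normalizations (Jaccard/cosine of reachable sets) are out of
  scope by design.
* The filter-tag vocabulary for PubMed publication types is configurable
  because no canonical mapping exists for "research articles".
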