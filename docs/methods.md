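# Methods

## The analysis model

The pipeline operationalizes a common systems-biology strategy for
proteomics follow-up in organisms without their own interactome data: treat
the differentially accumulated proteins (DAPs) of an experiment as a *seed
set*, transfer them onto a well-characterized reference interactome via
best-ortholog mapping, and study the seeds' interaction neighborhood as a
proxy for the process-specific molecular machinery. Its core assumptions,
inherited from the underlying biology, are:

* **Ortholog function transfer** — a seed protein's best BLAST hit on the
  reference proteome participates in comparable processes. The mapping is
  deliberately permissive (e-value < 0.5, best bit score wins) because
  non-model organisms rarely yield strict reciprocal best hits; the cutoff
  is configurable.
* **Guilt by association** — direct interactors of seed proteins are likely
  involved in the same processes, so the analysis object is the *closed
  first neighborhood* of the mapped seeds. The expansion keeps
  neighbor–neighbor edges (induced subgraph), since discarding them would
  misrepresent the local topology that the centrality metrics measure; a
  `star` mode (seed-incident edges only) is available for sensitivity
  analysis and can only remove edges, never add nodes.
* **Topology encodes importance** — nodes central to the subnetwork
  (high-degree hubs, high-betweenness bottlenecks, high closeness/radiality
  cores) are candidate regulators. Because betweenness and the other
  path-based metrics are undefined across disconnected parts, all metrics
  are computed on the giant component only; the discarded small clusters
  are reported with their sizes.

## Metric definitions and numerical choices

All distances are unweighted hop counts (reference interactomes carry no
usable edge weights). For a connected graph with `n` nodes and diameter
`δ_G`:

| metric | definition | notes |
|---|---|---|
| degree | `k_v` | |
| betweenness | `Σ_{s≠t≠v} σ_st(v)/σ_st / [(n−1)(n−2)/2]` | Brandes accumulation; endpoints excluded; all zeros for `n < 3` |
| closeness | `1 / Σ_w d(v,w)` | literal reciprocal-of-sum form; differs from the `(n−1)/Σd` convention by the constant factor `n−1` on a fixed graph, so Top-k sets are identical either way |
| radiality | `Σ_w (δ_G + 1 − d(v,w)) / (n−1)` | Valente–Foreman form; bounded in `[1, δ_G]` |
| clustering | `2·e_N / (k_v(k_v−1))`, `e_N` = edges among neighbors | 0 when `k_v < 2` |
| topological coefficient | mean over partners `w` (≠ v, sharing ≥ 1 neighbor) of `J(v,w)/k_v`; `J` = shared-neighbor count, +1 if `v,w` adjacent | low for hubs; 0 without partners |
| neighborhood connectivity | mean degree of `v`'s neighbors | 0 for isolated nodes |

Tie-breaks and degenerate inputs: ortholog mapping resolves equal bit
scores by smaller e-value, then lexicographically smallest subject id; the
giant component resolves equal component sizes by smallest member id; Top-k
includes every node tied with the k-th value (so a "Top 50" can contain
more than 50 nodes — the only policy consistent with reporting, e.g., 57
proteins for a degree Top-50); an empty value map yields an empty set.

The scale-freeness diagnostic is an ordinary least-squares line through
log10(CCDF) vs log10(degree) over the unique positive degree values,
reporting the slope magnitude and R². For a pure power law `p(k) ~ k^−γ`
the CCDF slope magnitude is `γ − 1`. This is an exploratory diagnostic, not
a maximum-likelihood estimator, and it refuses inputs with fewer than 20
positive-degree nodes or no degree spread.

GO enrichment uses the exact hypergeometric upper tail
`P(X ≥ b) = Σ_{i=b}^{min(n,B)} C(B,i)C(N−B,n−i)/C(N,n)` (evaluated through
the scipy survival function; validated in the test suite against exact
big-integer summation over the full N ≤ 60 lattice to < 1e-10 relative
error). Filters are two independent per-term predicates applied
conjunctively and hence order-independently: raw `p < 0.001` (no
multiple-testing correction in the decision rule, matching the workflow's
convention; Benjamini–Hochberg q-values are emitted as an informational
column) and a generic-term filter `B ≤ 100` that removes broad categories.
Annotations are a flat gene→term table; no GO-DAG propagation is performed,
so counts are not comparable to tools that propagate annotations up the
ontology graph.

The functional-relevance pruning of candidate proteins is, in the original
manual workflow, expert curation against annotation databases. Here it is
an explicit, reproducible stand-in: a case-insensitive substring match of
configurable keywords (default: germination-relevant functional categories
— cell cycle, cell wall/endosperm, hormone signaling, metabolism, protein
modification/ubiquitination, signaling/transport, storage reserves) against
each candidate's GO term ids, term labels and free-text protein label. It
is a transparent operationalization, not a reconstruction of any specific
curator's decisions.

## The synthetic-study generator

The generator produces inputs with the statistical structure the analysis
assumes, so every stage is testable offline:

* **Background interactome**: Barabási–Albert preferential attachment
  (default `n = 2000` nodes, `m = 3` edges per new node), giving a
  connected simple graph with a heavy-tailed degree distribution whose
  CCDF diagnostic lands in the 1.5–3.5 exponent window.
* **Seed study**: 88 seed proteins by default, of which
  `round(map_fraction·n_seeds) = 68` receive exactly one ortholog hit to
  distinct, uniformly sampled network nodes (the *planted module*); the
  remaining 20 have no hit. Half the seeds are labelled up-accumulated.
  Each missing within-module edge is added with probability 0.3
  (`module_density`), which raises module degrees by ≈ 20 and makes the
  module rediscoverable by degree ranking.
* **Annotations**: 120 GO terms, sizes uniform on [50, 100] — large enough
  that planted terms clear `p < 0.001` against the expanded-subnetwork
  target with a wide margin, yet under the 100-gene generic-term cutoff.
  Five terms are planted: their genes are drawn with 20-fold sampling
  weight (`planted_odds`) on module members, so roughly 40% of a planted
  term lies in the 68-gene module. At `planted_odds = 1` planted terms are
  exactly background terms, which is the null-calibration case used in the
  tests. Namespaces (MF/BP) are assigned at random; planted terms carry
  germination-category labels so the default keyword filter finds them.

All randomness derives from one integer seed via SHA-256-based,
stage-labelled substreams; identical configs give byte-identical
serialized bundles (sorted, newline-normalized plain-text formats).

What the generator does **not** emulate: proteomics intensities and spot
statistics (seed tables are taken as given), sequence similarity (hits are
drawn, not aligned), degree-correlated annotation bias, GO-term overlap
structure/DAG hierarchy, multi-hit ortholog ambiguity (exercised instead by
hand-written fixtures), and interactome study bias. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's logic under
its own assumptions, not the biological validity of any particular real
dataset.

## Problem sizes in the test and acceptance runs

Unit tests run on graphs of 4–400 nodes; oracle comparisons use exhaustive
brute-force algorithms on 4–12-node random connected graphs (200 of them in
the acceptance suite, tolerance 1e-9). Null calibration uses 2000 term
draws on an 800-node background; the end-to-end planted-recovery check and
the acceptance script run the full default study (2000-node background,
giant component ≈ 350–450 nodes), which completes in seconds on one core.
These sizes were chosen as the smallest at which the studied effects
(scale-free tail, module detectability, enrichment power) are comfortably
expressed.

## Known limitations

* Centrality is exact but pure-Python/networkx; interactomes beyond ~10⁵
  edges will make all-pairs stages slow.
* The CCDF fit is a diagnostic; do not quote its exponent as a rigorous
  estimate.
* Enrichment without DAG propagation undercounts high-level term signal
  relative to GO-aware tools.
* "Stress centrality" (raw shortest-path counts) is sometimes used
  interchangeably with betweenness in this workflow's literature; only
  normalized betweenness is implemented.
* The keyword filter is a policy choice; different keyword lists give
  different key-protein sets, and the matched keyword per protein is
  reported so the decision is auditable.
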