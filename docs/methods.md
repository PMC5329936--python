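# Methods

This note records the model implemented by `drugpath`, the choices made
where the procedure was genuinely underdetermined, the defaults and why,
and what the synthetic benchmark does and does not establish.

## Pathway model

A drug's molecular action is modelled as directed signal flow across three
levels: initiation (drug target genes, TG), perturbation (pharmacogenomic
variant genes VG and differentially expressed genes DEG) and destination
(disease genes DisG and side-effect genes SEG). A drug is admitted only if
all five categories are non-empty; otherwise construction raises
`DrugExcludedError` — mirroring the admission filter that real studies of
this design apply before building pathways.

Construction runs per ordered seed pair (s, e), for initiation→perturbation
and perturbation→destination:

1. **All shortest paths.** Every directed shortest path s → e in the
   curated network is enumerated. The procedure could equally have kept a
   single shortest path; we enumerate *all* of them with a configurable cap
   (`max_paths`, default 100 per pair, deterministic lexicographic order,
   truncation recorded) because any single-path choice would be an
   arbitrary tie-break.
2. **Terminal filter.** Only paths whose final interaction type is
   pathway-terminating survive. Terminal types default to
   `transcription_regulation` and `translocation`; unknown interaction
   types are accepted anywhere and are simply never terminal. If the filter
   removes every shortest path, the pair yields nothing — there is no
   fallback to longer paths, since the filter is defined *among the
   shortest paths*.
3. **PPI front-augmentation.** Only when step 2 yields nothing (including
   when s is absent from the curated network) may undirected PPI edges form
   the front of the path: a simple PPI path s → x of 1..3 edges to a
   curated node x that has a surviving terminal-filtered shortest curated
   path to e. Among all simple combined paths the pair
   (prefix length, curated length) is minimised lexicographically and all
   minimisers are kept. The implementation enumerates *all* simple prefixes
   per length, not only shortest ones, because a shortest prefix can
   collide with every available curated tail while a same-length or longer
   simple prefix does not; an exhaustive-search oracle in the test suite
   holds the implementation to exactly this definition on random graphs.
   The terminal filter applies to the curated tail of augmented paths too.
   PPI edges are traversed undirected but recorded in walk direction with
   interaction type `ppi`.

Pairs with s = e are skipped. Pairs yielding nothing are counted per
segment but are not errors. Parallel curated edges (several interaction
types between one ordered node pair) are collapsed for traversal; a path
survives the terminal filter if *any* type on its last hop is terminal, and
the recorded representative type prefers the lexicographically smallest
terminal type on the last hop (smallest type elsewhere). This keeps
construction deterministic without inflating the path set combinatorially.

The drug pathway is the union of both segments' surviving paths, with
per-path provenance (segment, seed pair, PPI prefix length) and per-edge
origin (curated vs ppi). Gene membership extraction keeps gene-type nodes,
excludes compounds and RNAs, and by default expands complex nodes into
their member genes (`expand_complexes=True`), since validation against
curated drug-action pathways is conventionally done on member genes.

## Similarity

Gene-Sim is the Jaccard coefficient of the two pathways' gene-membership
sets. GO-Sim and KEGG-Sim are Jaccard coefficients of enriched-term sets:
a term is enriched if its hypergeometric upper-tail P against the gene
universe is below `alpha` (default 0.01), with **no** multiple-testing
correction by default — matching the classical enrichment-annotation
tools this replaces; a Benjamini–Hochberg option exists but is off. Terms
with zero overlap are never enriched. The default gene universe is the
union of curated gene-type nodes and PPI genes; Jaccard itself is
universe-independent, so the universe matters only for the enrichment
background (and is deliberately an explicit argument, because the
background used by external annotation services is generally unknown).

Both-empty profiles score 0, not 1: two drugs with no annotated content are
not evidence of similar action. Drugs with *empty pathways* are excluded
from similarity matrices entirely (logged) — their similarity is undefined,
not zero.

## Statistics

The hypergeometric upper tail P(X ≥ q) is computed by log-space summation
(`scipy.special.gammaln`/`logsumexp`) over the feasible support, exact to
working precision for universes up to ~1e5; the test suite cross-checks it
against exact rational enumeration (t ≤ 12, every feasible input) and
against an independent library implementation. The one-tailed Fisher exact
test is the same tail under the margin mapping t=a+b+c+d, m=a+c, k=a+b,
q=a; "one-tailed" always means the enrichment (greater) direction. Odds
ratios are (a·d)/(b·c); the Haldane–Anscombe 0.5 correction is opt-in, and
applied automatically only inside `overlap_enrichment` so reported ratios
stay finite when a cell is zero.

## Association transfer and threshold selection

For each similarity measure, each drug's known associations transfer to
every other drug at or above threshold θ (similarity is symmetric, so
transfer is bidirectional); pairs already known are removed, making
candidates disjoint from the known set by construction. θ is selected per
measure by scanning a grid (default 0.00–1.00, step 0.01; an
observed-values grid can be supplied instead) and minimising the candidate
set's one-tailed enrichment P against the reference associations.
Thresholds with empty candidate sets are recorded as *untestable*, not
assigned P = 1. Ties at the minimum break to the **largest** threshold
(fewer, higher-confidence candidates). The enrichment universe is the
drug-roster × phenotype-vocabulary grid minus known pairs, because the
candidates exclude known pairs by construction and leaving them in would
distort the margins; `include_known=True` restores the alternative.
Predictions are the intersection of the three per-measure candidate sets —
deliberately conservative, sets rather than ranked lists. Side-effect
prediction is the identical machinery with side-effect known/reference
tables.

## Synthetic data

The generator produces what the method consumes, not a simulacrum of any
particular database:

* **Curated network** — 600 genes, 40 compounds, 20 complexes, 12 RNAs,
  2,600 directed typed edges; 25% of edges carry a terminal type. The
  graph is *modular*: nodes belong to 12 modules and 85% of edges stay
  within their source's module, with preferential attachment inside the
  choice set (Erdős–Rényi available). Modularity is essential realism:
  curated pathway unions are strongly modular, and without it every drug's
  shortest paths funnel through the same global hubs and all pathways
  converge on one common core.
* **PPI** — 1,500 undirected edges over the gene pool.
* **Drugs** — 20 drugs in 4 clusters. Per-drug seed totals are drawn from
  the 165 ± 43 calibration and scaled by `size_factor` (default 0.2, so
  ~33 genes/drug) to keep test bundles fast; category shares are TG 8%,
  VG 12%, DEG 45%, DisG 20%, SEG 15%, each at least 1. Cluster-mates draw
  70% of each category from cluster pools that live inside the cluster's
  own modules.
* **Catalogues** — 80 GO-BP-like and 40 KEGG-like terms, each anchored 70%
  to one module. Anchoring matters: fully random term membership is never
  enriched in module-localised pathways, which would make GO/KEGG-Sim
  identically zero.
* **Associations** — per cluster, 6 planted phenotypes; for each, the
  cluster's drugs are split into known holders and withheld drugs (the
  planted truth), plus 2 random background known pairs per drug. The
  reference set is the planted truth plus 10% noise pairs. Known and
  planted truth are disjoint by construction.

Everything derives from `rng_seed`; identical seeds give byte-identical
bundles (manifest checksums verify this).

What passing the planted-recovery benchmark shows: the full chain —
pathway construction, all three similarity measures, enrichment-driven
threshold selection, intersection — can re-discover withheld cluster-level
associations well above a label-permutation baseline. What it does **not**
show: performance on real pharmacological data, where identifier mapping,
annotation bias, incomplete networks and non-cluster-like similarity
structure all intrude; nor anything about the absolute calibration of the
enrichment p-values under dependence between pairs.

## Numerical and procedural details

* Determinism everywhere: sorted iteration orders, lexicographic path
  ordering, fixed tie-breaks; two runs on the same inputs produce
  bitwise-identical outputs (asserted end-to-end in the tests).
* Curated shortest-path enumeration walks the BFS distance DAG with a
  reverse-BFS distance map shared across all starts for one end, keeping
  whole-bundle construction at seconds.
* `max_paths` truncation is recorded per pair; at the default study sizes
  truncation is rare and affects only how many parallel equal-length paths
  are stored.
* Degenerate inputs fail loudly: empty seed categories, empty universes,
  infeasible hypergeometric counts, all-zero contingency tables, empty
  candidate sets (as *untestable*, distinguished from P = 1).
* The problem sizes used in the shipped tests and acceptance run (20-drug
  bundles, ≤ 12-node oracle graphs, 20-seed recovery replicates) were
  chosen so the complete suite runs in about a minute on one core.

## Known limitations

* The second pathway segment starts from the perturbation *seed* genes
  only, not from nodes reached by the first segment; the alternative
  reading (chaining through reached nodes) is noted but not implemented.
* No edge-sign semantics: activation vs inhibition does not modulate path
  validity — only direction and the terminal types matter.
* No semantic (information-content) GO similarity; profiles are
  enrichment-membership vectors by design.
* Predictions are unranked sets; downstream prioritisation is out of
  scope.
* Identifier normalisation across databases is treated as a data-
  preparation concern; all ids are opaque strings.
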