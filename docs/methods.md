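# Methods

## Interactome model

The unit of input is one row of binary interaction evidence: two interactor
gene symbols, two NCBI taxon IDs, an "experimentally verified" flag, a
"physical binding" flag and a list of supporting publication IDs. Column
mapping is configurable so both simple TSVs and PSI-MITAB 2.6 exports can
be consumed (MITAB taxa and publications carry `taxid:`/`pubmed:` prefixes;
the interaction-type column is matched against "physical"/"direct
interaction"; a present detection method counts as experimental evidence).

A record is retained iff all four criteria hold: experimental, both taxa
equal to the target taxon (default mouse, 10090), at least one publication,
physical binding. Retained records form an undirected simple graph; A–B /
B–A mirrors collapse to one edge, and self-interactions are dropped by
default because every downstream similarity is defined over interaction
*partners* (a configuration flag keeps them). Gene symbols are upper-cased
once at parse time so joins against module and regulator tables are exact
string matches; the published tables mix symbol casing, and any fuzzier
matching would make joins non-deterministic. Malformed rows are logged with
their row number and skipped — never silently dropped, never fatal —
whereas a missing column is a configuration error raised immediately.

"Hub" has no standard definition; `ProteinNetwork.hubs` takes the top
fraction of the degree distribution (default 10%), including all ties at
the cutoff degree so the result does not depend on sort order.

## Neighborhood similarity and the PNSM

For genes *A*, *B* with neighborhoods N(A), N(B):

* Simpson (overlap) index: |N(A) ∩ N(B)| / min(|N(A)|, |N(B)|). Undefined
  when either gene has no partners (error; callers must exclude degree-0
  genes).
* Jaccard index: |N(A) ∩ N(B)| / |N(A) ∪ N(B)|. Undefined only when both
  are isolated.

Simpson ≥ Jaccard always, with Simpson = 1 whenever the smaller
neighborhood is nested in the larger — the property that motivates it for
scale-free interactomes: adding partners to only the higher-degree gene of
a pair leaves Simpson unchanged while Jaccard decays. The pair's own edge
never counts as a shared partner (without self-loops this is automatic:
neither gene can be a member of its own neighborhood).

The PNSM is assembled over a candidate list (the module-assigned genes).
Candidates absent from the network or with degree 0 are dropped and the
retained/dropped split logged — mirroring the situation in real module
catalogs, where only a minority of module genes have any curated
interaction. Fewer than two retained genes aborts the pipeline. The matrix
is dense float64 (the realistic upper end, a few thousand genes, is ~tens
of MB); the diagonal is a preference slot left at 0 until clustering.

## Affinity propagation

Input is the similarity matrix S with preferences on the diagonal. Update
rules, with messages initialized to zero:

    r(A,B) <- s(A,B) - max_{B' != B} { a(A,B') + s(A,B') }
    a(A,B) <- min{ 0, r(B,B) + sum_{A' not in {A,B}} max(0, r(A',B)) }   (A != B)
    a(B,B) <- sum_{A' != B} max(0, r(A',B))

Both message matrices are damped, `m <- λ·m_old + (1-λ)·m_new`, default
λ = 0.5 (valid range [0.5, 1)): undamped messages oscillate on symmetric
inputs. Exemplars are the points with a(B,B) + r(B,B) > 0; the run stops
when that set is unchanged for 50 consecutive iterations (cap 1000). A run
that hits the cap returns `converged=False` with a warning rather than
raising. The vectorized updates are tested entry-for-entry against a naive
double-loop transcription of the rules.

Numerical and design choices:

* **Preference.** Default is the median of the off-diagonal similarities,
  broadcast as one shared scalar — the convention of the original
  algorithm; an explicit scalar or per-gene vector is accepted. Raising
  preferences can only increase the exemplar count (checked empirically in
  the tests over a preference grid).
* **Tie-breaking jitter.** A symmetric similarity matrix makes every
  within-cluster pair a perfectly matched pair of exemplar competitors;
  with exact ties the competitors can suppress each other and the cluster
  collapses onto a neighboring one. Optional additive noise of magnitude
  `noise_scale · range(S)` (seeded, default off) breaks these ties. The
  jitter perturbs only the message computation; exemplar assignment and
  the net-similarity objective are always evaluated on the clean matrix.
* **Final exemplar refinement.** After convergence, each cluster's
  exemplar is re-chosen as the member maximizing the summed similarity
  from the cluster (one medoid pass, as in the algorithm's published
  reference implementation). Damped messages can converge to the right
  partition but an off-by-one exemplar identity; the refinement is a
  direct local improvement of the objective.
* **Objective.** `net_similarity` = Σ_non-exemplars s(A, exemplar(A)) +
  Σ_exemplars s(B,B). `brute_force_exemplars` maximizes the same objective
  by enumerating every nonempty exemplar subset (guarded to n ≤ 12), with
  lexicographic tie-breaking, and serves as the exact oracle in tests.

**Where oracle equality holds.** On structurally well-separated matrices —
at least two blocks, every block of size ≥ 2, between-block pairs in the
majority so the median preference falls in the between-block value band —
converged message passing attains the brute-force optimum (tested over 100
random draws). Outside that regime the objective develops near-ties:
a dominant single block pushes the median preference into the
within-similarity band (splitting a cluster becomes nearly free), and a
singleton cluster's preference ties with its cross-similarities. On such
draws message passing may converge to a near-optimal configuration; the
reference implementation in scikit-learn shows the identical behavior on
the identical matrices, so this is a property of the algorithm, not of
this implementation.

The estimator (`AffinityPropagation`) follows scikit-learn conventions
(`fit`/`fit_predict`, `get_params`/`set_params`, trailing-underscore fitted
attributes) and accepts either a `SimilarityMatrix` or a square array;
scikit-learn's own affinity propagation is used in the test suite as an
independent cross-check on planted-block fixtures, never as the
implementation.

## Lineage association

The wiring is cell type → activators (the packaged ten-cell-type regulator
catalog) → modules (a regulator–module table) → genes (a gene–module
table). An exemplar associates with a cell type when at least `min_genes`
(default 1 — the weakest defensible reading, configurable for sensitivity
analysis) of its member genes lie in modules driven by ≥ 1 of that cell
type's regulators. Classes: lineage-specific (exactly 1 cell type), common
(all), shared (otherwise); exemplars with associations are partitioned
exhaustively by these three classes, and an exemplar whose genes hit no
regulated module is reported as unassociated rather than silently dropped.
Module regulation is an *input* (or planted by the generator) — it is
never inferred from expression; module inference itself is out of scope.

Module coverage reports, per module, the percentage of member genes with
degree ≥ 1 in the filtered network, flagging zero-interactor modules.

Bipartite views: the exemplar↔cell-type simple graph annotates every node
with a degree class (low/intermediate/high at thirds of the maximum degree
on its side — the usual green/yellow/red gradient); the regulator↔module
multigraph draws one parallel edge per distinct exemplar represented in a
regulated module, keyed by exemplar ID, so the edge multiplicity reads as
the diversity of interaction mechanisms a regulator drives. Both export to
GraphML (attributes preserved) and SIF (multigraph edges keep distinct
relation labels).

## Enrichment

Upper-tail hypergeometric test per (cluster, term): with universe size N
(default: the genes retained in the PNSM; the background is configurable
because no canonical choice exists), term size K, cluster size n, overlap
k, p = P(X ≥ k); k = 0 gives p = 1. Benjamini–Hochberg adjustment (via
statsmodels) across terms within a cluster, significance at adjusted
p ≤ 0.05 by default with a raw-p mode. Annotations can be propagated up a
child→parent term DAG (true-path rule, set unions, cycle detection names
an offending term), and the significance trajectory induces the subgraph
of significant terms plus their ancestor paths, always retaining the root.
The p-values are validated against exact integer-arithmetic tail sums for
every configuration with N ≤ 20 and against literal subset enumeration at
small N. Published per-term p-values from service-based enrichment tools
are not reproduction targets: they depend on tool versions and annotation
snapshots.

## Synthetic data: what it emulates, what it does not

`generate_interactome` plants `n_groups` groups of `group_size` genes, each
group wired to its own `within_shared_partners` common partner genes, on
top of a preferential-attachment background (m = 2) over the non-planted
pool, plus uniform noise edges (probability `noise_edge_prob` per pair).
The planted signal is *similarity of neighborhoods* — the quantity the
clustering actually sees — not edge density within groups. Defaults
(chosen once as the study conditions): 200 genes, 5 groups × 20, 8 shared
partners, noise 0.01, module coverage 0.3, two zero-interactor decoy
modules, 10 decoy terms; the standard dataset fixes seed 7. With these
conditions intra-group mean Simpson ≥ 0.8 and inter-group ≤ 0.1.

`generate_lineage` places each group in one module, pads modules with
inert genes to the requested interactome coverage, wires all but the last
group to a single cell type through a regulator owned by that cell type
alone (regulators shared between cell types — e.g. the myeloid/B-cell
activator SFPI1 — would leak associations, so cell types without a
uniquely-owned regulator cannot host a specific plant), and wires the last
group to one regulator of every cell type. `generate_annotations` plants
one term per group covering 90% of its genes plus random decoys under a
three-level DAG. All generators are deterministic in their seeds.

What passing on synthetic data does **not** show: real interactomes have
correlated study bias (hub genes are better studied), module catalogs
overlap and nest rather than partition, regulator–module wiring is
inferred with error, and real annotation terms are heavily redundant. The
planted structure is deliberately clean so that failures indict the
implementation, not the data.

## Known limitations

* Exemplar counts and memberships at full scale are sensitive to the
  interactome snapshot; only distributional and planted-truth properties
  are asserted, not published cluster memberships.
* The association rule (min_genes = 1) is permissive; a fraction-based
  threshold is available but the published analysis gives no calibration
  target.
* Enrichment assumes a fixed universe and independent terms; no
  term-term correlation correction beyond BH.
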