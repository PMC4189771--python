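# exemplarnet

Differential protein-network analysis of the immune cell lineage.

Immune cell types — from hematopoietic stem cells through granulocytes,
monocytes, macrophages, dendritic cells, NK cells, B cells and T cells —
share a common progenitor yet run very different molecular programs.
Gene-expression compendia of the mouse immune system organize genes into
regulatory modules driven by known lineage activators, but expression alone
says little about which *protein interaction* mechanisms those programs
engage. `exemplarnet` asks: which groups of proteins share interaction
partners in the mouse interactome, and are those groups wired to one
immune lineage or to all of them?

The pipeline:

1. **Interactome filtering.** Binary protein interaction evidence is kept
   only if it is (a) experimentally verified, (b) intra-species for the
   target taxon (mouse, 10090), (c) backed by at least one publication and
   (d) a physical binding interaction; surviving records form an
   undirected, deduplicated network.
2. **Protein network similarity matrix (PNSM).** For every pair of
   module-assigned genes *A*, *B* with at least one interaction partner,
   the Simpson overlap

   S(A,B) = |N(A) ∩ N(B)| / min(|N(A)|, |N(B)|)

   scores their shared partners relative to the least-connected gene — a
   deliberate choice for scale-free interactomes, where degrees span orders
   of magnitude and the Jaccard index (also provided) would penalize any
   low-degree gene paired with a hub.
3. **Affinity propagation.** The PNSM is clustered by message passing:
   responsibilities r(A,B) and availabilities a(A,B) are exchanged until a
   stable set of *exemplars* emerges — genes whose interaction neighborhood
   typifies a group of genes with similar partners. The diagonal
   preference s(A,A) is set to the median of the off-diagonal similarities,
   so the number of clusters is not specified in advance. A brute-force
   exemplar-set search over all subsets serves as an exact oracle on small
   matrices.
4. **Lineage association.** Each exemplar cluster is joined to cell types
   through the chain cell type → transcriptional activators → regulatory
   modules → member genes, then classified *lineage-specific* (exactly one
   cell type), *common* (all ten) or *shared* (in between). Two bipartite
   views are exported (exemplar ↔ cell type; regulator ↔ module with one
   parallel edge per exemplar) as GraphML/SIF.
5. **Term enrichment.** Upper-tail hypergeometric over-representation of
   annotation terms (GMT format) in each cluster, Benjamini–Hochberg
   adjusted, with optional true-path propagation up a term DAG and a
   "significance trajectory" subgraph of significant terms plus their
   ancestor paths.

A synthetic-data module generates scale-free interactomes with planted
shared-neighborhood groups, padded regulatory modules with controlled
interactome coverage, decoy modules, and planted annotation terms, so the
whole pipeline is testable end to end at desk scale with known ground
truth. Packaged reference tables transcribe the published ten-cell-type
regulator catalog and the published lineage-specific (19 rows) and common
(25 rows) exemplar tables.

## Worked example

```python
from exemplarnet.synthetic import generate_dataset
from exemplarnet.pnsm import build_pnsm
from exemplarnet.affinity import AffinityPropagation
from exemplarnet.lineage import associate_exemplars

data = generate_dataset(seed=7)            # 5 planted groups x 20 genes
lmap = data["lineage_map"]
pnsm = build_pnsm(data["network"], sorted(lmap.module_assignment))
ap = AffinityPropagation().fit(pnsm)       # sklearn-style estimator
print(f"{len(ap.result_.exemplars)} exemplars, converged={ap.converged_}, "
      f"net similarity {ap.net_similarity_:.2f}")
table = associate_exemplars(ap.result_, lmap)
print(table[["exemplar", "n_cell_types", "specificity"]].to_string(index=False))
```

prints

```
5 exemplars, converged=True, net similarity 95.00
exemplar  n_cell_types      specificity
GENE0001             1 lineage-specific
GENE0024             1 lineage-specific
GENE0049             1 lineage-specific
GENE0061             1 lineage-specific
GENE0080            10           common
```

The five exemplars are the planted groups: clustering found one exemplar
gene per group (net similarity 95 = 95 members at similarity 1.0 to their
exemplar plus five median preferences of 0), four groups associate with
exactly one cell type each and the fifth with all ten — exactly the
planted specificity structure.

The same analysis is scriptable from the shell:

```sh
exemplarnet simulate --out-dir data --seed 7
exemplarnet run config.yaml        # filter -> pnsm -> cluster -> integrate -> enrich -> export
```

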