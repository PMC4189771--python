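"""Term over-representation in exemplar clusters.

For each (gene set, term) pair, an upper-tail hypergeometric test asks
whether the overlap k between the gene set (size n) and the term's
annotated genes (size K) within a universe of N genes is larger than
chance: p = P(X >= k) for X ~ Hypergeom(N, K, n).  Benjamini–Hochberg
controls the FDR across terms.  Annotations may be propagated up a term DAG
(true-path rule: a gene annotated to a term is annotated to all its
ancestors) before testing, and the significant terms can be marked on the
DAG together with their ancestor paths — the "significance trajectory"
through the process tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """One term with its annotated genes."""

    term_id: str
    name: str
    genes: set[str]
    namespace: str = "biological_process"


@dataclass
class EnrichmentResult:
    gene_set_id: str
    term_id: str
    term_name: str
    overlap: int          # k
    gene_set_size: int    # n
    term_size: int        # K
    universe_size: int    # N
    p_value: float
    adjusted_p: float = float("nan")
    significant: bool = False


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """Parse a GMT file (term, description, gene...) into annotation sets."""
    sets = []
    with Path(path).open() as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(
                AnnotationSet(
                    term_id=parts[0],
                    name=parts[1],
                    genes={g.upper() for g in parts[2:] if g},
                )
            )
    return sets


def write_gmt(sets: Iterable[AnnotationSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.name, *sorted(s.genes)]) + "\n")


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives 1.0."""
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    gene_set: Iterable[str],
    annotations: Sequence[AnnotationSet],
    universe: Iterable[str],
    gene_set_id: str = "query",
    alpha: float = 0.05,
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Score every term against one gene set.

    Genes are upper-cased; the gene set and each term are intersected with
    the universe before counting.  Terms left empty by the universe
    intersection are skipped.  When ``adjust`` is set, BH-adjusted p-values
    and a significance flag at level ``alpha`` are filled in.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ConfigurationError("enrichment universe is empty")
    query = {g.upper() for g in gene_set} & universe_set
    results = []
    for ann in annotations:
        term_genes = ann.genes & universe_set
        if not term_genes:
            continue
        k = len(query & term_genes)
        p = hypergeom_pvalue(len(universe_set), len(term_genes), len(query), k)
        results.append(
            EnrichmentResult(
                gene_set_id=gene_set_id,
                term_id=ann.term_id,
                term_name=ann.name,
                overlap=k,
                gene_set_size=len(query),
                term_size=len(term_genes),
                universe_size=len(universe_set),
                p_value=p,
            )
        )
    if adjust and results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.adjusted_p = float(q)
            r.significant = q <= alpha
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_set": r.gene_set_id,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "overlap": r.overlap,
                "gene_set_size": r.gene_set_size,
                "term_size": r.term_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def load_dag(path: str | Path) -> nx.DiGraph:
    """Term DAG from a two-column child→parent TSV (header: child, parent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"child", "parent"}.issubset(df.columns):
        raise ValidationError("DAG table needs 'child' and 'parent' columns")
    g = nx.DiGraph()
    for c, p in zip(df["child"], df["parent"]):
        g.add_edge(str(c).strip(), str(p).strip())
    return g


def _check_acyclic(dag: nx.DiGraph) -> None:
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        return
    raise ValidationError(
        f"term graph contains a cycle involving {cycle[0][0]!r}"
    )


def propagate_annotations(
    dag: nx.DiGraph, annotations: Sequence[AnnotationSet]
) -> list[AnnotationSet]:
    """True-path propagation: each term's gene set gains every descendant's
    genes (edges point child → parent).  Terms on the DAG without direct
    annotations are created empty and filled by propagation; set union keeps
    diamond-shaped ancestry from double counting."""
    _check_acyclic(dag)
    by_id = {a.term_id: AnnotationSet(a.term_id, a.name, set(a.genes), a.namespace)
             for a in annotations}
    for term in dag.nodes:
        if term not in by_id:
            by_id[term] = AnnotationSet(term, term, set())
    # children first: reversed topological order of the child->parent DAG
    for term in nx.topological_sort(dag):
        for parent in dag.successors(term):
            by_id[parent].genes |= by_id[term].genes
    return list(by_id.values())


def significance_trajectory(
    dag: nx.DiGraph,
    results: Iterable[EnrichmentResult],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> nx.DiGraph:
    """Subgraph of significant terms plus their ancestor paths to the root.

    Nodes carry a boolean ``significant`` mark; ancestors pulled in only to
    complete paths are unmarked.  Root nodes (no parents) are always kept so
    an empty significant set still yields the root-only graph.
    """
    _check_acyclic(dag)
    significant = set()
    for r in results:
        p = r.adjusted_p if use_adjusted else r.p_value
        if np.isfinite(p) and p <= alpha and r.term_id in dag:
            significant.add(r.term_id)
    keep = set(significant)
    for term in significant:
        keep |= nx.descendants(dag, term)  # ancestors along child->parent edges
    roots = {n for n in dag.nodes if dag.out_degree(n) == 0}
    keep |= roots
    sub = dag.subgraph(keep).copy()
    for n in sub.nodes:
        sub.nodes[n]["significant"] = n in significant
    return sub
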