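"""Joining exemplar clusters to immune-cell lineages.

The chain runs cell type → transcriptional activators (regulators) →
regulatory modules of co-expressed genes → member genes.  An exemplar
cluster is associated with a cell type when enough of its member genes sit
in modules driven by at least one of that cell type's regulators.  Exemplars
associated with exactly one cell type are *lineage-specific*; with every
cell type, *common*; otherwise *shared*.

Two bipartite views are built: exemplar ↔ cell type (simple graph, with a
low/intermediate/high degree-class annotation for the usual green→yellow→red
gradient) and regulator ↔ module (multigraph, one parallel edge per distinct
exemplar represented in the module — a visual measure of how many distinct
protein-network mechanisms a regulator drives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .affinity import APResult
from .errors import ValidationError
from .interactome import ProteinNetwork

logger = logging.getLogger(__name__)

SPECIFICITY_CLASSES = ("lineage-specific", "shared", "common")


@dataclass
class LineageMap:
    """cell type → regulators → modules → genes wiring."""

    cell_types: list[str]
    regulators: dict[str, set[str]]           # cell type -> activator symbols
    module_assignment: dict[str, str] = field(default_factory=dict)   # gene -> module
    module_regulation: set[tuple[str, str]] = field(default_factory=set)  # (regulator, module)

    def regulators_of(self, cell_type: str) -> set[str]:
        return self.regulators.get(cell_type, set())

    def modules_of_cell_type(self, cell_type: str) -> set[str]:
        regs = self.regulators_of(cell_type)
        return {m for (r, m) in self.module_regulation if r in regs}

    def genes_of_module(self, module: str) -> set[str]:
        return {g for g, m in self.module_assignment.items() if m == module}


def load_regulator_table(path: str | Path) -> LineageMap:
    """Parse the cell-type → activators TSV (columns: cell_type, activators
    with comma-separated symbols).  Symbols are upper-cased; a regulator may
    legitimately serve several cell types.  A blank activator list is a
    validation error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_type", "activators"}.issubset(df.columns):
        raise ValidationError(
            "regulator table needs 'cell_type' and 'activators' columns"
        )
    cell_types: list[str] = []
    regulators: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        ct = str(row["cell_type"]).strip()
        raw = row["activators"]
        acts = {
            a.strip().upper()
            for a in str(raw if pd.notna(raw) else "").split(",")
            if a.strip()
        }
        if not acts:
            raise ValidationError(f"cell type {ct!r} has an empty activator list")
        cell_types.append(ct)
        regulators[ct] = acts
    return LineageMap(cell_types=cell_types, regulators=regulators)


def load_module_table(path: str | Path) -> dict[str, str]:
    """gene → module_id from a two-column TSV (gene, module_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "module_id"}.issubset(df.columns):
        raise ValidationError("module table needs 'gene' and 'module_id' columns")
    return {
        str(g).strip().upper(): str(m).strip()
        for g, m in zip(df["gene"], df["module_id"])
    }


def load_regulation_table(path: str | Path) -> set[tuple[str, str]]:
    """(regulator, module_id) pairs from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"regulator", "module_id"}.issubset(df.columns):
        raise ValidationError(
            "regulation table needs 'regulator' and 'module_id' columns"
        )
    return {
        (str(r).strip().upper(), str(m).strip())
        for r, m in zip(df["regulator"], df["module_id"])
    }


def classify_specificity(n_associated: int, n_cell_types: int) -> str:
    if n_associated == 1:
        return "lineage-specific"
    if n_associated == n_cell_types:
        return "common"
    return "shared"


def associate_exemplars(
    result: APResult, lmap: LineageMap, min_genes: int = 1
) -> pd.DataFrame:
    """Associate each exemplar cluster with cell types and classify it.

    An exemplar is associated with cell type ``c`` iff at least ``min_genes``
    of its member genes lie in modules regulated by one of ``c``'s
    regulators.  Returns a table with columns (exemplar, genes, cell_types,
    n_cell_types, specificity).  Exemplars with no module-mapped genes are
    excluded and logged; genes without a module assignment are logged as
    unmapped.
    """
    if min_genes < 1:
        raise ValidationError("min_genes must be >= 1")
    modules_per_ct = {ct: lmap.modules_of_cell_type(ct) for ct in lmap.cell_types}
    unmapped = {
        g for g in result.assignment if g not in lmap.module_assignment
    }
    if unmapped:
        logger.info("%d clustered genes have no module assignment", len(unmapped))
    rows = []
    for exemplar, members in sorted(result.clusters().items()):
        mapped = {g: lmap.module_assignment[g] for g in members if g in lmap.module_assignment}
        if not mapped:
            logger.warning(
                "exemplar %s has no module-mapped genes; excluded from the "
                "lineage table", exemplar,
            )
            continue
        associated = []
        for ct in lmap.cell_types:
            hits = sum(1 for m in mapped.values() if m in modules_per_ct[ct])
            if hits >= min_genes:
                associated.append(ct)
        if not associated:
            specificity = "unassociated"
        else:
            specificity = classify_specificity(len(associated), len(lmap.cell_types))
        rows.append(
            {
                "exemplar": exemplar,
                "genes": ",".join(sorted(members)),
                "cell_types": ",".join(associated),
                "n_cell_types": len(associated),
                "specificity": specificity,
            }
        )
    return pd.DataFrame(rows, columns=["exemplar", "genes", "cell_types", "n_cell_types", "specificity"])


def _degree_class(degree: int, max_degree: int) -> str:
    if max_degree <= 0:
        return "low"
    frac = degree / max_degree
    if frac <= 1 / 3:
        return "low"
    if frac <= 2 / 3:
        return "intermediate"
    return "high"


def build_cell_exemplar_bipartite(table: pd.DataFrame) -> nx.Graph:
    """Exemplar ↔ cell-type bipartite graph from an association table.

    Node attribute ``bipartite`` is "exemplar" or "cell_type"; every node
    carries a ``degree_class`` in {low, intermediate, high} scaled to the
    maximum degree of its class (the color-gradient annotation).
    """
    if table.empty:
        raise ValidationError("association table is empty")
    g = nx.Graph()
    for _, row in table.iterrows():
        ex = row["exemplar"]
        g.add_node(ex, bipartite="exemplar")
        for ct in str(row["cell_types"]).split(","):
            ct = ct.strip()
            if not ct:
                continue
            g.add_node(ct, bipartite="cell_type")
            g.add_edge(ex, ct)
    for side in ("exemplar", "cell_type"):
        nodes = [n for n, d in g.nodes(data=True) if d["bipartite"] == side]
        max_deg = max((g.degree(n) for n in nodes), default=0)
        for n in nodes:
            g.nodes[n]["degree_class"] = _degree_class(g.degree(n), max_deg)
    return g


def build_regulator_module_multigraph(
    result: APResult, lmap: LineageMap
) -> nx.MultiGraph:
    """Regulator ↔ module multigraph: for every regulated (regulator,
    module) pair, one parallel edge per distinct exemplar with at least one
    member gene in that module.  Edge attributes carry the exemplar ID and
    the regulator's cell type(s)."""
    g = nx.MultiGraph()
    cell_types_of_reg: dict[str, list[str]] = {}
    for ct, regs in lmap.regulators.items():
        for r in regs:
            cell_types_of_reg.setdefault(r, []).append(ct)
    exemplars_in_module: dict[str, set[str]] = {}
    for exemplar, members in result.clusters().items():
        for gene in members:
            module = lmap.module_assignment.get(gene)
            if module is not None:
                exemplars_in_module.setdefault(module, set()).add(exemplar)
    for regulator, module in sorted(lmap.module_regulation):
        g.add_node(regulator, bipartite="regulator",
                   cell_types=",".join(sorted(cell_types_of_reg.get(regulator, []))))
        g.add_node(module, bipartite="module")
        for exemplar in sorted(exemplars_in_module.get(module, ())):
            g.add_edge(
                regulator, module, key=exemplar, exemplar_id=exemplar,
                cell_types=",".join(sorted(cell_types_of_reg.get(regulator, []))),
            )
    return g


def module_coverage(
    module_assignment: dict[str, str], network: ProteinNetwork
) -> pd.DataFrame:
    """Per-module interactome coverage: the percentage of member genes with
    at least one interaction.  Modules at 0% are flagged."""
    rows = []
    modules: dict[str, list[str]] = {}
    for gene, module in module_assignment.items():
        modules.setdefault(module, []).append(gene)
    for module, genes in sorted(modules.items()):
        n_cov = sum(1 for g in genes if network.degree(g) >= 1)
        pct = 100.0 * n_cov / len(genes)
        rows.append(
            {
                "module_id": module,
                "n_genes": len(genes),
                "n_with_interaction": n_cov,
                "coverage_pct": pct,
                "zero_interactors": n_cov == 0,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["module_id", "n_genes", "n_with_interaction", "coverage_pct", "zero_interactors"],
    )
    n_zero = int(df["zero_interactors"].sum()) if not df.empty else 0
    if n_zero:
        logger.info("%d module(s) have zero interactors", n_zero)
    return df
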