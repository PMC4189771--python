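"""Synthetic interactomes, module structures, lineage wirings and
annotations with planted ground truth.

The generator emulates the statistical shape of the real inputs rather than
their content: a scale-free background interactome grown by preferential
attachment; planted groups of genes that share a common set of partner
proteins (so intra-group neighborhood similarity is high — the signal the
exemplar clustering actually detects); partial interactome coverage of
regulatory modules (only a fraction of module genes have any interaction,
achieved by padding modules with inert genes); decoy modules with zero
interactors; and a ten-cell-type lineage in which planted groups are wired
either to a single cell type (through a regulator that serves only that
type) or to every cell type.

All generators are deterministic in their seed, and the planted truth is
recorded alongside every emitted file.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import AnnotationSet, write_gmt
from .errors import ValidationError
from .interactome import MOUSE_TAXON, ProteinNetwork
from .lineage import LineageMap

logger = logging.getLogger(__name__)

#: default study conditions for the standard desk-scale dataset
DEFAULTS = dict(
    n_genes=200,
    n_groups=5,
    group_size=20,
    within_shared_partners=8,
    background_attachment=2,
    noise_edge_prob=0.01,
    coverage=0.3,
    n_decoy_modules=2,
    n_decoy_terms=10,
    term_size_range=(5, 30),
)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated dataset."""

    groups: dict[str, list[str]]            # group id -> member genes
    cell_types: dict[str, list[str]]        # group id -> planted cell types
    terms: dict[str, str]                   # group id -> planted term id
    shared_partners: dict[str, list[str]]   # group id -> common partner genes
    coverage: float
    seed: int | None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, genes in self.groups.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValidationError(
                    f"planted groups overlap on {sorted(overlap)[:3]}..."
                )
            seen |= set(genes)

    def partition_labels(self, genes: list[str]) -> list[int]:
        """Integer group label per gene (for ARI against a clustering)."""
        label_of = {}
        for i, (gid, members) in enumerate(sorted(self.groups.items())):
            for g in members:
                label_of[g] = i
        return [label_of[g] for g in genes]

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def generate_interactome(
    n_genes: int = DEFAULTS["n_genes"],
    n_groups: int = DEFAULTS["n_groups"],
    group_size: int = DEFAULTS["group_size"],
    within_shared_partners: int = DEFAULTS["within_shared_partners"],
    background_attachment: int = DEFAULTS["background_attachment"],
    noise_edge_prob: float = DEFAULTS["noise_edge_prob"],
    seed: int | None = None,
) -> tuple[ProteinNetwork, SyntheticTruth]:
    """Scale-free interactome with planted shared-neighborhood groups.

    ``n_genes`` counts the planted genes plus the background pool; each
    planted group's members are all wired to the same ``within_shared_partners``
    partner genes drawn from the pool, so the intra-group Simpson similarity
    is ~1 while inter-group similarity stays near 0.  The pool (partners
    included) is grown into a preferential-attachment background with
    ``background_attachment`` edges per new node, giving hubs a heavy
    degree tail; uniform noise edges are then overlaid with probability
    ``noise_edge_prob`` per gene pair.
    """
    n_planted = n_groups * group_size
    n_pool = n_genes - n_planted
    if n_planted > n_genes:
        raise ValidationError("n_groups * group_size exceeds n_genes")
    if n_pool < n_groups * within_shared_partners:
        raise ValidationError(
            "background pool too small for the requested shared partners"
        )
    if not 0 <= noise_edge_prob <= 1:
        raise ValidationError("noise_edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    planted = [f"GENE{i:04d}" for i in range(n_planted)]
    pool = [f"BG{i:04d}" for i in range(n_pool)]
    groups = {
        f"group{g + 1}": planted[g * group_size:(g + 1) * group_size]
        for g in range(n_groups)
    }
    partner_sets = {
        gid: pool[g * within_shared_partners:(g + 1) * within_shared_partners]
        for g, gid in enumerate(sorted(groups))
    }

    graph = nx.Graph()
    graph.add_nodes_from(planted + pool)
    # scale-free background over the pool (partner genes become hubs once
    # the planted members attach to them)
    if n_pool >= background_attachment + 1:
        ba_seed = int(rng.integers(0, 2**31 - 1))
        ba = nx.barabasi_albert_graph(n_pool, background_attachment, seed=ba_seed)
        for u, v in ba.edges:
            graph.add_edge(pool[u], pool[v])
    for gid, members in groups.items():
        for gene in members:
            for partner in partner_sets[gid]:
                graph.add_edge(gene, partner)
    if noise_edge_prob > 0:
        all_genes = planted + pool
        n = len(all_genes)
        iu = np.triu_indices(n, k=1)
        mask = rng.random(iu[0].size) < noise_edge_prob
        for ui, vi in zip(iu[0][mask], iu[1][mask]):
            graph.add_edge(all_genes[ui], all_genes[vi])

    truth = SyntheticTruth(
        groups={gid: list(m) for gid, m in groups.items()},
        cell_types={},
        terms={},
        shared_partners={gid: list(p) for gid, p in partner_sets.items()},
        coverage=float("nan"),
        seed=seed,
    )
    return ProteinNetwork(graph), truth


def _unique_regulator(lmap: LineageMap, cell_type: str) -> str:
    """A regulator serving only the given cell type (needed to plant a
    lineage-specific group without leaking into other cell types)."""
    owners: dict[str, set[str]] = {}
    for ct, regs in lmap.regulators.items():
        for r in regs:
            owners.setdefault(r, set()).add(ct)
    for r in sorted(lmap.regulators_of(cell_type)):
        if owners[r] == {cell_type}:
            return r
    raise ValidationError(
        f"cell type {cell_type!r} has no uniquely-owned regulator; cannot "
        "plant a lineage-specific group on it"
    )


def generate_separated_similarity(
    rng: np.random.Generator,
    n_range: tuple[int, int] = (4, 8),
    k_max: int = 3,
    within: tuple[float, float] = (0.8, 1.0),
    between: tuple[float, float] = (0.0, 0.1),
) -> tuple[np.ndarray, np.ndarray]:
    """Random well-separated symmetric similarity matrix with planted
    block labels; diagonal left at 0 for a preference to fill.

    "Well-separated" is guaranteed structurally, not just by the value
    bands: at least two blocks, every block of size >= 2 (a singleton's
    preference ties with its cross-similarities), and between-block pairs
    in the majority so the median preference falls inside the ``between``
    band, strictly below the ``within`` band.  Outside these conditions the
    exemplar objective develops near-ties and message passing (any
    implementation) need not reach the exact optimum.  Returns
    (matrix, labels).
    """
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    k = int(rng.integers(2, max(2, min(k_max, n // 2)) + 1))
    while True:
        sizes = np.full(k, 2)
        for _ in range(n - 2 * k):
            sizes[rng.integers(0, k)] += 1
        n_within = int((sizes * (sizes - 1) // 2).sum())
        if n_within < n * (n - 1) // 2 - n_within:
            break
    labels = rng.permutation(np.repeat(np.arange(k), sizes))
    M = rng.uniform(between[0], between[1], (n, n))
    same = labels[:, None] == labels[None, :]
    M[same] = rng.uniform(within[0], within[1], int(same.sum()))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M, labels


def generate_lineage(
    truth: SyntheticTruth,
    lmap: LineageMap,
    specific_cell_types: list[str] | None = None,
    coverage: float = DEFAULTS["coverage"],
    n_decoy_modules: int = DEFAULTS["n_decoy_modules"],
) -> LineageMap:
    """Plant lineage wiring: one module per group, padded to the requested
    interactome coverage, plus zero-interactor decoy modules.

    All groups but the last are planted lineage-specific on
    ``specific_cell_types`` (default: the Table-1 cell types that own a
    unique regulator, in order); the last group is planted common, wired to
    at least one regulator of every cell type.  The returned LineageMap
    shares the regulator table of ``lmap`` and gains module_assignment and
    module_regulation; the truth object is updated in place with the
    planted cell types.
    """
    if not 0 < coverage <= 1:
        raise ValidationError("coverage must lie in (0, 1]")
    group_ids = sorted(truth.groups)
    if specific_cell_types is None:
        candidates = [ct for ct in lmap.cell_types if _safe_unique(lmap, ct)]
        specific_cell_types = candidates[: len(group_ids) - 1]
    if len(specific_cell_types) < len(group_ids) - 1:
        raise ValidationError(
            "not enough cell types with uniquely-owned regulators to plant "
            f"{len(group_ids) - 1} specific groups"
        )

    module_assignment: dict[str, str] = {}
    module_regulation: set[tuple[str, str]] = set()
    for i, gid in enumerate(group_ids):
        module = f"M{i + 1:02d}"
        members = truth.groups[gid]
        n_total = max(len(members), int(round(len(members) / coverage)))
        pads = [f"PAD{i + 1:02d}_{j:03d}" for j in range(n_total - len(members))]
        for g in list(members) + pads:
            module_assignment[g] = module
        if i < len(group_ids) - 1:
            ct = specific_cell_types[i]
            module_regulation.add((_unique_regulator(lmap, ct), module))
            truth.cell_types[gid] = [ct]
        else:
            for ct in lmap.cell_types:
                reg = sorted(lmap.regulators_of(ct))[0]
                module_regulation.add((reg, module))
            truth.cell_types[gid] = list(lmap.cell_types)
    for d in range(n_decoy_modules):
        module = f"DECOY{d + 1:02d}"
        for j in range(10):
            module_assignment[f"DPAD{d + 1:02d}_{j:03d}"] = module
        # decoy modules are wired to an arbitrary regulator but hold no
        # interacting genes, mirroring the zero-interactor modules seen in
        # real module catalogs
        reg = sorted(lmap.regulators_of(lmap.cell_types[d % len(lmap.cell_types)]))[0]
        module_regulation.add((reg, module))
    truth.coverage = coverage
    return LineageMap(
        cell_types=list(lmap.cell_types),
        regulators={ct: set(r) for ct, r in lmap.regulators.items()},
        module_assignment=module_assignment,
        module_regulation=module_regulation,
    )


def _safe_unique(lmap: LineageMap, cell_type: str) -> bool:
    try:
        _unique_regulator(lmap, cell_type)
        return True
    except ValidationError:
        return False


def generate_annotations(
    truth: SyntheticTruth,
    n_decoy_terms: int = DEFAULTS["n_decoy_terms"],
    term_size_range: tuple[int, int] = DEFAULTS["term_size_range"],
    seed: int | None = None,
    planted_fraction: float = 0.9,
) -> tuple[list[AnnotationSet], nx.DiGraph]:
    """One planted term per group (covering >= 80% of its genes by default)
    plus random decoy terms, with a small child→parent DAG rooting every
    term under a branch node and a single root."""
    if not 0.8 <= planted_fraction <= 1.0:
        raise ValidationError("planted_fraction must lie in [0.8, 1.0]")
    rng = np.random.default_rng(seed)
    universe = sorted(g for members in truth.groups.values() for g in members)
    sets: list[AnnotationSet] = []
    dag = nx.DiGraph()
    root, planted_branch, decoy_branch = "T:ROOT", "T:PLANTED", "T:DECOY"
    dag.add_edge(planted_branch, root)
    dag.add_edge(decoy_branch, root)
    for gid in sorted(truth.groups):
        members = truth.groups[gid]
        n_pick = max(1, math.ceil(planted_fraction * len(members)))
        picked = sorted(rng.choice(members, size=n_pick, replace=False))
        term_id = f"T:{gid.upper()}"
        sets.append(AnnotationSet(term_id, f"planted signature of {gid}", set(picked)))
        dag.add_edge(term_id, planted_branch)
        truth.terms[gid] = term_id
    low, high = term_size_range
    if not 1 <= low <= high <= len(universe):
        raise ValidationError("invalid term_size_range for the gene universe")
    for d in range(n_decoy_terms):
        size = int(rng.integers(low, high + 1))
        picked = sorted(rng.choice(universe, size=size, replace=False))
        term_id = f"T:DECOY{d + 1:03d}"
        sets.append(AnnotationSet(term_id, f"decoy term {d + 1}", set(picked)))
        dag.add_edge(term_id, decoy_branch)
    return sets, dag


def write_dataset(
    out_dir: str | Path,
    network: ProteinNetwork,
    truth: SyntheticTruth,
    lmap: LineageMap,
    annotations: list[AnnotationSet],
    dag: nx.DiGraph,
) -> dict[str, Path]:
    """Emit the exact file dialects the pipeline consumes, plus the truth
    sidecar.  Returns the path of every written artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "modules": out / "modules.tsv",
        "regulators": out / "regulators.tsv",
        "regulation": out / "regulation.tsv",
        "annotations": out / "annotations.gmt",
        "dag": out / "dag.tsv",
        "truth": out / "truth.json",
    }
    with paths["interactions"].open("w") as fh:
        fh.write(
            "interactor_a\tinteractor_b\ttaxon_a\ttaxon_b\t"
            "experimental\tphysical_binding\tpubmed_ids\n"
        )
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\t{MOUSE_TAXON}\t{MOUSE_TAXON}\t1\t1\t1\n")
    with paths["modules"].open("w") as fh:
        fh.write("gene\tmodule_id\n")
        for gene, module in sorted(lmap.module_assignment.items()):
            fh.write(f"{gene}\t{module}\n")
    with paths["regulators"].open("w") as fh:
        fh.write("cell_type\tactivators\n")
        for ct in lmap.cell_types:
            fh.write(f"{ct}\t{', '.join(sorted(lmap.regulators[ct]))}\n")
    with paths["regulation"].open("w") as fh:
        fh.write("regulator\tmodule_id\n")
        for reg, module in sorted(lmap.module_regulation):
            fh.write(f"{reg}\t{module}\n")
    write_gmt(annotations, paths["annotations"])
    with paths["dag"].open("w") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")
    truth.to_json(paths["truth"])
    return paths


def generate_dataset(
    out_dir: str | Path | None = None,
    seed: int | None = 7,
    **overrides,
) -> dict:
    """Convenience wrapper: generate interactome, lineage and annotations
    under one seed (the standard dataset uses seed 7) and optionally write
    the files.  Returns a dict with the in-memory objects and, when
    ``out_dir`` is given, the artifact paths."""
    from .datasets import load_regulator_fixture

    params = dict(DEFAULTS)
    params.update(overrides)
    network, truth = generate_interactome(
        n_genes=params["n_genes"],
        n_groups=params["n_groups"],
        group_size=params["group_size"],
        within_shared_partners=params["within_shared_partners"],
        background_attachment=params["background_attachment"],
        noise_edge_prob=params["noise_edge_prob"],
        seed=seed,
    )
    base = load_regulator_fixture()
    lmap = generate_lineage(
        truth,
        base,
        coverage=params["coverage"],
        n_decoy_modules=params["n_decoy_modules"],
    )
    annotations, dag = generate_annotations(
        truth,
        n_decoy_terms=params["n_decoy_terms"],
        term_size_range=params["term_size_range"],
        seed=None if seed is None else seed + 1,
    )
    result = {
        "network": network,
        "truth": truth,
        "lineage_map": lmap,
        "annotations": annotations,
        "dag": dag,
    }
    if out_dir is not None:
        result["paths"] = write_dataset(out_dir, network, truth, lmap, annotations, dag)
    return result
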