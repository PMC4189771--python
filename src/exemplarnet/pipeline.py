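"""End-to-end orchestration: filter → pnsm → cluster → integrate → enrich →
export, with a checksummed run manifest.

Every stage writes its artifacts under the configured output directory; the
manifest records each stage's artifacts with SHA-256 checksums so reruns
with identical inputs and seeds can be verified byte-for-byte (up to the
deterministic stages).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import enrichment as enr
from .affinity import APConfig, run_affinity_propagation
from .errors import ConfigurationError, ValidationError
from .interactome import Dialect, filter_interactions, load_interactions
from .lineage import (
    associate_exemplars,
    build_cell_exemplar_bipartite,
    build_regulator_module_multigraph,
    load_module_table,
    load_regulation_table,
    load_regulator_table,
    module_coverage,
)
from .pnsm import build_pnsm

logger = logging.getLogger(__name__)

STAGES = ("filter", "pnsm", "cluster", "integrate", "enrich", "export")


@dataclass
class RunConfig:
    """Serializable parameters of one pipeline run."""

    interactions: str
    modules: str
    regulators: str
    regulation: str
    output_dir: str
    annotations: str | None = None
    dag: str | None = None
    target_taxon: int = 10090
    index: str = "simpson"
    preference: str | float = "median"
    damping: float = 0.5
    max_iterations: int = 1000
    convergence_iterations: int = 50
    noise_scale: float = 0.0
    min_genes: int = 1
    alpha: float = 0.05
    seed: int | None = None
    log_level: str = "INFO"

    def ap_config(self) -> APConfig:
        return APConfig(
            preference=self.preference,
            damping=self.damping,
            max_iterations=self.max_iterations,
            convergence_iterations=self.convergence_iterations,
            noise_scale=self.noise_scale,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        missing = {"interactions", "modules", "regulators", "regulation", "output_dir"} - set(data)
        if missing:
            raise ConfigurationError(f"missing config keys: {sorted(missing)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def export_network(network: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write a (possibly bipartite, possibly multi-) graph as GraphML or SIF.

    SIF lines read "source relation target"; parallel multigraph edges get
    distinct relation labels from their exemplar key.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "sif":
        with path.open("w") as fh:
            if network.is_multigraph():
                for u, v, key in sorted(network.edges(keys=True), key=str):
                    fh.write(f"{u}\t{key}\t{v}\n")
            else:
                for u, v in sorted(network.edges, key=str):
                    fh.write(f"{u}\tpp\t{v}\n")
    else:
        raise ValidationError(f"unknown export format {fmt!r}; use 'sif' or 'graphml'")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all six stages in order and return the run manifest.

    Pre-flight checks that every declared input exists before the first
    stage runs; any stage failure aborts with the stage named.
    """
    declared = {
        "interactions": config.interactions,
        "modules": config.modules,
        "regulators": config.regulators,
        "regulation": config.regulation,
    }
    if config.annotations:
        declared["annotations"] = config.annotations
    if config.dag:
        declared["dag"] = config.dag
    missing = {k: v for k, v in declared.items() if not Path(v).exists()}
    if missing:
        raise ConfigurationError(
            "pre-flight check failed; missing input file(s): "
            + ", ".join(f"{k}={v}" for k, v in missing.items())
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": dataclasses.asdict(config)}

    def record(stage: str, artifacts: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "artifacts": {
                    name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in artifacts.items()
                },
            }
        )

    stage = "filter"
    try:
        records = load_interactions(config.interactions, Dialect.default())
        network = filter_interactions(records, target_taxon=config.target_taxon)
        edge_path = out / "network_edges.tsv"
        network.write_edge_tsv(edge_path)
        sif_path = out / "network.sif"
        network.write_sif(sif_path)
        record(stage, {"edges": edge_path, "sif": sif_path})

        stage = "pnsm"
        module_assignment = load_module_table(config.modules)
        candidates = sorted(module_assignment)
        pnsm = build_pnsm(network, candidates, index=config.index)
        pnsm_path = out / "pnsm.tsv"
        pnsm.write_tsv(pnsm_path)
        record(stage, {"pnsm": pnsm_path})

        stage = "cluster"
        result = run_affinity_propagation(pnsm, config.ap_config())
        cluster_path = out / "clusters.tsv"
        with cluster_path.open("w") as fh:
            fh.write("gene\texemplar\tis_exemplar\n")
            for gene in sorted(result.assignment):
                ex = result.assignment[gene]
                fh.write(f"{gene}\t{ex}\t{int(gene == ex)}\n")
        meta_path = out / "cluster_meta.json"
        with meta_path.open("w") as fh:
            json.dump(
                {
                    "n_exemplars": len(result.exemplars),
                    "n_iterations": result.n_iterations,
                    "converged": result.converged,
                    "net_similarity": result.net_similarity,
                },
                fh, indent=2,
            )
        record(stage, {"clusters": cluster_path, "meta": meta_path})

        stage = "integrate"
        lmap = load_regulator_table(config.regulators)
        lmap.module_assignment = module_assignment
        lmap.module_regulation = load_regulation_table(config.regulation)
        table = associate_exemplars(result, lmap, min_genes=config.min_genes)
        table_path = out / "exemplar_lineage.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        coverage = module_coverage(module_assignment, network)
        coverage_path = out / "module_coverage.tsv"
        coverage.to_csv(coverage_path, sep="\t", index=False)
        record(stage, {"exemplar_lineage": table_path, "module_coverage": coverage_path})

        stage = "enrich"
        enrich_artifacts: dict[str, Path] = {}
        if config.annotations:
            annotations = enr.read_gmt(config.annotations)
            dag = enr.load_dag(config.dag) if config.dag else None
            if dag is not None:
                annotations = enr.propagate_annotations(dag, annotations)
            universe = pnsm.genes
            all_results = []
            for exemplar, members in sorted(result.clusters().items()):
                all_results.extend(
                    enr.hypergeom_enrich(
                        members, annotations, universe,
                        gene_set_id=exemplar, alpha=config.alpha,
                    )
                )
            enrich_path = out / "enrichment.tsv"
            enr.results_to_frame(all_results).to_csv(enrich_path, sep="\t", index=False)
            enrich_artifacts["enrichment"] = enrich_path
            if dag is not None:
                traj = enr.significance_trajectory(dag, all_results, alpha=config.alpha)
                traj_path = out / "significance_trajectory.graphml"
                export_network(traj, traj_path, "graphml")
                enrich_artifacts["trajectory"] = traj_path
        record(stage, enrich_artifacts)

        stage = "export"
        cell_bipartite = build_cell_exemplar_bipartite(table)
        reg_multi = build_regulator_module_multigraph(result, lmap)
        exports = {
            "cell_exemplar_graphml": export_network(
                cell_bipartite, out / "cell_exemplar.graphml", "graphml"),
            "cell_exemplar_sif": export_network(
                cell_bipartite, out / "cell_exemplar.sif", "sif"),
            "regulator_module_graphml": export_network(
                reg_multi, out / "regulator_module.graphml", "graphml"),
            "regulator_module_sif": export_network(
                reg_multi, out / "regulator_module.sif", "sif"),
        }
        config_path = out / "run_config.yaml"
        config.to_yaml(config_path)
        exports["run_config"] = config_path
        record(stage, exports)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest_path = out / "manifest.json"
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
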