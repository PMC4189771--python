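import numpy as np
import pytest

from exemplarnet.affinity import APConfig, run_affinity_propagation
from exemplarnet.interactome import InteractionRecord, ProteinNetwork
from exemplarnet.pnsm import build_pnsm
from exemplarnet.synthetic import generate_dataset


def network_from_neighborhoods(neighborhoods: dict[str, set[str]]) -> ProteinNetwork:
    """Build a network realizing the given neighborhoods via direct edges.

    Only valid when the neighborhood map is consistent (b in N(a) implies
    a in N(b) once both are listed); partner-only proteins may appear
    solely on the right-hand side.
    """
    edges = [(g, p) for g, parts in neighborhoods.items() for p in parts]
    return ProteinNetwork.from_edges(edges)


@pytest.fixture
def star_network() -> ProteinNetwork:
    return ProteinNetwork.from_edges([("C", leaf) for leaf in "XYZ"])


@pytest.fixture
def toy_records() -> list[InteractionRecord]:
    """Five evidence rows: one cross-taxon, one without publications, the
    remaining three passing all four criteria."""
    ok = dict(taxon_a=10090, taxon_b=10090, experimental=True,
              physical_binding=True, pubmed_ids=("11111",))
    return [
        InteractionRecord("A", "B", **ok),
        InteractionRecord("B", "C", **ok),
        InteractionRecord("C", "D", **ok),
        InteractionRecord("A", "E", 10090, 9606, True, True, ("22222",)),
        InteractionRecord("D", "E", 10090, 10090, True, True, ()),
    ]


@pytest.fixture(scope="session")
def standard_dataset() -> dict:
    """The standard synthetic study conditions: 5 groups x 20 genes,
    8 shared partners per group, noise 0.01, seed 7."""
    return generate_dataset(seed=7)


@pytest.fixture(scope="session")
def standard_pnsm(standard_dataset):
    lmap = standard_dataset["lineage_map"]
    return build_pnsm(standard_dataset["network"], sorted(lmap.module_assignment))


@pytest.fixture(scope="session")
def standard_result(standard_pnsm):
    return run_affinity_propagation(standard_pnsm, APConfig())
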