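"""Binary protein–protein interaction evidence: parsing, filtering, queries.

Interaction evidence rows (one per reported binary interaction) are reduced
to an undirected, deduplicated protein network by four retention criteria:
the interaction must be (a) experimentally verified, (b) intra-species for
the target taxon, (c) supported by at least one publication, and
(d) a physical binding interaction.  Gene symbols are upper-cased so joins
against module and regulator tables are deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

MOUSE_TAXON = 10090

_TRUE_VALUES = {"1", "true", "t", "yes", "y"}
_FALSE_VALUES = {"0", "false", "f", "no", "n", "", "-"}


def _parse_flag(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE_VALUES:
        return True
    if text in _FALSE_VALUES:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


@dataclass(frozen=True)
class InteractionRecord:
    """One row of interaction evidence prior to filtering."""

    interactor_a: str
    interactor_b: str
    taxon_a: int
    taxon_b: int
    experimental: bool
    physical_binding: bool
    pubmed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.interactor_a or not self.interactor_b:
            raise ValidationError("interactor symbols must be non-empty")


@dataclass
class Dialect:
    """Column mapping for tab-delimited interaction files.

    ``columns`` maps each required field to either a header name (str) or a
    0-based column index (int).  The MITAB preset consumes PSI-MITAB 2.6
    exports: interactors from columns 1–2, taxa from 10–11, publications
    from column 9 and the interaction type from column 12 (1-based), with
    ``taxid:``/``pubmed:`` prefixes stripped.
    """

    columns: Mapping[str, str | int]
    has_header: bool = True
    mitab_values: bool = False

    REQUIRED = (
        "interactor_a",
        "interactor_b",
        "taxon_a",
        "taxon_b",
        "experimental",
        "physical_binding",
        "pubmed_ids",
    )

    @classmethod
    def default(cls) -> "Dialect":
        return cls(columns={name: name for name in cls.REQUIRED})

    @classmethod
    def mitab26(cls) -> "Dialect":
        return cls(
            columns={
                "interactor_a": 0,
                "interactor_b": 1,
                "taxon_a": 9,
                "taxon_b": 10,
                "experimental": 6,   # detection method present => experimental
                "physical_binding": 11,
                "pubmed_ids": 8,
            },
            has_header=False,
            mitab_values=True,
        )

    def validate(self) -> None:
        missing = [name for name in self.REQUIRED if name not in self.columns]
        if missing:
            raise ConfigurationError(
                f"dialect is missing required column mapping(s): {', '.join(missing)}"
            )


def _strip_prefix(value: str, prefix: str) -> str:
    value = value.strip()
    if value.lower().startswith(prefix):
        value = value[len(prefix):]
    return value.split("(")[0].strip()


def _mitab_taxon(value: str) -> int:
    return int(_strip_prefix(value, "taxid:"))


def _mitab_pubmed(value: str) -> tuple[str, ...]:
    ids = []
    for part in value.split("|"):
        part = part.strip()
        if part and part != "-":
            ids.append(_strip_prefix(part, "pubmed:"))
    return tuple(ids)


def _mitab_symbol(value: str) -> str:
    # accept bare symbols or db:accession pairs; keep the accession part
    value = value.strip()
    if ":" in value:
        value = value.split(":", 1)[1]
    return value.upper()


def load_interactions(
    path: str | Path, dialect: Dialect | None = None
) -> list[InteractionRecord]:
    """Parse a tab-delimited interaction file into evidence records.

    Malformed rows are reported through the module logger (with their row
    number and the offending value) and skipped; structural problems — a
    missing required column or an unreadable file — raise immediately.
    """
    dialect = dialect or Dialect.default()
    dialect.validate()
    path = Path(path)
    records: list[InteractionRecord] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        rows = list(reader)
    header: dict[str, int] = {}
    if dialect.has_header:
        if not rows:
            return records
        header = {name: i for i, name in enumerate(rows[0])}
        rows = rows[1:]

    def col(row: Sequence[str], fieldname: str) -> str:
        key = dialect.columns[fieldname]
        if isinstance(key, int):
            idx = key
        else:
            if key not in header:
                raise ConfigurationError(f"required column {key!r} not found in header")
            idx = header[key]
        try:
            return row[idx]
        except IndexError:
            raise ValueError(f"row has no column {idx} for field {fieldname!r}")

    for rownum, row in enumerate(rows, start=2 if dialect.has_header else 1):
        if not row or all(not cell.strip() for cell in row):
            continue
        try:
            if dialect.mitab_values:
                rec = InteractionRecord(
                    interactor_a=_mitab_symbol(col(row, "interactor_a")),
                    interactor_b=_mitab_symbol(col(row, "interactor_b")),
                    taxon_a=_mitab_taxon(col(row, "taxon_a")),
                    taxon_b=_mitab_taxon(col(row, "taxon_b")),
                    experimental=col(row, "experimental").strip() not in {"", "-"},
                    physical_binding="physical" in col(row, "physical_binding").lower()
                    or "direct interaction" in col(row, "physical_binding").lower(),
                    pubmed_ids=_mitab_pubmed(col(row, "pubmed_ids")),
                )
            else:
                pubmed_raw = col(row, "pubmed_ids").strip()
                pubmed = tuple(
                    p.strip() for p in pubmed_raw.replace("|", ",").split(",") if p.strip()
                )
                rec = InteractionRecord(
                    interactor_a=col(row, "interactor_a").strip().upper(),
                    interactor_b=col(row, "interactor_b").strip().upper(),
                    taxon_a=int(col(row, "taxon_a")),
                    taxon_b=int(col(row, "taxon_b")),
                    experimental=_parse_flag(col(row, "experimental")),
                    physical_binding=_parse_flag(col(row, "physical_binding")),
                    pubmed_ids=pubmed,
                )
        except ConfigurationError:
            raise
        except (ValueError, ValidationError) as exc:
            logger.warning("skipping malformed row %d of %s: %s", rownum, path, exc)
            continue
        records.append(rec)
    return records


class ProteinNetwork:
    """Undirected, deduplicated binary protein interaction network."""

    def __init__(self, graph: nx.Graph | None = None):
        self._graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "ProteinNetwork":
        g = nx.Graph()
        for a, b in edges:
            g.add_edge(a.upper(), b.upper())
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self._graph.edges}

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def neighborhood(self, gene: str) -> set[str]:
        """Interaction partners N(gene); empty for genes absent from the
        network.  The gene itself is never a member of its own neighborhood."""
        if gene not in self._graph:
            return set()
        return set(self._graph.neighbors(gene)) - {gene}

    def degree(self, gene: str) -> int:
        return len(self.neighborhood(gene))

    def hubs(self, top_fraction: float = 0.1) -> set[str]:
        """Genes in the top ``top_fraction`` of the degree distribution.

        Ties at the cutoff degree are all included, so the returned set may
        be larger than ``ceil(top_fraction * n)``.
        """
        if not 0 < top_fraction <= 1:
            raise ValidationError("top_fraction must be in (0, 1]")
        degrees = {g: self.degree(g) for g in self._graph.nodes}
        if not degrees:
            return set()
        n_top = max(1, int(round(top_fraction * len(degrees))))
        cutoff = sorted(degrees.values(), reverse=True)[n_top - 1]
        return {g for g, d in degrees.items() if d >= cutoff}

    def to_records(self) -> list[InteractionRecord]:
        """Reconstruct minimal passing evidence rows from the network edges
        (used for the filtering-idempotence property)."""
        return [
            InteractionRecord(a, b, MOUSE_TAXON, MOUSE_TAXON, True, True, ("0",))
            for a, b in sorted(tuple(sorted(e)) for e in self._graph.edges)
        ]

    def write_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("interactor_a\tinteractor_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self._graph.edges):
                fh.write(f"{a}\t{b}\n")

    def write_sif(self, path: str | Path, relation: str = "pp") -> None:
        with Path(path).open("w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in self._graph.edges):
                fh.write(f"{a}\t{relation}\t{b}\n")


def filter_interactions(
    records: Iterable[InteractionRecord],
    target_taxon: int = MOUSE_TAXON,
    keep_self_loops: bool = False,
) -> ProteinNetwork:
    """Apply the four retention criteria and build the undirected network.

    A record survives iff it is experimentally verified, both interactors
    belong to ``target_taxon``, it carries at least one publication ID, and
    it is flagged as physical binding.  Mirror rows (A–B and B–A) collapse
    onto a single undirected edge.  Self-interactions are dropped unless
    ``keep_self_loops`` is set, since neighborhood similarity is defined
    over interaction partners.
    """
    g = nx.Graph()
    n_in = n_kept = 0
    for rec in records:
        n_in += 1
        if not rec.experimental:
            continue
        if rec.taxon_a != target_taxon or rec.taxon_b != target_taxon:
            continue
        if not rec.pubmed_ids:
            continue
        if not rec.physical_binding:
            continue
        if rec.interactor_a == rec.interactor_b and not keep_self_loops:
            continue
        n_kept += 1
        g.add_edge(rec.interactor_a, rec.interactor_b)
    logger.info(
        "interaction filter: %d/%d records retained, %d undirected edges",
        n_kept, n_in, g.number_of_edges(),
    )
    if n_kept == 0:
        logger.warning("no interaction records survived filtering; network is empty")
    return ProteinNetwork(g)


def neighborhood(network: ProteinNetwork, gene: str) -> set[str]:
    """Functional wrapper over :meth:`ProteinNetwork.neighborhood`."""
    return network.neighborhood(gene)


def hubs(network: ProteinNetwork, top_fraction: float = 0.1) -> set[str]:
    """Functional wrapper over :meth:`ProteinNetwork.hubs`."""
    return network.hubs(top_fraction)
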