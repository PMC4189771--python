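"""Packaged reference tables.

Three small TSVs ship with the package, transcribed from the published
study of the mouse immune-cell lineage:

* ``table1_regulators.tsv`` — the ten immune cell types with their known
  transcriptional activators (verbatim, including regulators shared across
  cell types such as SFPI1 and GATA3);
* ``table2_lineage_specific.tsv`` — the 19 lineage-specific protein-network
  exemplars with member genes, functional annotation and associated cell
  type, kept verbatim including the original spelling variants
  ("Hematopoetic stem cells", "Granylocytes", "abTcells", ...);
* ``table3_common.tsv`` — the 25 exemplars common to all ten cell types.

`CELL_TYPE_ALIASES` folds the spelling variants onto the canonical ten
cell-type names of the regulator table.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .lineage import LineageMap, load_regulator_table

#: printed spelling variants -> canonical cell-type names (regulator table)
CELL_TYPE_ALIASES = {
    "hematopoetic stem cells": "Hematopoietic stem cells",
    "hematopoietic stem cells": "Hematopoietic stem cells",
    "granylocytes": "Granulocytes",
    "ggranylocyte": "Granulocytes",
    "granulocytes": "Granulocytes",
    "macrophages": "Macrophage",
    "macrophage": "Macrophage",
    "abtcells": "abT cells",
    "abt cells": "abT cells",
    "gdt cells": "gdT Cells",
    "dendritic cells": "Dendritic cells",
    "b cells": "B cells",
    "monocytes": "Monocytes",
    "natural killer cells": "Natural killer cells",
    "natural killer t cells": "Natural killer t cells",
}


def _data_path(name: str) -> Path:
    return Path(resources.files("exemplarnet.data") / name)


def normalize_cell_type(name: str) -> str:
    key = " ".join(str(name).split()).lower()
    return CELL_TYPE_ALIASES.get(key, str(name).strip())


def _parse_gene_field(raw: object) -> list[str]:
    # gene lists are comma-separated but a few printed rows fall back to
    # whitespace separation; split on both
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return []
    return [g for g in re.split(r"[,\s]+", str(raw).strip()) if g]


def load_regulator_fixture() -> LineageMap:
    """The ten immune cell types and their transcriptional activators."""
    return load_regulator_table(_data_path("table1_regulators.tsv"))


def _load_exemplar_table(name: str, with_cell_type: bool) -> pd.DataFrame:
    df = pd.read_csv(_data_path(name), sep="\t", dtype=str)
    df["exemplar_id"] = df["exemplar_id"].astype(int)
    df["gene_list"] = df["genes"].map(_parse_gene_field)
    if with_cell_type:
        df["cell_type_normalized"] = df["cell_type"].map(normalize_cell_type)
    return df


def load_lineage_specific_exemplars() -> pd.DataFrame:
    """The 19 published lineage-specific exemplars, with a
    ``cell_type_normalized`` column mapping the printed spellings onto the
    canonical ten cell types."""
    return _load_exemplar_table("table2_lineage_specific.tsv", with_cell_type=True)


def load_common_exemplars() -> pd.DataFrame:
    """The 25 published exemplars common to all ten immune cell types."""
    return _load_exemplar_table("table3_common.tsv", with_cell_type=False)


def hsc_fraction(table: pd.DataFrame | None = None) -> tuple[float, int]:
    """Fraction (in percent) of lineage-specific exemplars associated with
    hematopoietic stem cells, and the number of table rows it is computed
    over."""
    if table is None:
        table = load_lineage_specific_exemplars()
    n = len(table)
    k = int((table["cell_type_normalized"] == "Hematopoietic stem cells").sum())
    return 100.0 * k / n, n
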