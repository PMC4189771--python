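"""Protein network similarity matrix (PNSM) construction.

Two genes are similar when their interaction partners overlap.  The Simpson
(overlap) coefficient |N(A) ∩ N(B)| / min(|N(A)|, |N(B)|) scores the shared
partners relative to the least-connected gene of the pair, so a low-degree
gene whose few partners are all shared with a hub still scores highly — the
right behavior in scale-free interactomes, where node degrees differ by
orders of magnitude.  The Jaccard index |N(A) ∩ N(B)| / |N(A) ∪ N(B)| is
offered as an alternative; it penalizes degree disparity.

Genes with no interaction partners have undefined similarity and are dropped
(and logged) before the matrix is assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PipelineError, UndefinedSimilarityError, ValidationError
from .interactome import ProteinNetwork

logger = logging.getLogger(__name__)

INDEXES = ("simpson", "jaccard")


def simpson(network: ProteinNetwork, a: str, b: str) -> float:
    """Simpson overlap of the two genes' interaction neighborhoods.

    Raises :class:`UndefinedSimilarityError` if either gene has degree 0.
    """
    na, nb = network.neighborhood(a), network.neighborhood(b)
    if not na or not nb:
        raise UndefinedSimilarityError(
            f"simpson({a!r}, {b!r}) undefined: both genes need degree >= 1"
        )
    shared = (na & nb) - {a, b}
    return len(shared) / min(len(na), len(nb))


def jaccard(network: ProteinNetwork, a: str, b: str) -> float:
    """Jaccard overlap of the two genes' interaction neighborhoods.

    Raises :class:`UndefinedSimilarityError` only when both genes have
    degree 0 (empty union).
    """
    na, nb = network.neighborhood(a), network.neighborhood(b)
    if not na and not nb:
        raise UndefinedSimilarityError(
            f"jaccard({a!r}, {b!r}) undefined: at least one gene needs degree >= 1"
        )
    shared = (na & nb) - {a, b}
    return len(shared) / len(na | nb)


@dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene similarity matrix.

    ``values[i, j]`` holds the similarity between ``genes[i]`` and
    ``genes[j]``; the diagonal is the preference slot s(A, A), left at 0
    until a clustering preference is assigned.
    """

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} genes"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def off_diagonal(self) -> np.ndarray:
        n = len(self.genes)
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]

    def set_preference(self, preference: float | np.ndarray) -> None:
        np.fill_diagonal(self.values, preference)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="gene")

    def write_long_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene_a\tgene_b\tscore\n")
            for i, a in enumerate(self.genes):
                for j in range(i + 1, len(self.genes)):
                    fh.write(f"{a}\t{self.genes[j]}\t{self.values[i, j]:.6g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(genes=list(df.columns), values=df.to_numpy())


def build_pnsm(
    network: ProteinNetwork,
    candidate_genes: Sequence[str],
    index: str = "simpson",
) -> SimilarityMatrix:
    """Assemble the PNSM over the candidate genes that have interactions.

    Candidates absent from the network or with degree 0 are dropped (the
    retained/dropped split is logged); fewer than two retained genes is a
    pipeline error since there is nothing to cluster.  Off-diagonal entries
    hold the chosen index; the diagonal preference slot is initialized to 0.
    """
    if index not in INDEXES:
        raise ValidationError(f"unknown similarity index {index!r}; choose from {INDEXES}")
    if not candidate_genes:
        raise PipelineError("candidate gene list is empty")
    seen: set[str] = set()
    candidates = []
    for g in candidate_genes:
        g = g.upper()
        if g not in seen:
            seen.add(g)
            candidates.append(g)
    retained = [g for g in candidates if network.degree(g) >= 1]
    dropped = len(candidates) - len(retained)
    logger.info(
        "PNSM gene retention: %d/%d candidates with >=1 interaction (%d dropped)",
        len(retained), len(candidates), dropped,
    )
    if len(retained) < 2:
        raise PipelineError(
            f"only {len(retained)} candidate gene(s) have interactions; "
            "need at least 2 to build a similarity matrix"
        )

    # neighborhoods as an incidence matrix over all partner proteins
    partners = sorted({p for g in retained for p in network.neighborhood(g)})
    pindex = {p: i for i, p in enumerate(partners)}
    inc = np.zeros((len(retained), len(partners)), dtype=np.int32)
    for i, g in enumerate(retained):
        for p in network.neighborhood(g):
            inc[i, pindex[p]] = 1
    inter = inc @ inc.T
    deg = inc.sum(axis=1)
    # shared partners exclude the pair itself (relevant only with self-loops,
    # which the filter already removes; inc has no self columns by design)
    if index == "simpson":
        denom = np.minimum.outer(deg, deg)
    else:
        denom = np.add.outer(deg, deg) - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, inter / denom, 0.0)
    np.fill_diagonal(values, 0.0)
    return SimilarityMatrix(genes=retained, values=values)


class NeighborhoodSimilarity:
    """Transformer-style PNSM builder.

    Parameters
    ----------
    metric : {"simpson", "jaccard"}
        Neighborhood-overlap index used for every gene pair.

    After ``fit(network)`` the fitted network is stored as ``network_``;
    ``transform(genes)`` returns the :class:`SimilarityMatrix` over the
    candidates that survive the degree >= 1 retention rule.
    """

    def __init__(self, metric: str = "simpson"):
        self.metric = metric

    def get_params(self, deep: bool = True) -> dict:
        return {"metric": self.metric}

    def set_params(self, **params) -> "NeighborhoodSimilarity":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: ProteinNetwork, y=None) -> "NeighborhoodSimilarity":
        if not isinstance(X, ProteinNetwork):
            raise ValidationError("NeighborhoodSimilarity.fit expects a ProteinNetwork")
        self.network_ = X
        return self

    def transform(self, genes: Sequence[str]) -> SimilarityMatrix:
        if not hasattr(self, "network_"):
            raise ValidationError("NeighborhoodSimilarity is not fitted")
        return build_pnsm(self.network_, genes, index=self.metric)

    def fit_transform(self, X: ProteinNetwork, genes: Sequence[str]) -> SimilarityMatrix:
        return self.fit(X).transform(genes)
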