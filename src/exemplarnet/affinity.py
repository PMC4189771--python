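"""Affinity propagation on the PNSM.

Message-passing clustering of a similarity matrix.  Every gene is
simultaneously a data point and a candidate exemplar; two message matrices
are exchanged until a stable exemplar set emerges:

* responsibility r(A, B) — sent from A to candidate exemplar B; how well
  suited B is to serve as A's exemplar, relative to A's other candidates:
      r(A, B) <- s(A, B) - max_{B' != B} { a(A, B') + s(A, B') }
* availability a(A, B) — sent from candidate B to A; accumulated evidence
  that B should be an exemplar:
      a(A, B) <- min{ 0, r(B, B) + sum_{A' not in {A, B}} max(0, r(A', B)) }
  with the self-availability a(B, B) = sum_{A' != B} max(0, r(A', B)).

The diagonal s(A, A) is the *preference*: how readily A becomes an exemplar.
Following the source method, the default preference is the median of the
off-diagonal similarities, broadcast to every gene.  Messages are damped
(r <- damping * r_old + (1 - damping) * r_new) to prevent oscillation on
symmetric inputs.  Exemplars are the genes with a(B, B) + r(B, B) > 0; every
other gene is assigned to its most similar exemplar.

A brute-force exemplar-set search over all nonempty subsets is provided as
an exact oracle for small matrices (n <= 12), maximizing the same net
similarity objective the message passing optimizes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import NumericalError, ValidationError
from .pnsm import SimilarityMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration / state / result containers

@dataclass
class APConfig:
    """Knobs for one affinity propagation run.

    preference: "median" (scalar median of off-diagonal similarities,
    broadcast), a float, or an explicit per-gene vector.
    noise_scale: magnitude of the optional tie-breaking jitter, as a
    fraction of the similarity range; 0 disables it.
    """

    preference: str | float | Sequence[float] = "median"
    damping: float = 0.5
    max_iterations: int = 1000
    convergence_iterations: int = 50
    noise_scale: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1.0:
            raise ValidationError("damping must lie in [0.5, 1)")
        if self.convergence_iterations >= self.max_iterations:
            raise ValidationError("convergence_iterations must be < max_iterations")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")


@dataclass
class APState:
    """Current message matrices of a run in progress."""

    responsibilities: np.ndarray
    availabilities: np.ndarray
    iteration: int = 0


@dataclass
class APResult:
    """Converged (or truncated) clustering outcome."""

    exemplars: set[str]
    assignment: dict[str, str]
    n_iterations: int
    converged: bool
    net_similarity: float

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {e: set() for e in self.exemplars}
        for gene, ex in self.assignment.items():
            out[ex].add(gene)
        return out


# --------------------------------------------------------------------------
# update rules (exposed for testing against hand-computed values)

def median_preference(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Shared-scalar preference vector: the median of all off-diagonal
    similarities, one entry per gene."""
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValidationError("median preference needs a matrix with >= 2 genes")
    off = values[~np.eye(n, dtype=bool)]
    return np.full(n, float(np.median(off)))


def _check_finite(M: np.ndarray, what: str, iteration: int) -> None:
    if not np.all(np.isfinite(M)):
        raise NumericalError(f"non-finite {what} at iteration {iteration}")


def update_responsibilities(
    S: np.ndarray, state: APState, damping: float
) -> APState:
    """One damped responsibility sweep (in place on a copied state)."""
    A, R = state.availabilities, state.responsibilities
    _check_finite(A, "availabilities", state.iteration)
    AS = A + S
    n = S.shape[0]
    idx = np.arange(n)
    first = AS.argmax(axis=1)
    first_val = AS[idx, first]
    AS_masked = AS.copy()
    AS_masked[idx, first] = -np.inf
    second_val = AS_masked.max(axis=1)
    # for each (A,B): max over B' != B of a(A,B') + s(A,B')
    best_other = np.where(
        np.arange(n)[None, :] == first[:, None], second_val[:, None], first_val[:, None]
    )
    R_new = S - best_other
    R_damped = damping * R + (1.0 - damping) * R_new
    _check_finite(R_damped, "responsibilities", state.iteration)
    return APState(R_damped, A.copy(), state.iteration)


def update_availabilities(state: APState, damping: float) -> APState:
    """One damped availability sweep."""
    R, A = state.responsibilities, state.availabilities
    _check_finite(R, "responsibilities", state.iteration)
    n = R.shape[0]
    Rp = np.maximum(R, 0.0)
    np.fill_diagonal(Rp, R.diagonal())  # self-responsibility enters unclipped
    col_sums = Rp.sum(axis=0)
    # off-diagonal: min(0, r(B,B) + sum_{A' not in {A,B}} max(0, r(A',B)))
    A_new = np.minimum(0.0, col_sums[None, :] - Rp)
    # self-availability: sum of positive responsibilities from all others
    np.fill_diagonal(A_new, col_sums - R.diagonal())
    A_damped = damping * A + (1.0 - damping) * A_new
    _check_finite(A_damped, "availabilities", state.iteration)
    return APState(R.copy(), A_damped, state.iteration + 1)


# --------------------------------------------------------------------------
# estimator

class AffinityPropagation(ClusterMixin, BaseEstimator):
    """Affinity propagation over a precomputed similarity matrix.

    Parameters
    ----------
    preference : "median", float or array-like, default="median"
        Diagonal self-similarity s(A, A).  "median" broadcasts the scalar
        median of the off-diagonal similarities to every gene.
    damping : float, default=0.5
        Message damping factor in [0.5, 1).
    max_iter : int, default=1000
        Hard iteration cap.
    convergence_iter : int, default=50
        Number of consecutive iterations with an unchanged exemplar set
        required to declare convergence.
    noise_scale : float, default=0.0
        Optional additive jitter (fraction of the similarity range) that
        breaks exact ties on degenerate inputs; seeded by ``random_state``.
    random_state : int or None
        Seed for the jitter RNG.

    Attributes
    ----------
    exemplar_indices_ : ndarray of int — indices of the exemplar genes.
    labels_ : ndarray of int — cluster index of each gene.
    converged_ : bool
    n_iter_ : int
    net_similarity_ : float — sum of each point's similarity to its
        exemplar plus the exemplar preferences (the objective).
    result_ : APResult keyed by gene symbol (or stringified indices when a
        bare array is fitted).
    """

    def __init__(
        self,
        *,
        preference: str | float | Sequence[float] = "median",
        damping: float = 0.5,
        max_iter: int = 1000,
        convergence_iter: int = 50,
        noise_scale: float = 0.0,
        random_state: int | None = None,
    ):
        self.preference = preference
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter
        self.noise_scale = noise_scale
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _prepared_matrix(self, X) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Returns (clean preference-filled matrix, message matrix, genes).

        The message matrix differs from the clean one only when jitter is
        enabled: tiny additive noise breaks the exact symmetric ties that
        otherwise stall the message passing (a symmetric PNSM makes every
        within-cluster pair a perfectly matched exemplar competitor).  The
        assignment and the net-similarity objective are always evaluated on
        the clean matrix.
        """
        if isinstance(X, SimilarityMatrix):
            genes = list(X.genes)
            S = X.values.astype(float, copy=True)
        else:
            S = np.asarray(X, dtype=float).copy()
            if S.ndim != 2 or S.shape[0] != S.shape[1]:
                raise ValidationError("similarity matrix must be square")
            genes = [str(i) for i in range(S.shape[0])]
        if not np.all(np.isfinite(S)):
            raise NumericalError("similarity matrix contains non-finite values")
        n = S.shape[0]
        if n >= 2:
            if isinstance(self.preference, str):
                if self.preference != "median":
                    raise ValidationError(
                        f"unknown preference {self.preference!r}; use 'median', "
                        "a scalar, or a vector"
                    )
                pref = median_preference(S)
            else:
                pref = np.broadcast_to(
                    np.asarray(self.preference, dtype=float), (n,)
                ).copy()
            np.fill_diagonal(S, pref)
        S_msg = S
        if self.noise_scale > 0 and n >= 2:
            rng = np.random.default_rng(self.random_state)
            span = float(S.max() - S.min()) or 1.0
            S_msg = S + rng.uniform(-1, 1, size=S.shape) * self.noise_scale * span
        return S, S_msg, genes

    def fit(self, X, y=None) -> "AffinityPropagation":
        """Cluster the similarity matrix ``X`` (SimilarityMatrix or square
        array)."""
        cfg = APConfig(
            preference=self.preference,
            damping=self.damping,
            max_iterations=self.max_iter,
            convergence_iterations=self.convergence_iter,
            noise_scale=self.noise_scale,
            seed=self.random_state,
        )
        S, S_msg, genes = self._prepared_matrix(X)
        n = S.shape[0]
        self.n_features_in_ = n
        if n == 0:
            raise ValidationError("cannot cluster an empty similarity matrix")
        if n == 1:
            self.exemplar_indices_ = np.array([0])
            self.labels_ = np.array([0])
            self.converged_ = True
            self.n_iter_ = 0
            self.net_similarity_ = float(S[0, 0])
            self.result_ = APResult(
                {genes[0]}, {genes[0]: genes[0]}, 0, True, float(S[0, 0])
            )
            return self

        state = APState(np.zeros((n, n)), np.zeros((n, n)))
        stable = 0
        prev_exemplars: tuple[int, ...] | None = None
        converged = False
        for _ in range(cfg.max_iterations):
            state = update_responsibilities(S_msg, state, cfg.damping)
            state = update_availabilities(state, cfg.damping)
            evidence = state.availabilities.diagonal() + state.responsibilities.diagonal()
            exemplars = tuple(np.flatnonzero(evidence > 0))
            if exemplars and exemplars == prev_exemplars:
                stable += 1
                if stable >= cfg.convergence_iterations:
                    converged = True
                    break
            else:
                stable = 0
            prev_exemplars = exemplars
        if not converged:
            warnings.warn(
                "affinity propagation did not converge within "
                f"{cfg.max_iterations} iterations; consider noise_scale > 0 "
                "to break ties",
                stacklevel=2,
            )
        exemplar_idx = list(prev_exemplars or ())
        if not exemplar_idx:
            evidence = state.availabilities.diagonal() + state.responsibilities.diagonal()
            exemplar_idx = [int(np.argmax(evidence))]
            converged = False
        exemplar_idx = self._refine_exemplars(S, exemplar_idx)
        assignment_idx = self._assign(S, exemplar_idx)
        self.exemplar_indices_ = np.asarray(exemplar_idx)
        label_of = {e: k for k, e in enumerate(exemplar_idx)}
        self.labels_ = np.asarray([label_of[assignment_idx[i]] for i in range(n)])
        self.converged_ = converged
        self.n_iter_ = state.iteration
        obj = sum(S[i, assignment_idx[i]] for i in range(n))
        self.net_similarity_ = float(obj)
        self.result_ = APResult(
            exemplars={genes[e] for e in exemplar_idx},
            assignment={genes[i]: genes[assignment_idx[i]] for i in range(n)},
            n_iterations=state.iteration,
            converged=converged,
            net_similarity=float(obj),
        )
        return self

    @staticmethod
    def _refine_exemplars(S: np.ndarray, exemplar_idx: list[int]) -> list[int]:
        """Final within-cluster exemplar refinement (as in the original
        published implementation): given the converged partition, replace
        each exemplar by the member of its cluster that maximizes the summed
        similarity from the cluster — a direct local improvement of the net
        similarity objective that message damping can narrowly miss."""
        ex = np.asarray(exemplar_idx)
        c = np.argmax(S[:, ex], axis=1)
        c[ex] = np.arange(ex.size)
        refined = []
        for k in range(ex.size):
            members = np.flatnonzero(c == k)
            j = members[int(np.argmax(S[np.ix_(members, members)].sum(axis=0)))]
            refined.append(int(j))
        return sorted(refined)

    @staticmethod
    def _assign(S: np.ndarray, exemplar_idx: list[int]) -> dict[int, int]:
        assignment: dict[int, int] = {}
        ex = np.asarray(exemplar_idx)
        for i in range(S.shape[0]):
            if i in exemplar_idx:
                assignment[i] = i
            else:
                assignment[i] = int(ex[np.argmax(S[i, ex])])
        return assignment

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# --------------------------------------------------------------------------
# functional wrappers and oracles

def run_affinity_propagation(
    S: SimilarityMatrix | np.ndarray, config: APConfig | None = None
) -> APResult:
    """Run AP with an :class:`APConfig` and return the gene-keyed result."""
    config = config or APConfig()
    est = AffinityPropagation(
        preference=config.preference,
        damping=config.damping,
        max_iter=config.max_iterations,
        convergence_iter=config.convergence_iterations,
        noise_scale=config.noise_scale,
        random_state=config.seed,
    )
    return est.fit(S).result_


def net_similarity(S: SimilarityMatrix | np.ndarray, result: APResult) -> float:
    """Objective value of an assignment: sum over non-exemplars of
    s(A, exemplar(A)) plus the exemplar preferences s(B, B)."""
    if isinstance(S, SimilarityMatrix):
        genes, values = S.genes, S.values
    else:
        values = np.asarray(S, dtype=float)
        genes = [str(i) for i in range(values.shape[0])]
    index = {g: i for i, g in enumerate(genes)}
    for gene, ex in result.assignment.items():
        if ex not in result.exemplars:
            raise ValidationError(
                f"assignment of {gene!r} references non-exemplar {ex!r}"
            )
    for ex in result.exemplars:
        if result.assignment.get(ex) != ex:
            raise ValidationError(f"exemplar {ex!r} is not assigned to itself")
    return float(
        sum(values[index[g], index[e]] for g, e in result.assignment.items())
    )


def brute_force_exemplars(
    S: SimilarityMatrix | np.ndarray, preference: str | float | Sequence[float] = "median"
) -> APResult:
    """Exhaustive exemplar-set search (exact oracle, n <= 12).

    Scores every nonempty subset of genes as the exemplar set, assigning
    each remaining gene to its most similar exemplar, and returns the
    configuration with maximum net similarity.  Ties break toward the
    lexicographically smallest exemplar index set.
    """
    if isinstance(S, SimilarityMatrix):
        genes = list(S.genes)
        values = S.values.astype(float, copy=True)
    else:
        values = np.asarray(S, dtype=float).copy()
        genes = [str(i) for i in range(values.shape[0])]
    n = values.shape[0]
    if n > 12:
        raise ValidationError(f"brute force oracle limited to 12 genes (got {n})")
    if n == 0:
        raise ValidationError("empty similarity matrix")
    if n >= 2:
        if isinstance(preference, str):
            np.fill_diagonal(values, median_preference(values))
        else:
            np.fill_diagonal(
                values, np.broadcast_to(np.asarray(preference, dtype=float), (n,))
            )
    best: tuple[float, tuple[int, ...]] | None = None
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            ex = np.asarray(subset)
            score = 0.0
            for i in range(n):
                if i in subset:
                    score += values[i, i]
                else:
                    score += values[i, ex].max()
            if best is None or score > best[0] + 1e-12 or (
                abs(score - best[0]) <= 1e-12 and subset < best[1]
            ):
                best = (score, subset)
    assert best is not None
    score, subset = best
    assignment = AffinityPropagation._assign(values, list(subset))
    return APResult(
        exemplars={genes[e] for e in subset},
        assignment={genes[i]: genes[assignment[i]] for i in range(n)},
        n_iterations=0,
        converged=True,
        net_similarity=float(score),
    )
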