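"""KATZ walk-counting scores on the heterogeneous network.

The heterogeneous adjacency joins the lncRNA similarity network LS, the
disease similarity network DS and the known association network A into one
symmetric block matrix

    A* = [[LS, A ],
          [A^T, DS]]

The KATZ measure scores a (lncRNA, disease) pair by the damped weighted walk
count between the two nodes: walks of length ``l`` contribute with weight
``beta^l``, so shorter walks dominate. Truncated at order ``k``,

    S* = sum_{l=1..k} beta^l (A*)^l,

and in closed form (valid when ``beta * rho(A*) < 1``)

    S* = (I - beta A*)^{-1} - I.

The association score matrix S is the lncRNA x disease block of S*: rows
``0..nl-1``, columns ``nl..nl+nd-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import NumericError, StructuralError
from .matrices import ScoreMatrix, SimilarityMatrix
from .network import AssociationNetwork


@dataclass(frozen=True)
class HeterogeneousMatrix:
    """Symmetric (nl+nd) x (nl+nd) block matrix over lncRNA then disease nodes."""

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    @property
    def nl(self) -> int:
        return len(self.lncrna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    def association_block(self, series: np.ndarray) -> np.ndarray:
        """lncRNA x disease block of a matrix in heterogeneous coordinates."""
        return series[: self.nl, self.nl:]


@dataclass(frozen=True)
class KatzParams:
    """Damping factor beta and evaluation order (an integer or "closed_form")."""

    beta: float = 0.01
    order: int | str = "closed_form"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.order != "closed_form" and (not isinstance(self.order, int) or self.order < 1):
            raise ValueError("order must be a positive integer or 'closed_form'")


def build_heterogeneous_matrix(lncrna_sim: SimilarityMatrix,
                               disease_sim: SimilarityMatrix,
                               net: AssociationNetwork) -> HeterogeneousMatrix:
    if tuple(lncrna_sim.ids) != tuple(net.lncrna_ids):
        raise StructuralError("LS id order does not match the network lncRNA order")
    if tuple(disease_sim.ids) != tuple(net.disease_ids):
        raise StructuralError("DS id order does not match the network disease order")
    adjacency = net.adjacency.astype(float)
    values = np.block([[lncrna_sim.values, adjacency],
                       [adjacency.T, disease_sim.values]])
    return HeterogeneousMatrix(net.lncrna_ids, net.disease_ids, values)


def spectral_radius(matrix: np.ndarray) -> float:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        return 0.0
    if np.allclose(matrix, matrix.T, atol=1e-12):
        return float(np.max(np.abs(np.linalg.eigvalsh(matrix))))
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


def katz_scores_truncated(hetero: HeterogeneousMatrix, beta: float,
                          k: int) -> ScoreMatrix:
    """Association block of sum_{l=1..k} beta^l (A*)^l."""
    if beta <= 0 or k < 1:
        raise ValueError("need beta > 0 and k >= 1")
    damped = beta * np.asarray(hetero.values, dtype=float)
    if not np.all(np.isfinite(damped)):
        raise NumericError("heterogeneous matrix has non-finite entries")
    term = damped.copy()
    series = damped.copy()
    for _ in range(k - 1):
        term = term @ damped
        series += term
    return ScoreMatrix(hetero.lncrna_ids, hetero.disease_ids,
                       hetero.association_block(series))


def katz_scores_closed_form(hetero: HeterogeneousMatrix, beta: float) -> ScoreMatrix:
    """Association block of (I - beta A*)^{-1} - I.

    Requires the spectral condition ``beta * rho(A*) < 1``; otherwise the
    walk series diverges and the call refuses with the maximum admissible
    beta in the diagnostic.
    """
    values = np.asarray(hetero.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise NumericError("heterogeneous matrix has non-finite entries")
    rho = spectral_radius(values)
    if beta * rho >= 1.0:
        raise NumericError(
            f"spectral condition violated: beta*rho = {beta * rho:.6g} >= 1 "
            f"(rho(A*) = {rho:.6g}, max admissible beta = {1.0 / rho:.6g})"
        )
    n = values.shape[0]
    resolvent = np.linalg.solve(np.eye(n) - beta * values, np.eye(n))
    return ScoreMatrix(hetero.lncrna_ids, hetero.disease_ids,
                       hetero.association_block(resolvent - np.eye(n)))


def katz_scores(hetero: HeterogeneousMatrix, params: KatzParams, *,
                fallback_order: int = 4) -> ScoreMatrix:
    """Evaluate per ``params``; closed form falls back to truncation at
    ``fallback_order`` when the spectral condition fails."""
    if params.order == "closed_form":
        try:
            return katz_scores_closed_form(hetero, params.beta)
        except NumericError:
            return katz_scores_truncated(hetero, params.beta, fallback_order)
    return katz_scores_truncated(hetero, params.beta, int(params.order))


def rank_candidates(scores: ScoreMatrix, net: AssociationNetwork,
                    disease_id: str) -> list[tuple[str, float, float]]:
    """Candidate lncRNAs of one disease, best score first, midrank ties.

    Candidates are the lncRNAs without a known association with the disease
    (adjacency 0). Returned as (lncrna_id, score, rank) with rank 1 = top;
    tied scores share their average rank.
    """
    if (tuple(scores.lncrna_ids) != tuple(net.lncrna_ids)
            or tuple(scores.disease_ids) != tuple(net.disease_ids)):
        raise StructuralError("score matrix ids do not match the network")
    j = net.disease_index(disease_id)
    candidate_idx = np.nonzero(net.adjacency[:, j] == 0)[0]
    candidate_scores = scores.values[candidate_idx, j]
    ranks = rankdata(-candidate_scores, method="average")
    order = np.argsort(candidate_scores)[::-1]
    return [
        (net.lncrna_ids[candidate_idx[i]], float(candidate_scores[i]), float(ranks[i]))
        for i in order
    ]
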