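"""Expression similarity, functional-similarity ingestion, Gaussian kernels.

Three lncRNA/disease similarity sources besides the ontology:

* expression similarity ES: Spearman rank correlation between lincRNA
  expression profiles across tissues; 0 for any pair in which either lncRNA
  has no profile (only lincRNAs are profiled);
* functional similarity FS: a precomputed labeled square table consumed
  as-is, together with the binary coverage indicator ``wf``;
* Gaussian interaction-profile kernels KD/KL:
  ``K(a, b) = exp(-gamma * ||IP(a) - IP(b)||^2)`` with the bandwidth
  ``gamma = gamma' / mean_k ||IP(k)||^2`` normalized by the average number
  of known associations per entity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import ConstantInputWarning, spearmanr

from .errors import ConfigurationError, InputError
from .matrices import SimilarityMatrix, read_labeled_tsv
from .network import AssociationNetwork

logger = logging.getLogger(__name__)

NegativePolicy = Literal["clamp", "absolute", "keep"]


@dataclass(frozen=True)
class ExpressionProfileSet:
    """lincRNA x tissue expression matrix (arbitrary platform units)."""

    lincrna_ids: tuple[str, ...]
    tissue_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lincrna_ids", tuple(self.lincrna_ids))
        object.__setattr__(self, "tissue_ids", tuple(self.tissue_ids))
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.lincrna_ids), len(self.tissue_ids)):
            raise InputError("expression matrix shape does not match id lists")
        if len(self.tissue_ids) < 2:
            raise InputError("need at least 2 tissues for rank correlation")
        if not np.all(np.isfinite(values)):
            raise InputError("expression matrix has missing/non-finite entries")


def load_expression(path) -> ExpressionProfileSet:
    """Read the lincRNA x tissue TSV; rows with missing values are dropped."""
    frame = read_labeled_tsv(path)
    incomplete = frame.index[frame.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("dropping %d expression rows with missing values: %s",
                       len(incomplete), list(incomplete)[:5])
        frame = frame.drop(index=incomplete)
    if frame.empty:
        raise InputError(f"{path}: no complete expression profiles")
    return ExpressionProfileSet(tuple(frame.index), tuple(frame.columns),
                                frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class KernelBandwidth:
    """Normalized Gaussian bandwidth gamma = gamma' / mean squared profile norm."""

    gamma_prime: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ConfigurationError("gamma_prime must be positive")


def _apply_negative_policy(values: np.ndarray, policy: NegativePolicy) -> np.ndarray:
    if policy == "clamp":
        return np.clip(values, 0.0, None)
    if policy == "absolute":
        return np.abs(values)
    if policy == "keep":
        return values
    raise ConfigurationError(f"unknown negative-value policy {policy!r}")


def expression_similarity(profiles: ExpressionProfileSet, lncrna_ids, *,
                          negative_policy: NegativePolicy = "clamp",
                          ) -> tuple[SimilarityMatrix, np.ndarray]:
    """Spearman correlation matrix ES over the network lncRNA list.

    Returns ``(ES, we)`` where ``we(i, j) = 1`` iff both lncRNAs carry an
    expression profile (i.e. are lincRNAs). Unprofiled pairs score 0;
    constant profiles (undefined rank correlation) also score 0 and are
    logged. Negative correlations are clamped to 0 by default since the
    downstream walk count treats similarities as nonnegative edge weights.
    """
    lncrna_ids = list(lncrna_ids)
    n = len(lncrna_ids)
    profiled = [l for l in lncrna_ids if l in set(profiles.lincrna_ids)]
    we = np.zeros((n, n), dtype=np.int8)
    values = np.zeros((n, n))
    np.fill_diagonal(values, 1.0)
    if profiled:
        row_of = {l: i for i, l in enumerate(profiles.lincrna_ids)}
        block = profiles.values[[row_of[l] for l in profiled]]
        with warnings.catch_warnings():
            # constant profiles yield NaN plus a warning; handled below
            warnings.simplefilter("ignore", ConstantInputWarning)
            if len(profiled) > 2:
                rho = np.asarray(spearmanr(block, axis=1).statistic)
            elif len(profiled) == 2:
                r = float(spearmanr(block[0], block[1]).statistic)
                rho = np.array([[1.0, r], [r, 1.0]])
            else:
                rho = np.ones((1, 1))
        constant = np.ptp(block, axis=1) == 0
        if constant.any():
            logger.warning("constant expression profiles (ES set to 0): %s",
                           [profiled[i] for i in np.nonzero(constant)[0]])
        rho = np.where(np.isnan(rho), 0.0, rho)
        rho = _apply_negative_policy(rho, negative_policy)
        np.fill_diagonal(rho, 1.0)
        idx = [lncrna_ids.index(l) for l in profiled]
        values[np.ix_(idx, idx)] = rho
        we[np.ix_(idx, idx)] = 1
        values[idx, idx] = 1.0
    # diagonal of unprofiled lncRNAs: identity similarity, but we=0 there
    return SimilarityMatrix(tuple(lncrna_ids), values, "ES"), we


def load_functional_similarity(path, lncrna_ids,
                               ) -> tuple[SimilarityMatrix, np.ndarray]:
    """Restrict/expand a precomputed functional-similarity table to the network.

    Returns ``(FS, wf)``: ``wf(i, j) = 1`` iff both lncRNAs appear in the
    file. Asymmetries beyond 1e-8 are symmetrized by averaging, and entries
    outside [0, 1] are clamped (both logged); otherwise values pass through
    untouched — the upstream similarity model is treated as ground input.
    """
    return functional_similarity_from_frame(read_labeled_tsv(path), lncrna_ids,
                                            source=str(path))


def functional_similarity_from_frame(frame: pd.DataFrame, lncrna_ids, *,
                                     source: str = "<memory>",
                                     ) -> tuple[SimilarityMatrix, np.ndarray]:
    if list(frame.index) != list(frame.columns):
        frame = frame.reindex(index=frame.index, columns=frame.index)
    raw = frame.to_numpy(dtype=float)
    if raw.size and np.nanmax(np.abs(raw - raw.T)) > 1e-8:
        logger.warning("%s: asymmetric functional similarity; symmetrizing by averaging",
                       source)
        raw = (raw + raw.T) / 2.0
    if raw.size and (np.nanmin(raw) < 0 or np.nanmax(raw) > 1):
        logger.warning("%s: functional similarity entries outside [0, 1]; clamping",
                       source)
        raw = np.clip(raw, 0.0, 1.0)
    lncrna_ids = list(lncrna_ids)
    n = len(lncrna_ids)
    covered = [l for l in lncrna_ids if l in set(frame.index)]
    values = np.zeros((n, n))
    np.fill_diagonal(values, 1.0)
    wf = np.zeros((n, n), dtype=np.int8)
    if covered:
        pos = {l: i for i, l in enumerate(frame.index)}
        sub = raw[np.ix_([pos[l] for l in covered], [pos[l] for l in covered])]
        idx = [lncrna_ids.index(l) for l in covered]
        values[np.ix_(idx, idx)] = (sub + sub.T) / 2.0
        wf[np.ix_(idx, idx)] = 1
    return SimilarityMatrix(tuple(lncrna_ids), values, "FS"), wf


def kernel_bandwidth(net: AssociationNetwork, side: Literal["disease", "lncrna"],
                     gamma_prime: float = 1.0) -> KernelBandwidth:
    """gamma' divided by the mean squared interaction-profile norm.

    For binary profiles the squared norm of an entity's profile is its number
    of known associations, so the denominator is the average number of
    associations per disease (disease side) or per lncRNA (lncRNA side).
    """
    if gamma_prime <= 0:
        raise ConfigurationError("gamma_prime must be positive")
    profiles = _side_profiles(net, side)
    mean_sq_norm = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ConfigurationError(
            f"{side} kernel bandwidth undefined: the network has no associations"
        )
    return KernelBandwidth(gamma_prime, gamma_prime / mean_sq_norm)


def _side_profiles(net: AssociationNetwork, side: str) -> np.ndarray:
    if side == "disease":
        return net.adjacency.T.astype(float)
    if side == "lncrna":
        return net.adjacency.astype(float)
    raise ValueError(f"side must be 'disease' or 'lncrna', got {side!r}")


def gaussian_kernel_matrix(net: AssociationNetwork, side: Literal["disease", "lncrna"],
                           gamma_prime: float = 1.0, *,
                           isolated: Literal["identity", "kernel"] = "identity",
                           ) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel KD (disease side) or KL (lncRNA side).

    Entities with an all-zero profile (no known associations, e.g. after CV
    masking) carry no topological signal; by default their kernel row/column
    is the identity pattern (diagonal 1, off-diagonal 0) so that integration
    can fall back to the remaining similarity sources. ``isolated="kernel"``
    keeps the raw formula values instead.
    """
    bandwidth = kernel_bandwidth(net, side, gamma_prime)
    profiles = _side_profiles(net, side)
    sq_norms = (profiles ** 2).sum(axis=1)
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    sq_dist = np.clip(sq_dist, 0.0, None)
    values = np.exp(-bandwidth.gamma * sq_dist)
    np.fill_diagonal(values, 1.0)
    if isolated == "identity":
        empty = np.nonzero(sq_norms == 0)[0]
        if empty.size:
            values[empty, :] = 0.0
            values[:, empty] = 0.0
            values[empty, empty] = 1.0
    role = "KD" if side == "disease" else "KL"
    ids = net.disease_ids if side == "disease" else net.lncrna_ids
    return SimilarityMatrix(ids, values, role)
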