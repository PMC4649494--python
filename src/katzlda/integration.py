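"""Indicator-weighted integration of the similarity sources.

Disease side: the semantic similarity SS is only defined on the annotated
subset IS, so the integrated similarity averages SS with the Gaussian kernel
KD where both diseases are annotated and falls back to KD elsewhere.

lncRNA side: expression similarity ES is defined where both lncRNAs are
profiled lincRNAs (indicator ``we``) and functional similarity FS where both
appear in the precomputed table (indicator ``wf``); the kernel KL is always
defined. The integrated similarity is the equal-weight mean over the sources
available for each pair:

    LS(i, j) = (we*ES + wf*FS + KL) / (we + wf + 1)

Equal weights are used throughout; they are exposed for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StructuralError
from .matrices import SimilarityMatrix


@dataclass(frozen=True)
class IntegrationContext:
    """Availability indicators: annotated diseases IS, lincRNA pairs we, FS pairs wf."""

    annotated_diseases: frozenset[str]
    we: np.ndarray
    wf: np.ndarray

    def __post_init__(self) -> None:
        for name, indicator in (("we", self.we), ("wf", self.wf)):
            indicator = np.asarray(indicator)
            if not np.isin(indicator, (0, 1)).all():
                raise StructuralError(f"{name} indicator must be binary")
            if not np.array_equal(indicator, indicator.T):
                raise StructuralError(f"{name} indicator must be symmetric")


def integrate_disease_similarity(semantic: SimilarityMatrix | None,
                                 kernel: SimilarityMatrix,
                                 annotated: frozenset[str] | set[str],
                                 *, semantic_weight: float = 0.5) -> SimilarityMatrix:
    """DS: mean of SS and KD on IS x IS pairs, KD elsewhere."""
    if kernel.role != "KD":
        raise StructuralError(f"expected a KD kernel, got role {kernel.role}")
    n = kernel.n
    values = kernel.values.copy()
    if semantic is not None and annotated:
        missing = set(annotated) - set(semantic.ids)
        if missing:
            raise StructuralError(f"annotated diseases absent from SS: {sorted(missing)}")
        in_is = np.array([d in set(annotated) for d in kernel.ids])
        ss_full = np.zeros((n, n))
        pos = {d: i for i, d in enumerate(semantic.ids)}
        idx = np.nonzero(in_is)[0]
        sem_idx = [pos[kernel.ids[i]] for i in idx]
        ss_full[np.ix_(idx, idx)] = semantic.values[np.ix_(sem_idx, sem_idx)]
        both = np.outer(in_is, in_is)
        values = np.where(
            both,
            semantic_weight * ss_full + (1.0 - semantic_weight) * kernel.values,
            kernel.values,
        )
    return SimilarityMatrix(kernel.ids, values, "DS")


def integrate_lncrna_similarity(expression: SimilarityMatrix | None,
                                functional: SimilarityMatrix | None,
                                kernel: SimilarityMatrix,
                                we: np.ndarray | None, wf: np.ndarray | None,
                                *, weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                                ) -> SimilarityMatrix:
    """LS: per-pair weighted mean of the available sources (ES, FS, KL)."""
    if kernel.role != "KL":
        raise StructuralError(f"expected a KL kernel, got role {kernel.role}")
    n = kernel.n
    for name, ind in (("we", we), ("wf", wf)):
        if ind is not None and np.asarray(ind).shape != (n, n):
            raise StructuralError(
                f"{name} indicator shape {np.asarray(ind).shape} != ({n}, {n})")
    we = np.zeros((n, n), dtype=np.int8) if (we is None or expression is None) else np.asarray(we)
    wf = np.zeros((n, n), dtype=np.int8) if (wf is None or functional is None) else np.asarray(wf)
    for name, src, ind in (("ES", expression, we), ("FS", functional, wf)):
        if ind.shape != (n, n):
            raise StructuralError(f"{name} indicator shape {ind.shape} != ({n}, {n})")
        if src is not None and src.n != n:
            raise StructuralError(f"{name} matrix dimension {src.n} != {n}")
        if src is not None and tuple(src.ids) != tuple(kernel.ids):
            raise StructuralError(f"{name} id order does not match the kernel")
    w_es, w_fs, w_kl = weights
    es = expression.values if expression is not None else np.zeros((n, n))
    fs = functional.values if functional is not None else np.zeros((n, n))
    numerator = w_es * we * es + w_fs * wf * fs + w_kl * kernel.values
    denominator = w_es * we + w_fs * wf + w_kl
    return SimilarityMatrix(kernel.ids, numerator / denominator, "LS")
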