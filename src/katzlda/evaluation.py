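"""Cross-validation protocols and ROC/AUC computation.

Three protocols evaluate how well a scorer recovers held-out associations:

* **global LOOCV** — each known pair is left out in turn; the scorer sees
  only the masked network; the held-out pair is ranked against all pairs
  without known evidence (the candidate pairs, shared by all diseases);
* **local LOOCV** — same masking, but the held-out pair competes only
  against the candidate lncRNAs of its own disease;
* **repeated k-fold** — the known pairs are randomly partitioned into
  ``folds`` parts; each part is masked in turn and its pairs are ranked
  against the candidate pairs; an AUC per repetition, summarized as
  mean +/- sd over repetitions.

A smaller rank is better. Sensitivity at a rank threshold is the fraction
of held-out pairs ranked at or above it, specificity the fraction of
candidates below it; sweeping the threshold yields the ROC curve and its
trapezoidal area the AUC (1 = perfect, 0.5 = random). Ranks use the
midrank convention for ties, which makes a constant scorer come out at
exactly 0.5.

The ``scorer`` argument is any callable mapping a (masked)
:class:`~katzlda.network.AssociationNetwork` to a
:class:`~katzlda.matrices.ScoreMatrix` — normally
:meth:`katzlda.pipeline.KatzldaModel.score`. Since scorers only ever see
the masked network, held-out associations cannot leak into the kernels or
the walk count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, InputError
from .matrices import ScoreMatrix
from .network import AssociationNetwork

logger = logging.getLogger(__name__)

Scorer = Callable[[AssociationNetwork], ScoreMatrix]
Pooling = Literal["score", "rank"]


@dataclass(frozen=True)
class TestRecord:
    """One held-out association and how it ranked among its candidates."""

    lncrna_id: str
    disease_id: str
    score: float
    rank: float
    candidate_count: int


@dataclass
class CvResult:
    protocol: str
    records: list[TestRecord]
    roc_points: list[tuple[float, float]]
    auc: float
    rep_aucs: list[float] = field(default_factory=list)
    auc_mean: float | None = None
    auc_sd: float | None = None

    def summary(self) -> dict:
        out = {"protocol": self.protocol, "auc": self.auc,
               "n_test": len(self.records)}
        if self.rep_aucs:
            out.update(auc_mean=self.auc_mean, auc_sd=self.auc_sd,
                       repetitions=len(self.rep_aucs))
        return out


def _midrank_of_test(test_score: float, candidate_scores: np.ndarray) -> float:
    """Rank of the test score among itself + candidates (1 = best, midrank ties)."""
    pooled = np.concatenate(([test_score], candidate_scores))
    return float(rankdata(-pooled, method="average")[0])


def roc_auc(test_ranks: Sequence[float], candidate_counts: Sequence[int],
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC from per-test ranks.

    Each held-out pair with rank ``r`` among ``m`` candidates (rank in
    ``[1, m+1]``) is placed at normalized candidate fraction
    ``u = (r - 1) / m`` — the fraction of its candidates scoring above it.
    Sweeping the threshold over u gives FPR = u and TPR = fraction of test
    pairs at or above the threshold. The trapezoidal area equals
    ``1 - mean(u)``, the normalized Mann-Whitney statistic.
    """
    ranks = np.asarray(test_ranks, dtype=float)
    counts = np.asarray(candidate_counts, dtype=float)
    if ranks.size == 0:
        raise InputError("ROC undefined for an empty test set")
    if np.any(counts < 1):
        raise InputError("every test pair needs at least one candidate")
    if np.any(ranks < 1) or np.any(ranks > counts + 1):
        raise InputError("rank outside [1, candidate_count + 1]")
    u = (ranks - 1.0) / counts
    n = u.size
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tpr = 0.0
    for threshold in np.unique(u):
        if points[-1][0] != threshold:
            points.append((float(threshold), tpr))
        tpr += float(np.sum(u == threshold)) / n
        points.append((float(threshold), tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = float(1.0 - u.mean())
    return points, auc


def trapezoid_auc(points: Sequence[tuple[float, float]]) -> float:
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def _pooled_score_roc(pos: np.ndarray, neg: np.ndarray,
                      ) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep over pooled positive/negative scores (ties 1/2)."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.nonzero(np.diff(scores))[0]
    cut = np.r_[distinct, scores.size - 1]
    tps = np.cumsum(labels)[cut]
    fps = np.cumsum(1 - labels)[cut]
    tpr = np.r_[0.0, tps / pos.size]
    fpr = np.r_[0.0, fps / neg.size]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _score_lookup(scores: ScoreMatrix, net: AssociationNetwork) -> np.ndarray:
    if (tuple(scores.lncrna_ids) != tuple(net.lncrna_ids)
            or tuple(scores.disease_ids) != tuple(net.disease_ids)):
        raise InputError("scorer returned a matrix not aligned with the network")
    return scores.values


def global_loocv(net: AssociationNetwork, scorer: Scorer, *,
                 pooling: Pooling = "score") -> CvResult:
    """Leave each known pair out; rank it against all unknown pairs."""
    pairs = net.known_pairs()
    if len(pairs) < 2:
        raise ConfigurationError("global LOOCV needs at least 2 known associations")
    zero_mask = net.adjacency == 0
    records: list[TestRecord] = []
    neg_pools: list[np.ndarray] = []
    for lncrna_id, disease_id in pairs:
        masked = net.with_masked([(lncrna_id, disease_id)])
        values = _score_lookup(scorer(masked), net)
        i, j = net.lncrna_index(lncrna_id), net.disease_index(disease_id)
        candidates = values[zero_mask]
        rank = _midrank_of_test(values[i, j], candidates)
        records.append(TestRecord(lncrna_id, disease_id, float(values[i, j]),
                                  rank, candidates.size))
        if pooling == "score":
            neg_pools.append(candidates)
    return _finish("global_loocv", records, pooling, neg_pools)


def local_loocv(net: AssociationNetwork, scorer: Scorer, *,
                pooling: Pooling = "rank") -> CvResult:
    """Leave each known pair out; rank it only among its disease's candidates."""
    pairs = net.known_pairs()
    if len(pairs) < 2:
        raise ConfigurationError("local LOOCV needs at least 2 known associations")
    records: list[TestRecord] = []
    neg_pools: list[np.ndarray] = []
    for lncrna_id, disease_id in pairs:
        masked = net.with_masked([(lncrna_id, disease_id)])
        values = _score_lookup(scorer(masked), net)
        i, j = net.lncrna_index(lncrna_id), net.disease_index(disease_id)
        candidate_rows = np.nonzero(net.adjacency[:, j] == 0)[0]
        candidates = values[candidate_rows, j]
        rank = _midrank_of_test(values[i, j], candidates)
        records.append(TestRecord(lncrna_id, disease_id, float(values[i, j]),
                                  rank, candidates.size))
        if pooling == "score":
            neg_pools.append(candidates)
    return _finish("local_loocv", records, pooling, neg_pools)


def kfold_cv(net: AssociationNetwork, scorer: Scorer, *, folds: int = 5,
             repetitions: int = 100, seed: int | None = None,
             pooling: Pooling = "rank") -> CvResult:
    """Repeated random k-fold CV over the known associations.

    Per repetition, the known pairs are shuffled into ``folds`` parts; each
    part is masked in turn and its pairs ranked against the unknown pairs.
    The per-repetition AUCs are summarized by mean and standard deviation.
    """
    pairs = net.known_pairs()
    if len(pairs) < folds:
        raise ConfigurationError(f"{len(pairs)} associations cannot fill {folds} folds")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))
        logger.warning("kfold_cv called without a seed; using OS-entropy seed %d", seed)
    rng = np.random.default_rng(seed)
    zero_mask = net.adjacency == 0
    rep_aucs: list[float] = []
    all_records: list[TestRecord] = []
    for _ in range(repetitions):
        order = rng.permutation(len(pairs))
        rep_records: list[TestRecord] = []
        neg_pools: list[np.ndarray] = []
        for fold in range(folds):
            held_out = [pairs[idx] for idx in order[fold::folds]]
            masked = net.with_masked(held_out)
            values = _score_lookup(scorer(masked), net)
            candidates = values[zero_mask]
            for lncrna_id, disease_id in held_out:
                i, j = net.lncrna_index(lncrna_id), net.disease_index(disease_id)
                rank = _midrank_of_test(values[i, j], candidates)
                rep_records.append(TestRecord(lncrna_id, disease_id,
                                              float(values[i, j]), rank,
                                              candidates.size))
            if pooling == "score":
                neg_pools.append(candidates)
        rep_result = _finish("kfold", rep_records, pooling, neg_pools)
        rep_aucs.append(rep_result.auc)
        all_records.extend(rep_records)
    roc_points, auc = roc_auc([r.rank for r in all_records],
                              [r.candidate_count for r in all_records])
    result = CvResult("kfold", all_records, roc_points, auc, rep_aucs=rep_aucs)
    result.auc_mean = float(np.mean(rep_aucs))
    result.auc_sd = float(np.std(rep_aucs, ddof=1)) if len(rep_aucs) > 1 else 0.0
    return result


def _finish(protocol: str, records: list[TestRecord], pooling: Pooling,
            neg_pools: list[np.ndarray]) -> CvResult:
    if pooling == "score":
        pos = np.array([r.score for r in records])
        neg = np.concatenate(neg_pools)
        roc_points, auc = _pooled_score_roc(pos, neg)
    else:
        roc_points, auc = roc_auc([r.rank for r in records],
                                  [r.candidate_count for r in records])
    return CvResult(protocol, records, roc_points, auc)


def average_rank(ranks: Sequence[float]) -> float:
    """Arithmetic mean of a nonempty list of ranks."""
    ranks = list(ranks)
    if not ranks:
        raise InputError("average_rank of an empty list is undefined")
    if any(r <= 0 for r in ranks):
        raise InputError("ranks must be positive")
    return float(np.mean(ranks))
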