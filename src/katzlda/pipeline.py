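"""End-to-end model: static similarity inputs + network -> KATZ scores.

A :class:`KatzldaModel` bundles everything that does not depend on the
(possibly cross-validation-masked) association network: the disease
ontology-derived semantic similarity, the lincRNA expression similarity,
the precomputed functional similarity, the kernel bandwidth parameters and
the KATZ parameters. Calling :meth:`KatzldaModel.score` on a network then

1. computes the Gaussian interaction-profile kernels KD/KL from that
   network's adjacency (or reuses frozen kernels, see ``kernel_policy``),
2. integrates them with the static sources into DS and LS,
3. assembles the heterogeneous block matrix and evaluates the KATZ series.

Because the kernels are recomputed from whatever adjacency is passed in,
cross-validation that masks associations before calling ``score`` is free
of information leakage by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError
from .integration import integrate_disease_similarity, integrate_lncrna_similarity
from .katz import KatzParams, build_heterogeneous_matrix, katz_scores
from .matrices import ScoreMatrix, SimilarityMatrix
from .network import AssociationNetwork
from .profiles import gaussian_kernel_matrix


def _identity_kernel(ids: tuple[str, ...], role: str) -> SimilarityMatrix:
    return SimilarityMatrix(ids, np.eye(len(ids)), role)


@dataclass
class KatzldaModel:
    """Static inputs and parameters; score any compatible association network."""

    semantic: SimilarityMatrix | None = None
    annotated_diseases: frozenset[str] = field(default_factory=frozenset)
    expression: SimilarityMatrix | None = None
    we: np.ndarray | None = None
    functional: SimilarityMatrix | None = None
    wf: np.ndarray | None = None
    params: KatzParams = field(default_factory=KatzParams)
    gamma_prime_disease: float = 1.0
    gamma_prime_lncrna: float = 1.0
    kernel_policy: Literal["recompute", "freeze"] = "recompute"
    semantic_weight: float = 0.5
    lncrna_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fallback_order: int = 4
    _frozen: tuple[SimilarityMatrix, SimilarityMatrix] | None = field(
        default=None, repr=False)

    def freeze_kernels(self, net: AssociationNetwork) -> None:
        """Precompute KD/KL from ``net`` for reuse under ``kernel_policy='freeze'``."""
        self._frozen = (self._kernel(net, "disease"), self._kernel(net, "lncrna"))

    def _kernel(self, net: AssociationNetwork, side: str) -> SimilarityMatrix:
        gamma_prime = (self.gamma_prime_disease if side == "disease"
                       else self.gamma_prime_lncrna)
        try:
            return gaussian_kernel_matrix(net, side, gamma_prime)  # type: ignore[arg-type]
        except ConfigurationError:
            # adjacency entirely empty: no topological signal at all
            ids = net.disease_ids if side == "disease" else net.lncrna_ids
            return _identity_kernel(ids, "KD" if side == "disease" else "KL")

    def kernels(self, net: AssociationNetwork) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        if self.kernel_policy == "freeze":
            if self._frozen is None:
                self.freeze_kernels(net)
            return self._frozen  # type: ignore[return-value]
        return self._kernel(net, "disease"), self._kernel(net, "lncrna")

    def similarities(self, net: AssociationNetwork
                     ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """Integrated (LS, DS) for the given network."""
        kd, kl = self.kernels(net)
        ds = integrate_disease_similarity(self.semantic, kd, self.annotated_diseases,
                                          semantic_weight=self.semantic_weight)
        ls = integrate_lncrna_similarity(self.expression, self.functional, kl,
                                         self.we, self.wf, weights=self.lncrna_weights)
        return ls, ds

    def score(self, net: AssociationNetwork) -> ScoreMatrix:
        ls, ds = self.similarities(net)
        hetero = build_heterogeneous_matrix(ls, ds, net)
        return katz_scores(hetero, self.params, fallback_order=self.fallback_order)


def make_model(net: AssociationNetwork, *,
               ontology: tuple[list[tuple[str, str]], dict[str, str]] | None = None,
               expression_profiles=None,
               functional_frame=None,
               params: KatzParams | None = None,
               negative_policy: str = "clamp",
               **model_kwargs) -> KatzldaModel:
    """Assemble a model from in-memory inputs aligned to ``net``.

    ``ontology`` is an (edge list, disease->term mapping) pair;
    ``expression_profiles`` an :class:`~katzlda.profiles.ExpressionProfileSet`;
    ``functional_frame`` a labeled square DataFrame. Any of the three may be
    omitted, in which case the integrated similarities fall back to the
    Gaussian kernels alone.
    """
    from .profiles import expression_similarity, functional_similarity_from_frame
    from .semantic import corpus_from_ontology, semantic_similarity_matrix

    semantic = None
    annotated: frozenset[str] = frozenset()
    if ontology is not None:
        edges, mapping = ontology
        corpus, annotated_list = corpus_from_ontology(edges, mapping,
                                                      list(net.disease_ids))
        if annotated_list:
            semantic = semantic_similarity_matrix(corpus, annotated_list)
            annotated = frozenset(annotated_list)
    expression = we = None
    if expression_profiles is not None:
        expression, we = expression_similarity(expression_profiles, net.lncrna_ids,
                                               negative_policy=negative_policy)
    functional = wf = None
    if functional_frame is not None:
        functional, wf = functional_similarity_from_frame(functional_frame,
                                                          net.lncrna_ids)
    return KatzldaModel(semantic=semantic, annotated_diseases=annotated,
                        expression=expression, we=we,
                        functional=functional, wf=wf,
                        params=params or KatzParams(), **model_kwargs)
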