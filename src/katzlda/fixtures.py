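"""Deterministic synthetic generators for every pipeline input.

The generators emulate the four data sources the predictor consumes — the
binary association network, a layered disease ontology, block-structured
lincRNA expression profiles, and a noisy precomputed functional-similarity
matrix — plus a planted-signal variant of the network in which true
associations follow a shared module structure, so that similarity-aware
ranking has a recoverable signal.

Determinism: every generator draws from ``numpy.random.default_rng([seed,
STREAM])`` where ``STREAM`` is a fixed per-generator constant, so adding a
new generator never perturbs the output of an existing one and a fixed
``FixtureSpec.seed`` is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import write_labeled_tsv
from .network import AssociationNetwork, save_associations
from .profiles import ExpressionProfileSet

# per-generator sub-seed stream constants (never reuse or renumber)
_STREAM_NETWORK = 1
_STREAM_DAG = 2
_STREAM_EXPRESSION = 3
_STREAM_FUNCTIONAL = 4
_STREAM_PLANTED = 5


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and noise parameters of one synthetic study condition."""

    nl: int = 60
    nd: int = 40
    density: float = 0.05
    dag_depth: int = 4
    dag_branching: int = 2
    n_tissues: int = 22
    n_blocks: int = 4
    signal_strength: float = 0.9
    annotated_fraction: float = 0.8
    profiled_fraction: float = 0.8
    functional_fraction: float = 0.7
    expression_noise: float = 0.5
    functional_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.density < 1.0):
            raise ValueError("density must lie in (0, 1)")
        if not (0.5 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0.5, 1]")
        for name in ("nl", "nd", "dag_depth", "dag_branching", "n_tissues", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def lncrna_ids(self) -> tuple[str, ...]:
        return tuple(f"L{i:04d}" for i in range(1, self.nl + 1))

    def disease_ids(self) -> tuple[str, ...]:
        return tuple(f"D{j:04d}" for j in range(1, self.nd + 1))


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _block_labels(count: int, n_blocks: int) -> np.ndarray:
    """Deterministic round-robin module assignment 0..n_blocks-1."""
    return np.arange(count) % n_blocks


def random_network(spec: FixtureSpec) -> AssociationNetwork:
    """Erdos-Renyi-style bipartite network: iid Bernoulli(density) entries.

    Resamples (same stream) until at least one association exists.
    """
    rng = _rng(spec, _STREAM_NETWORK)
    while True:
        adjacency = (rng.random((spec.nl, spec.nd)) < spec.density).astype(np.int8)
        if adjacency.any():
            return AssociationNetwork(spec.lncrna_ids(), spec.disease_ids(), adjacency)


def planted_signal_network(spec: FixtureSpec,
                           ) -> tuple[AssociationNetwork, np.ndarray, np.ndarray]:
    """Association network whose edges respect paired lncRNA/disease modules.

    lncRNAs and diseases are split round-robin into ``n_blocks`` paired
    modules. With ``s = signal_strength``, within-pair cells are
    associations with probability proportional to ``s`` and cross-pair
    cells with probability proportional to ``1 - s``, normalized so the
    expected overall density equals ``spec.density`` at every ``s``. Thus
    ``s = 0.5`` degenerates to the uniform Bernoulli(density) network (no
    structure) and ``s = 1`` to a block-diagonal one. Each module pair is
    guaranteed at least one association. Returns (network, lncRNA block
    labels, disease block labels) with labels aligned to the id order.
    """
    rng = _rng(spec, _STREAM_PLANTED)
    lnc_blocks = _block_labels(spec.nl, spec.n_blocks)
    dis_blocks = _block_labels(spec.nd, spec.n_blocks)
    same = lnc_blocks[:, None] == dis_blocks[None, :]
    s = spec.signal_strength
    within_fraction = float(same.mean())
    norm = within_fraction * s + (1.0 - within_fraction) * (1.0 - s)
    p_in = min(1.0, s * spec.density / norm)
    p_out = min(1.0, (1.0 - s) * spec.density / norm)
    probs = np.where(same, p_in, p_out)
    adjacency = (rng.random((spec.nl, spec.nd)) < probs).astype(np.int8)
    for block in range(spec.n_blocks):
        rows = np.nonzero(lnc_blocks == block)[0]
        cols = np.nonzero(dis_blocks == block)[0]
        if rows.size and cols.size and not adjacency[np.ix_(rows, cols)].any():
            adjacency[rng.choice(rows), rng.choice(cols)] = 1
    net = AssociationNetwork(spec.lncrna_ids(), spec.disease_ids(), adjacency)
    return net, lnc_blocks, dis_blocks


def synthetic_dag_corpus(spec: FixtureSpec, disease_blocks: np.ndarray | None = None,
                         ) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Layered random ontology plus a disease-name -> term-id mapping.

    One shared root; below it, each module owns a subtree rooted at a
    module term (a child of the global root), with ``dag_branching`` terms
    per subsequent layer, every term drawing one parent from the previous
    layer (edges only cross layers downward, so the graph is acyclic by
    construction). All diseases of a module therefore share at least the
    module-root term, which occurs in only that module's DAGs and so
    carries positive information content. A random ``annotated_fraction``
    of diseases is mapped to a leaf-layer term of its module's subtree —
    emulating the subset of diseases that carry ontology annotations.
    """
    rng = _rng(spec, _STREAM_DAG)
    if disease_blocks is None:
        disease_blocks = _block_labels(spec.nd, spec.n_blocks)
    edges: list[tuple[str, str]] = []
    leaves: dict[int, list[str]] = {}
    root = "T0000"
    for block in range(spec.n_blocks):
        module_root = f"T{block + 1:02d}0000"
        edges.append((root, module_root))
        previous = [module_root]
        for depth in range(1, spec.dag_depth + 1):
            layer = [f"T{block + 1:02d}{depth:02d}{k:02d}"
                     for k in range(spec.dag_branching)]
            for term in layer:
                edges.append((str(rng.choice(previous)), term))
            previous = layer
        leaves[block] = previous
    disease_ids = spec.disease_ids()
    n_annotated = int(round(spec.annotated_fraction * spec.nd))
    annotated = rng.choice(spec.nd, size=n_annotated, replace=False)
    mapping = {
        disease_ids[j]: str(rng.choice(leaves[int(disease_blocks[j])]))
        for j in sorted(annotated)
    }
    return edges, mapping


def synthetic_expression(spec: FixtureSpec, lncrna_blocks: np.ndarray | None = None,
                         ) -> ExpressionProfileSet:
    """Block-correlated lincRNA expression profiles across tissues.

    Each module has a latent tissue pattern; a profiled lincRNA's profile is
    its module pattern plus iid Gaussian noise of sd ``expression_noise``,
    so within-module Spearman correlation exceeds between-module correlation
    in expectation. Only ``profiled_fraction`` of lncRNAs are lincRNAs with
    profiles.
    """
    rng = _rng(spec, _STREAM_EXPRESSION)
    if lncrna_blocks is None:
        lncrna_blocks = _block_labels(spec.nl, spec.n_blocks)
    latent = rng.normal(size=(spec.n_blocks, spec.n_tissues))
    lncrna_ids = spec.lncrna_ids()
    n_profiled = max(2, int(round(spec.profiled_fraction * spec.nl)))
    profiled = np.sort(rng.choice(spec.nl, size=min(n_profiled, spec.nl), replace=False))
    values = (latent[lncrna_blocks[profiled]]
              + spec.expression_noise * rng.normal(size=(profiled.size, spec.n_tissues)))
    return ExpressionProfileSet(tuple(lncrna_ids[i] for i in profiled),
                                tuple(f"tissue{t:02d}" for t in range(spec.n_tissues)),
                                values)


def synthetic_functional_similarity(spec: FixtureSpec,
                                    lncrna_blocks: np.ndarray | None = None,
                                    ) -> pd.DataFrame:
    """Noisy precomputed functional-similarity table over a lncRNA subset.

    Within-module pairs center on 0.75, cross-module pairs on 0.25, with
    truncated Gaussian noise; symmetric with unit diagonal; only
    ``functional_fraction`` of lncRNAs appear in the table (the coverage
    indicator ``wf`` is derived from membership at load time).
    """
    rng = _rng(spec, _STREAM_FUNCTIONAL)
    if lncrna_blocks is None:
        lncrna_blocks = _block_labels(spec.nl, spec.n_blocks)
    lncrna_ids = spec.lncrna_ids()
    n_covered = max(2, int(round(spec.functional_fraction * spec.nl)))
    covered = np.sort(rng.choice(spec.nl, size=min(n_covered, spec.nl), replace=False))
    blocks = lncrna_blocks[covered]
    base = np.where(blocks[:, None] == blocks[None, :], 0.75, 0.25)
    noise = spec.functional_noise * rng.normal(size=base.shape)
    values = np.clip(base + (noise + noise.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    ids = [lncrna_ids[i] for i in covered]
    return pd.DataFrame(values, index=ids, columns=ids)


@dataclass(frozen=True)
class FixtureBundle:
    """All generated inputs of one study condition, plus the planted labels."""

    spec: FixtureSpec
    network: AssociationNetwork
    lncrna_blocks: np.ndarray
    disease_blocks: np.ndarray
    ontology_edges: list[tuple[str, str]] = field(repr=False)
    disease_mapping: dict[str, str] = field(repr=False)
    expression: ExpressionProfileSet = field(repr=False)
    functional: pd.DataFrame = field(repr=False)


def generate_inputs(spec: FixtureSpec, *, planted: bool = True) -> FixtureBundle:
    """Generate the full input set; ``planted=False`` uses the uniform network."""
    if planted:
        net, lnc_blocks, dis_blocks = planted_signal_network(spec)
    else:
        net = random_network(spec)
        lnc_blocks = _block_labels(spec.nl, spec.n_blocks)
        dis_blocks = _block_labels(spec.nd, spec.n_blocks)
    edges, mapping = synthetic_dag_corpus(spec, dis_blocks)
    expression = synthetic_expression(spec, lnc_blocks)
    functional = synthetic_functional_similarity(spec, lnc_blocks)
    return FixtureBundle(spec, net, lnc_blocks, dis_blocks, edges, mapping,
                         expression, functional)


def write_fixture_files(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write all inputs in the exact formats the loaders consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "ontology_edges": outdir / "ontology_edges.tsv",
        "disease_terms": outdir / "disease_terms.tsv",
        "expression": outdir / "expression.tsv",
        "functional": outdir / "functional_similarity.tsv",
    }
    save_associations(bundle.network, paths["associations"])
    with open(paths["ontology_edges"], "w", encoding="utf-8") as handle:
        handle.write("parent_id\tchild_id\n")
        for parent, child in bundle.ontology_edges:
            handle.write(f"{parent}\t{child}\n")
    with open(paths["disease_terms"], "w", encoding="utf-8") as handle:
        handle.write("disease_id\tterm_id\n")
        for disease, term in bundle.disease_mapping.items():
            handle.write(f"{disease}\t{term}\n")
    write_labeled_tsv(bundle.expression.values, bundle.expression.lincrna_ids,
                      bundle.expression.tissue_ids, paths["expression"])
    bundle.functional.to_csv(paths["functional"], sep="\t")
    return paths
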