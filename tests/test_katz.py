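"""Heterogeneous matrix assembly and KATZ walk-counting scores."""

import numpy as np
import pytest

from katzlda.errors import NumericError, StructuralError
from katzlda.katz import (KatzParams, build_heterogeneous_matrix, katz_scores,
                          katz_scores_closed_form, katz_scores_truncated,
                          rank_candidates, spectral_radius)
from katzlda.matrices import ScoreMatrix, SimilarityMatrix
from katzlda.network import AssociationNetwork

from conftest import random_bipartite


def hetero_from(ls_values, ds_values, adjacency):
    adjacency = np.asarray(adjacency)
    nl, nd = adjacency.shape
    ids_l = tuple(f"L{i}" for i in range(nl))
    ids_d = tuple(f"D{j}" for j in range(nd))
    net = AssociationNetwork(ids_l, ids_d, adjacency)
    ls = SimilarityMatrix(ids_l, np.asarray(ls_values, dtype=float), "LS")
    ds = SimilarityMatrix(ids_d, np.asarray(ds_values, dtype=float), "DS")
    return net, build_heterogeneous_matrix(ls, ds, net)


def walk_count_oracle(matrix, beta, k):
    """Independent oracle: enumerate node sequences and sum edge products."""
    n = matrix.shape[0]
    total = np.zeros((n, n))
    paths = [[(i,), 1.0] for i in range(n)]  # walks as explicit sequences
    for length in range(1, k + 1):
        extended = []
        for nodes, weight in paths:
            for nxt in range(n):
                w = weight * matrix[nodes[-1], nxt]
                if w != 0.0:
                    extended.append([nodes + (nxt,), w])
        for nodes, weight in extended:
            total[nodes[0], nodes[-1]] += beta ** length * weight
        paths = extended
    return total


class TestHeterogeneousMatrix:
    def test_minimal_block_layout(self):
        _, hetero = hetero_from([[1.0]], [[1.0]], [[1]])
        assert np.array_equal(hetero.values, np.ones((2, 2)))

    def test_empty_adjacency_gives_block_diagonal(self):
        _, hetero = hetero_from(np.eye(2), np.eye(2), np.zeros((2, 2), dtype=int))
        assert np.array_equal(hetero.values, np.eye(4))

    def test_matrix_is_symmetric_by_construction(self):
        rng = np.random.default_rng(0)
        net = random_bipartite(rng, 4, 3)
        ls = rng.uniform(size=(4, 4)); ls = (ls + ls.T) / 2; np.fill_diagonal(ls, 1)
        ds = rng.uniform(size=(3, 3)); ds = (ds + ds.T) / 2; np.fill_diagonal(ds, 1)
        hetero = build_heterogeneous_matrix(
            SimilarityMatrix(net.lncrna_ids, ls, "LS"),
            SimilarityMatrix(net.disease_ids, ds, "DS"), net)
        assert np.array_equal(hetero.values, hetero.values.T)

    def test_id_order_mismatch_is_structural_error(self):
        net = AssociationNetwork(("L0", "L1"), ("D0",), np.array([[1], [0]]))
        ls = SimilarityMatrix(("L1", "L0"), np.eye(2), "LS")
        ds = SimilarityMatrix(("D0",), np.eye(1), "DS")
        with pytest.raises(StructuralError):
            build_heterogeneous_matrix(ls, ds, net)


class TestTruncatedScores:
    def test_k1_is_beta_times_adjacency(self):
        adjacency = np.array([[1, 0, 1], [0, 1, 0]])
        net, hetero = hetero_from(np.eye(2), np.eye(3), adjacency)
        scores = katz_scores_truncated(hetero, beta=0.3, k=1)
        assert np.allclose(scores.values, 0.3 * adjacency, atol=1e-15)

    def test_hand_enumerated_single_edge_example(self):
        # single association L0-D0, identity similarities (unit self-loops).
        # Walks L0 -> D0 by length: 1 of length 1; 2 of length 2 (loop at
        # either end); 4 of length 3 (two loop placements on each end plus
        # the backtracking walk L0-D0-L0-D0), so S = b + 2b^2 + 4b^3.
        _, hetero = hetero_from(np.eye(2), np.eye(2),
                                np.array([[1, 0], [0, 0]]))
        scores = katz_scores_truncated(hetero, beta=0.1, k=3)
        beta = 0.1
        oracle = walk_count_oracle(hetero.values, beta, 3)[0, 2]
        assert scores.values[0, 0] == pytest.approx(oracle, abs=1e-15)
        assert scores.values[0, 0] == pytest.approx(
            beta + 2 * beta ** 2 + 4 * beta ** 3, abs=1e-15)
        assert np.all(scores.values[1:] == 0) and np.all(scores.values[0, 1:] == 0)

    def test_matches_walk_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            nl, nd = rng.integers(2, 6, size=2)
            net = random_bipartite(rng, nl, nd, density=0.5)
            ls = rng.uniform(0, 1, (nl, nl)); ls = (ls + ls.T) / 2
            ds = rng.uniform(0, 1, (nd, nd)); ds = (ds + ds.T) / 2
            np.fill_diagonal(ls, 1); np.fill_diagonal(ds, 1)
            hetero = build_heterogeneous_matrix(
                SimilarityMatrix(net.lncrna_ids, ls, "LS"),
                SimilarityMatrix(net.disease_ids, ds, "DS"), net)
            k = int(rng.integers(1, 5))
            scores = katz_scores_truncated(hetero, beta=0.2, k=k)
            oracle = walk_count_oracle(hetero.values, 0.2, k)[:nl, nl:]
            assert np.allclose(scores.values, oracle, atol=1e-10)

    def test_scores_nondecreasing_in_k(self):
        rng = np.random.default_rng(7)
        net = random_bipartite(rng, 4, 3, density=0.5)
        hetero = build_heterogeneous_matrix(
            SimilarityMatrix(net.lncrna_ids, np.eye(4), "LS"),
            SimilarityMatrix(net.disease_ids, np.eye(3), "DS"), net)
        previous = katz_scores_truncated(hetero, 0.1, 1).values
        for k in range(2, 6):
            current = katz_scores_truncated(hetero, 0.1, k).values
            assert np.all(current >= previous - 1e-15)
            previous = current

    def test_beta_monotonicity(self):
        rng = np.random.default_rng(19)
        net = random_bipartite(rng, 5, 4, density=0.4)
        hetero = build_heterogeneous_matrix(
            SimilarityMatrix(net.lncrna_ids, np.eye(5), "LS"),
            SimilarityMatrix(net.disease_ids, np.eye(4), "DS"), net)
        lo = katz_scores_truncated(hetero, 0.05, 4).values
        hi = katz_scores_truncated(hetero, 0.10, 4).values
        assert np.all(hi >= lo - 1e-15)

    def test_edge_addition_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = random_bipartite(rng, 4, 4, density=0.4)
            zeros = np.argwhere(net.adjacency == 0)
            if zeros.size == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            denser = net.adjacency.copy()
            denser[i, j] = 1
            net2 = AssociationNetwork(net.lncrna_ids, net.disease_ids, denser)
            ls = SimilarityMatrix(net.lncrna_ids, np.eye(4), "LS")
            ds = SimilarityMatrix(net.disease_ids, np.eye(4), "DS")
            before = katz_scores_truncated(
                build_heterogeneous_matrix(ls, ds, net), 0.1, 4).values
            after = katz_scores_truncated(
                build_heterogeneous_matrix(ls, ds, net2), 0.1, 4).values
            assert np.all(after >= before - 1e-15)


class TestClosedForm:
    def test_zero_matrix_scores_zero(self):
        _, hetero = hetero_from(np.zeros((2, 2)), np.zeros((2, 2)),
                                np.zeros((2, 2), dtype=int))
        scores = katz_scores_closed_form(hetero, beta=0.5)
        assert np.all(scores.values == 0)

    def test_agrees_with_converged_series(self):
        _, hetero = hetero_from(np.eye(2), np.eye(2),
                                np.array([[1, 0], [0, 0]]))
        closed = katz_scores_closed_form(hetero, beta=0.1)
        truncated = katz_scores_truncated(hetero, beta=0.1, k=50)
        assert np.allclose(closed.values, truncated.values, atol=1e-10)

    def test_agreement_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            nl, nd = rng.integers(2, 6, size=2)
            net = random_bipartite(rng, nl, nd, density=0.5)
            hetero = build_heterogeneous_matrix(
                SimilarityMatrix(net.lncrna_ids, np.eye(nl), "LS"),
                SimilarityMatrix(net.disease_ids, np.eye(nd), "DS"), net)
            rho = spectral_radius(hetero.values)
            beta = 0.5 / rho
            k = int(np.ceil(np.log(1e-10) / np.log(beta * rho)))
            closed = katz_scores_closed_form(hetero, beta)
            truncated = katz_scores_truncated(hetero, beta, k)
            assert np.allclose(closed.values, truncated.values, atol=1e-8)

    def test_leading_order_linear_in_beta(self):
        _, hetero = hetero_from(np.eye(2), np.eye(2),
                                np.array([[1, 1], [0, 1]]))
        s1 = katz_scores_closed_form(hetero, 1e-6).values
        s2 = katz_scores_closed_form(hetero, 2e-6).values
        direct = np.array([[1, 1], [0, 1]], dtype=bool)  # leading order is beta*A
        assert np.allclose(s2[direct] / s1[direct], 2.0, atol=1e-4)

    def test_spectral_violation_refuses_with_diagnostic(self):
        _, hetero = hetero_from(np.eye(2), np.eye(2), np.ones((2, 2), dtype=int))
        rho = spectral_radius(hetero.values)
        with pytest.raises(NumericError, match="max admissible beta"):
            katz_scores_closed_form(hetero, 1.01 / rho)

    def test_dispatch_falls_back_to_truncation(self):
        _, hetero = hetero_from(np.eye(2), np.eye(2), np.ones((2, 2), dtype=int))
        rho = spectral_radius(hetero.values)
        params = KatzParams(beta=2.0 / rho, order="closed_form")
        fallback = katz_scores(hetero, params, fallback_order=4)
        explicit = katz_scores_truncated(hetero, 2.0 / rho, 4)
        assert np.array_equal(fallback.values, explicit.values)


class TestRankCandidates:
    def net_with_scores(self, adjacency, score_values):
        adjacency = np.asarray(adjacency)
        nl, nd = adjacency.shape
        net = AssociationNetwork(tuple(f"L{i}" for i in range(nl)),
                                 tuple(f"D{j}" for j in range(nd)), adjacency)
        scores = ScoreMatrix(net.lncrna_ids, net.disease_ids,
                             np.asarray(score_values, dtype=float))
        return net, scores

    def test_known_pairs_excluded_and_best_first(self):
        net, scores = self.net_with_scores(
            [[1, 0], [0, 0], [0, 0]],
            [[9.0, 0.1], [0.5, 0.2], [0.7, 0.3]])
        ranked = rank_candidates(scores, net, "D0")
        assert [r[0] for r in ranked] == ["L2", "L1"]
        assert [r[2] for r in ranked] == [1.0, 2.0]

    def test_full_tie_gives_average_rank(self):
        net, scores = self.net_with_scores(
            [[0], [0], [0]], [[0.5], [0.5], [0.5]])
        ranked = rank_candidates(scores, net, "D0")
        assert all(rank == 2.0 for _, _, rank in ranked)

    def test_matches_naive_sort_oracle_with_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            nl = int(rng.integers(3, 10))
            values = rng.choice([0.1, 0.2, 0.3, 0.4], size=(nl, 1))
            net, scores = self.net_with_scores(np.zeros((nl, 1), dtype=int),
                                               values)
            ranked = dict((l, r) for l, _, r in rank_candidates(scores, net, "D0"))
            flat = values[:, 0]
            for i, lncrna in enumerate(net.lncrna_ids):
                naive = (1 + np.sum(flat > flat[i])
                         + 0.5 * (np.sum(flat == flat[i]) - 1))
                assert ranked[lncrna] == pytest.approx(naive)
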