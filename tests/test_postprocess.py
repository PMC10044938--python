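"""Constrained decoding: mask rules, relaxation, rounding, exact oracle."""

import networkx as nx
import numpy as np
import pytest

from foldmap.postprocess import (MIN_SEPARATION, SolverConfig,
                                 brute_force_optimum, build_constraint_mask,
                                 contact_map_to_pairs, discretize,
                                 greedy_complete, integer_objective,
                                 pairs_to_contact_map, predict_structure,
                                 relaxed_primal_dual_solve)
from foldmap.sequence import make_sequence

from conftest import random_sequence, random_symmetric_scores


def _feasible(P, mask):
    return ((P == P.T).all() and not np.diag(P).any()
            and not (P.astype(bool) & ~mask.astype(bool)).any()
            and (P.sum(axis=1) <= 1).all())


def _matching_oracle(S, mask, rho):
    """Independent exact optimum via general max-weight matching."""
    L = S.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(L))
    iu, ju = np.triu_indices(L, k=1)
    for i, j in zip(iu, ju):
        if mask[i, j]:
            G.add_edge(int(i), int(j), weight=2.0 * (S[i, j] - rho))
    match = nx.max_weight_matching(G, maxcardinality=False)
    return sum(G[u][v]["weight"] for u, v in match)


class TestConstraintMask:
    def test_unpairable_sequence_gives_empty_mask(self):
        assert build_constraint_mask(make_sequence("AAAAAAA")).sum() == 0

    def test_gaaac_only_terminal_gc(self):
        mask = build_constraint_mask(make_sequence("GAAAC"))
        expected = np.zeros((5, 5), dtype=np.uint8)
        expected[0, 4] = expected[4, 0] = 1
        assert (mask == expected).all()

    def test_no_short_range_pairs_ever(self, rng):
        for _ in range(30):
            seq = random_sequence(rng, int(rng.integers(5, 60)))
            mask = build_constraint_mask(seq)
            sep = np.abs(np.subtract.outer(np.arange(len(seq)), np.arange(len(seq))))
            assert not mask[sep < MIN_SEPARATION].any()
            assert (mask == mask.T).all()

    def test_only_canonical_and_wobble(self, rng):
        seq = random_sequence(rng, 40)
        mask = build_constraint_mask(seq)
        for i, j in zip(*np.nonzero(mask)):
            duo = frozenset(seq.bases[i] + seq.bases[j])
            assert duo in ({"A", "U"}, {"C", "G"}, {"G", "U"})


class TestRelaxedSolve:
    def test_all_negative_scores_converge_to_zero(self):
        seq = make_sequence("GGGGAAAACCCC")
        S = -np.ones((12, 12))
        rel = relaxed_primal_dual_solve(S, build_constraint_mask(seq))
        assert rel.max() < 1e-6

    def test_single_allowed_cell_saturates(self):
        seq = make_sequence("GAAAC")
        S = np.zeros((5, 5))
        S[0, 4] = S[4, 0] = 5.0
        rel = relaxed_primal_dual_solve(S, build_constraint_mask(seq))
        assert rel[0, 4] == pytest.approx(1.0)
        assert rel[4, 0] == pytest.approx(1.0)

    def test_rejects_asymmetric_scores(self):
        seq = make_sequence("GAAAC")
        S = np.zeros((5, 5))
        S[0, 4] = 1.0  # transpose cell left at 0
        with pytest.raises(ValueError):
            relaxed_primal_dual_solve(S, build_constraint_mask(seq))

    def test_relaxation_upper_bounds_integer_optimum(self, rng):
        # LP feasible region contains every integer-feasible P; check in the
        # well-converged regime (long iteration budget)
        cfg = SolverConfig(iterations=1000)
        for _ in range(20):
            seq = random_sequence(rng, 10)
            S = random_symmetric_scores(rng, 10)
            mask = build_constraint_mask(seq)
            best, _ = brute_force_optimum(S, mask, cfg.rho)
            rel = relaxed_primal_dual_solve(S, mask, cfg)
            rel_obj = float((S * rel).sum() - cfg.rho * rel.sum())
            assert rel_obj >= best - 0.05 * max(1.0, abs(best))


class TestDiscretize:
    def test_zero_input_empty_output(self):
        mask = np.ones((8, 8), dtype=np.uint8)
        assert discretize(np.zeros((8, 8)), mask).sum() == 0

    def test_conflict_keeps_higher_value(self):
        L = 10
        mask = np.ones((L, L), dtype=np.uint8)
        rel = np.zeros((L, L))
        rel[0, 5] = rel[5, 0] = 0.9
        rel[0, 7] = rel[7, 0] = 0.8  # shares base 0
        P = discretize(rel, mask)
        assert P[0, 5] == 1 and P[0, 7] == 0

    def test_row_sums_bounded_on_random_inputs(self, rng):
        for _ in range(300):
            L = int(rng.integers(5, 30))
            rel = rng.random((L, L))
            rel = 0.5 * (rel + rel.T)
            mask = (rng.random((L, L)) < 0.5)
            mask = (mask | mask.T).astype(np.uint8)
            P = discretize(rel, mask, threshold=0.3)
            assert (P.sum(axis=1) <= 1).all()
            assert (P == P.T).all()

    def test_deterministic_tie_break(self):
        L = 10
        mask = np.ones((L, L), dtype=np.uint8)
        rel = np.zeros((L, L))
        rel[0, 5] = rel[5, 0] = 0.7
        rel[0, 6] = rel[6, 0] = 0.7  # tie: smallest (i, j) wins
        P = discretize(rel, mask)
        assert P[0, 5] == 1 and P[0, 6] == 0


class TestPredictStructure:
    def test_crossing_pairs_returned(self):
        # A...G...U...C with strong scores on (0,8) A-U and (4,12) G-C
        seq = make_sequence("AAAAGAAAUAAAC")
        S = np.zeros((13, 13))
        S[0, 8] = S[8, 0] = 3.0
        S[4, 12] = S[12, 4] = 3.0
        P = predict_structure(seq, S)
        pairs = contact_map_to_pairs(P)
        assert (0, 8) in pairs and (4, 12) in pairs

    def test_zero_scores_with_penalty_give_empty_structure(self):
        seq = make_sequence("GGGGAAAACCCC")
        P = predict_structure(seq, np.zeros((12, 12)), SolverConfig(rho=0.1))
        assert P.sum() == 0

    def test_feasible_on_adversarial_scores(self, rng):
        for scale in (0.1, 1.0, 100.0):
            seq = random_sequence(rng, 50)
            S = random_symmetric_scores(rng, 50, scale)
            P = predict_structure(seq, S)
            assert _feasible(P, build_constraint_mask(seq))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_structure(random_sequence(rng, 10), np.zeros((12, 12)))

    def test_pair_count_monotone_in_rho(self, rng):
        seq = random_sequence(rng, 40)
        S = random_symmetric_scores(rng, 40)
        counts = []
        for rho in (0.0, 0.2, 0.5, 1.0, 2.0):
            P = predict_structure(seq, S, SolverConfig(rho=rho))
            counts.append(int(P.sum()) // 2)
        assert counts == sorted(counts, reverse=True)

    def test_greedy_complete_never_decreases_objective(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 30)
            S = random_symmetric_scores(rng, 30)
            mask = build_constraint_mask(seq)
            rel = relaxed_primal_dual_solve(S, mask)
            P0 = discretize(rel, mask)
            P1 = greedy_complete(P0, S, mask, 0.01)
            assert integer_objective(S, P1, 0.01) >= integer_objective(S, P0, 0.01)
            assert _feasible(P1, mask)


class TestBruteForce:
    def test_empty_mask(self):
        val, P = brute_force_optimum(np.ones((6, 6)), np.zeros((6, 6)), 0.0)
        assert val == 0.0 and P.sum() == 0

    def test_single_allowed_pair(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[0, 5] = mask[5, 0] = 1
        S = np.zeros((6, 6))
        S[0, 5] = S[5, 0] = 1.5
        val, P = brute_force_optimum(S, mask, 0.0)
        assert val == pytest.approx(3.0)
        assert P[0, 5] == 1

    def test_refuses_large_instances(self):
        with pytest.raises(ValueError):
            brute_force_optimum(np.zeros((20, 20)), np.zeros((20, 20)), 0.0)

    def test_agrees_with_matching_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(6, 13))
            seq = random_sequence(rng, L)
            S = random_symmetric_scores(rng, L)
            mask = build_constraint_mask(seq)
            val, P = brute_force_optimum(S, mask, 0.01)
            assert val == pytest.approx(_matching_oracle(S, mask, 0.01), abs=1e-9)
            assert val == pytest.approx(integer_objective(S, P, 0.01), abs=1e-9)
            assert _feasible(P, mask)
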