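"""Alignment graph, ILP solve, and the brute-force / DP oracles."""

import numpy as np
import pytest

from pottsalign import (AlignConfig, ScoreTables, brute_force_align,
                        build_alignment_graph, dp_align_independent,
                        independent_site_config, random_potts_model,
                        score_alignment, solve_alignment, solve_from_tables,
                        total_gap_cost)
from pottsalign.ilp import Alignment

from conftest import random_align_config, random_score_tables


def tables(sv, sw=None, self_score=10.0):
    return ScoreTables(sv=np.asarray(sv, dtype=float), sw=sw or {},
                       self_score_A=self_score, self_score_B=self_score)


class TestAlignmentGraph:
    @pytest.mark.parametrize("LA,LB,nodes,edges", [
        (1, 1, 1, 0),
        (2, 2, 4, 1),
        (3, 3, 9, 9),       # C(3,2)² increasing quadruples
        (4, 2, 8, 6),
    ])
    def test_node_and_edge_counts(self, LA, LB, nodes, edges):
        g = build_alignment_graph(LA, LB)
        assert g.n_nodes == nodes
        assert g.n_edges == edges
        assert sum(1 for _ in g.edges()) == edges

    def test_row_and_col_sets_are_antichains(self):
        g = build_alignment_graph(4, 4)
        heads = g.row_set(1, 1, 3)
        assert heads == [(3, 2), (3, 3)]
        # no two nodes of a row set lie on a common increasing path
        for (a, b) in heads:
            for (c, d) in heads:
                if (a, b) != (c, d):
                    assert not (a < c and b < d)
        assert g.col_set(2, 2, 1) == [(0, 1), (1, 1)]

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            build_alignment_graph(0, 3)


class TestAlignmentInvariants:
    def test_pairs_must_strictly_increase(self):
        with pytest.raises(ValueError):
            Alignment(pairs=[(0, 1), (1, 1)], score=0.0)
        with pytest.raises(ValueError):
            Alignment(pairs=[(1, 0), (0, 1)], score=0.0)


class TestSolveBasics:
    def test_two_by_two_all_positive_aligns_diagonal(self):
        cfg = AlignConfig(alpha_w=1.0, gap_open=0.0, offset_gamma=0.0,
                          epsilon=1e-9)
        r = solve_from_tables(tables(np.ones((2, 2))), cfg)
        assert r.alignment.pairs == [(0, 0), (1, 1)]
        assert r.lower_bound == pytest.approx(2.0)

    def test_all_negative_scores_align_nothing(self):
        cfg = AlignConfig(gap_open=0.0, offset_gamma=0.0, epsilon=1e-9)
        r = solve_from_tables(tables(-np.ones((3, 3))), cfg)
        assert r.alignment.pairs == []
        assert r.lower_bound == pytest.approx(0.0)

    def test_single_negative_cell(self):
        cfg = AlignConfig(gap_open=0.0, offset_gamma=0.0, epsilon=1e-9)
        r = solve_from_tables(tables([[-5.0]]), cfg)
        assert r.alignment.pairs == [] and r.lower_bound == pytest.approx(0.0)

    def test_coupling_alone_can_drive_matches(self):
        cfg = AlignConfig(alpha_w=1.0, gap_open=0.0, offset_gamma=0.0,
                          epsilon=1e-9)
        r = solve_from_tables(tables(np.zeros((2, 2)), {(0, 1, 0, 1): 10.0}),
                              cfg)
        assert r.alignment.pairs == [(0, 0), (1, 1)]
        assert r.lower_bound == pytest.approx(10.0)

    def test_self_alignment_recovers_identity(self):
        m = random_potts_model(4, 4, field_scale=1.5, n_coupled_pairs=2,
                               seed=11)
        r = solve_alignment(m, m, AlignConfig(offset_gamma=0.1, epsilon=1e-9),
                            v0=np.zeros(4))
        assert r.alignment.pairs == [(i, i) for i in range(4)]
        assert r.relative_gap <= 1e-9 or r.status == "optimal"


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(25))
    def test_ilp_matches_brute_force_with_couplings(self, seed):
        t = random_score_tables(seed, coupled=True)
        cfg = random_align_config(seed)
        bf = brute_force_align(t, cfg)
        r = solve_from_tables(t, cfg)
        assert r.lower_bound == pytest.approx(bf.score, abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_matches_brute_force_without_couplings(self, seed):
        t = random_score_tables(seed + 500, L_A=6, L_B=7, coupled=False)
        cfg = random_align_config(seed + 500, alpha_w=0.0)
        dp = dp_align_independent(t.sv, cfg.gap_open, cfg.gap_extend)
        bf = brute_force_align(t, cfg)
        assert dp.score == pytest.approx(bf.score, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_independent_site_ilp_equals_dp(self, seed):
        t = random_score_tables(seed + 900, L_A=5, L_B=6, coupled=False)
        cfg = random_align_config(seed + 900, alpha_w=0.0)
        dp = dp_align_independent(t.sv, cfg.gap_open, cfg.gap_extend)
        r = solve_from_tables(t, cfg)
        assert r.lower_bound == pytest.approx(dp.score, abs=1e-7)

    def test_dp_diagonal_preference_and_empty(self):
        sv = np.full((4, 4), -1.0)
        assert dp_align_independent(sv, 1.0, 0.0).pairs == []
        sv = -np.ones((4, 4)) + 5 * np.eye(4)
        assert dp_align_independent(sv, 1.0, 0.0).pairs == \
            [(i, i) for i in range(4)]

    def test_brute_force_size_guard(self):
        with pytest.raises(ValueError):
            brute_force_align(random_score_tables(1, L_A=9, L_B=3),
                              AlignConfig())


class TestSolverProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_of_arguments(self, seed):
        A = random_potts_model(4, 3, field_scale=1.5, n_coupled_pairs=2,
                               seed=seed)
        B = random_potts_model(5, 3, field_scale=1.5, n_coupled_pairs=2,
                               seed=seed + 50)
        cfg = AlignConfig(alpha_w=2.0, gap_open=1.0, offset_gamma=0.2,
                          epsilon=1e-9)
        rab = solve_alignment(A, B, cfg, v0=np.zeros(3))
        rba = solve_alignment(B, A, cfg, v0=np.zeros(3))
        assert rab.lower_bound == pytest.approx(rba.lower_bound, abs=1e-7)
        assert sorted((k, i) for i, k in rab.alignment.pairs) == \
            rba.alignment.pairs

    def test_offset_monotonically_shrinks_alignments(self):
        t0 = random_score_tables(77, L_A=5, L_B=5, coupled=True)
        n_prev = np.inf
        for gamma in (0.0, 0.5, 1.0, 2.0, 4.0):
            t = ScoreTables(sv=t0.sv - gamma, sw=t0.sw, self_score_A=10.0,
                            self_score_B=10.0)
            cfg = AlignConfig(alpha_w=1.0, gap_open=0.5, offset_gamma=gamma,
                              epsilon=1e-9)
            r = solve_from_tables(t, cfg)
            assert r.alignment.n_aligned <= n_prev
            n_prev = r.alignment.n_aligned

    @pytest.mark.parametrize("seed", range(5))
    def test_certificate_honesty_rescoring(self, seed):
        t = random_score_tables(seed + 2000, coupled=True)
        cfg = random_align_config(seed + 2000)
        r = solve_from_tables(t, cfg)
        assert score_alignment(r.alignment.pairs, t, cfg) == \
            pytest.approx(r.lower_bound, abs=1e-6)
        assert r.lower_bound <= r.upper_bound + 1e-9

    def test_gap_cost_bookkeeping(self):
        cfg = AlignConfig(gap_open=2.0, gap_extend=0.5, offset_gamma=0.0)
        # (0,0) -> (2,1): one segment of length 1 in A; (2,1)->(3,4): one
        # segment of length 2 in B
        pairs = [(0, 0), (2, 1), (3, 4)]
        cost = total_gap_cost(pairs, 4, 5, cfg)
        assert cost == pytest.approx((2.0 + 0.5) + (2.0 + 1.0))

    def test_epsilon_certificate_definition(self):
        t = random_score_tables(31, L_A=5, L_B=5, coupled=True,
                                self_score=20.0)
        cfg = AlignConfig(alpha_w=1.0, gap_open=1.0, offset_gamma=0.0,
                          epsilon=0.5)
        r = solve_from_tables(t, cfg)
        if r.status == "epsilon_optimal":
            gap = 2 * (r.upper_bound - r.lower_bound) / (
                t.self_score_A + t.self_score_B)
            assert gap <= cfg.epsilon + 1e-12
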