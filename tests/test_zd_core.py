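"""ZD detection, relations, consistency, independence, existence, symmetry."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from zdgames import (build_double_control, check_consistency,
                     check_independence, check_symmetry, compute_zd_subspace,
                     enforced_relations, iterated_prisoners_dilemma,
                     payoff_matrix, press_dyson, random_game,
                     random_strategy, random_zd_instance, repeat_strategy,
                     rock_paper_scissors, strategy_from_marginal, tit_for_tat,
                     two_relation_game, zd_existence)
from zdgames._numeric import exact_array, zeros_exact
from zdgames.exact_linalg import column_space, contains, matrix_rank
from zdgames.game_model import InvariantError, build_perfect_monitoring_game
from zdgames.strategy_model import MemoryOneStrategy
from zdgames.zd_core import LinearRelation

F = Fraction


# ---------------------------------------------------------------------------
# detection

def test_tft_is_zd_with_equal_payoff_relation(ipd, tft):
    report = compute_zd_subspace(tft, ipd)
    assert report.is_zd and report.dim == 1
    relations = enforced_relations(report, ipd)
    assert len(relations) == 1
    assert list(relations[0].alpha) == [0, 1, -1]  # e_1 - e_2 = 0
    assert not relations[0].ambiguous


def test_repeat_is_not_zd(ipd):
    report = compute_zd_subspace(repeat_strategy(ipd, 0), ipd)
    assert report.dim == 0 and not report.is_zd
    assert enforced_relations(report, ipd) == []


def test_certificates_remultiply_exactly(ipd, tft):
    report = compute_zd_subspace(tft, ipd)
    pd = press_dyson(tft, ipd).matrix
    s = payoff_matrix(ipd).matrix
    for k in range(report.dim):
        u = report.basis[:, k]
        assert all(x == y for x, y in zip(pd.dot(report.combination_certs[k]), u))
        assert all(x == y for x, y in zip(s.dot(report.relation_certs[k]), u))


def test_double_control_dim_two_with_payoff_vectors_inside(double_control):
    game, strat = double_control.game, double_control.strategy
    report = compute_zd_subspace(strat, game)
    assert report.dim == 2
    v = column_space(report.basis)
    assert contains(v, game.payoffs[0])
    assert contains(v, game.payoffs[1])
    relations = enforced_relations(report, game)
    # the two relations jointly force e_1 = e_2 = 0
    res = check_consistency([report], game)
    assert res.consistent
    assert list(res.solution.particular) == [0, 0]
    assert res.solution.solution_dim == 0
    assert len(relations) == 2


def test_double_control_printed_coefficients(double_control):
    # evaluated from the printed formulas at (1, 2, 1/2, 1/4, 1/4, 1/2)
    assert double_control.s1_coefficients == (F(-16, 3), F(-20, 3))
    assert double_control.s2_coefficients == (F(-20, 3), F(-16, 3))


def test_rank_deficient_s_flags_ambiguity(rps):
    rng = np.random.default_rng(0)
    strat = random_strategy(rps, 0, rng)
    report = compute_zd_subspace(strat, rps)
    assert report.relation_ambiguity.shape[1] == 1  # null(S) is 1-dim


# ---------------------------------------------------------------------------
# linear relations

def test_relation_canonical_scaling():
    rel = LinearRelation.canonical(exact_array([0, F(-1, 2), F(1, 2)]))
    assert list(rel.alpha) == [0, 1, -1]


def test_relation_all_zero_rejected():
    with pytest.raises(InvariantError):
        LinearRelation(alpha=exact_array([0, 0, 0]))


# ---------------------------------------------------------------------------
# consistency

def test_tft_pair_consistent_on_equal_payoff_line(ipd):
    reports = [compute_zd_subspace(tit_for_tat(ipd, 0), ipd),
               compute_zd_subspace(tit_for_tat(ipd, 1), ipd)]
    res = check_consistency(reports, ipd)
    assert res.consistent
    assert res.rank_a == res.rank_a_bar == 1
    e = res.solution.particular
    assert e[0] == e[1]
    assert res.solution.solution_dim == 1  # the whole line e_1 = e_2


def test_empty_set_consistent(ipd):
    res = check_consistency([], ipd)
    assert res.consistent
    assert res.solution.solution_dim == ipd.n_players


def test_non_zd_report_rejected(ipd):
    report = compute_zd_subspace(repeat_strategy(ipd, 0), ipd)
    with pytest.raises(InvariantError, match="not ZD"):
        check_consistency([report], ipd)


@pytest.mark.parametrize("seed", range(40))
def test_consistency_sweep(seed):
    # any set of detected ZD strategies must be consistent
    rng = np.random.default_rng(1000 + seed)
    game, _, reports = random_zd_instance(rng)
    res = check_consistency(reports, game)
    assert res.consistent
    # dimension cap: pooled span has at most N independent relations
    pooled = np.concatenate([r.basis for r in reports], axis=1)
    assert matrix_rank(pooled) <= game.n_players


# ---------------------------------------------------------------------------
# independence

def test_tft_mirror_pair_dependent(ipd):
    reports = [compute_zd_subspace(tit_for_tat(ipd, 0), ipd),
               compute_zd_subspace(tit_for_tat(ipd, 1), ipd)]
    res = check_independence(reports, ipd)
    assert not res.independent
    assert res.witness is not None
    # the witness vectors are nonzero, one per player, linearly dependent
    v0, v1 = res.witness[0], res.witness[1]
    assert any(x != 0 for x in v0) and any(x != 0 for x in v1)
    stacked = np.concatenate([v0.reshape(-1, 1), v1.reshape(-1, 1)], axis=1)
    assert matrix_rank(stacked) == 1


def test_single_zd_player_independent(ipd, tft):
    res = check_independence([compute_zd_subspace(tft, ipd)], ipd)
    assert res.independent


@pytest.mark.parametrize("seed", range(40))
def test_independence_sweep_no_zero_entries(seed):
    rng = np.random.default_rng(2000 + seed)
    game, _, reports = random_zd_instance(rng, min_weight=1)
    res = check_independence(reports, game)
    assert res.no_zero_hypothesis
    assert res.independent


# ---------------------------------------------------------------------------
# Lemma 1: the all-ones vector never lies in the pooled strategy span

@pytest.mark.parametrize("seed", range(30))
def test_ones_never_in_pooled_press_dyson_span(seed):
    rng = np.random.default_rng(3000 + seed)
    counts = tuple(int(rng.integers(2, 4)) for _ in range(int(rng.integers(2, 4))))
    game = random_game(seed=seed, action_counts=counts)
    pooled = np.concatenate(
        [press_dyson(random_strategy(game, n, rng), game).matrix
         for n in range(game.n_players)], axis=1)
    ones = exact_array([1] * game.n_states)
    assert not contains(column_space(pooled), ones)


# ---------------------------------------------------------------------------
# existence

def test_no_zd_in_rock_paper_scissors(rps):
    res = zd_existence(rps, 0)
    assert res.exists is False
    assert res.certificate["decision"] == "all_lps_infeasible"


def test_zd_exists_in_ipd_and_tft_is_valid_witness(ipd, tft):
    res = zd_existence(ipd, 0)
    assert res.exists is True
    assert res.witness is not None
    assert compute_zd_subspace(res.witness, ipd).is_zd
    # tit-for-tat is an accepted external witness for the same claim
    assert compute_zd_subspace(tft, ipd).is_zd


def test_zd_exists_in_two_relation_game(trg):
    res = zd_existence(trg, 0)
    assert res.exists is True
    assert compute_zd_subspace(res.witness, trg).is_zd


def test_exact_mode_refuses_imperfect_monitoring():
    from zdgames import winner_signal_game
    game = winner_signal_game()
    with pytest.raises(InvariantError, match="heuristic"):
        zd_existence(game, 0)


def grid_search_2x2(game, player, grid):
    """Brute-force oracle: enumerate marginal tables over a coarse grid."""
    s = payoff_matrix(game).matrix
    span_s = column_space(s)
    other = 1 - player
    for probs in itertools.product(grid, repeat=4):
        marginal = zeros_exact((2, game.n_states))
        for j, p in enumerate(probs):
            marginal[0, j] = p
            marginal[1, j] = 1 - p
        strat = strategy_from_marginal(game, player, marginal)
        pd = press_dyson(strat, game).matrix
        u = pd[:, 0]
        if any(x != 0 for x in u) and contains(span_s, u):
            return True
    return False


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
def test_existence_agrees_with_grid_search_on_2x2(seed):
    game = random_game(seed=seed, action_counts=(2, 2))
    grid = [F(k, 4) for k in range(5)]
    lp = zd_existence(game, 0)
    grid_found = grid_search_2x2(game, 0, grid)
    if grid_found:
        assert lp.exists is True
    if lp.exists is False:
        assert not grid_found


def test_grid_search_finds_tft_in_ipd(ipd):
    assert grid_search_2x2(ipd, 0, [F(k, 2) for k in range(3)])


def test_heuristic_mode_on_imperfect_monitoring_never_claims_false():
    from zdgames import winner_signal_game
    game = winner_signal_game()
    res = zd_existence(game, 0, heuristic=True, seed=0, restarts=5)
    assert res.mode == "heuristic"
    assert res.exists in (True, None)  # a miss is undecided, never False


# ---------------------------------------------------------------------------
# symmetry

def test_two_relation_game_symmetric_under_swap(trg):
    res = check_symmetry(trg)
    assert (1, 0) in res["symmetric_permutations"]
    assert res["weakly_symmetric"]


def test_ipd_symmetric_under_swap(ipd):
    res = check_symmetry(ipd)
    assert (1, 0) in res["symmetric_permutations"]
    assert res["weakly_symmetric"]


def test_asymmetric_game_only_identity():
    game = build_perfect_monitoring_game(
        (2, 2), [[1, 2, 3, 4], [5, 6, 7, 8]])
    res = check_symmetry(game)
    assert res["symmetric_permutations"] == [(0, 1)]
    assert not res["weakly_symmetric"]


def test_symmetry_refuses_large_player_count():
    counts = (2,) * 7
    game = build_perfect_monitoring_game(
        counts, np.zeros((7, 2 ** 7), dtype=int))
    with pytest.raises(InvariantError, match="refused"):
        check_symmetry(game)


def test_full_dimensional_zd_impossible_in_weakly_symmetric_fixtures(rps):
    # empirical reading of the impossibility statements: an N-dimensional
    # ZD strategy cannot exist in these weakly symmetric games, so the
    # existence search never returns a dim-2 witness for rock-paper-scissors
    res = zd_existence(rps, 0)
    assert res.exists is False  # no ZD at all, a fortiori none of dim N


# ---------------------------------------------------------------------------
# double control construction

def test_double_control_invalid_parameters():
    with pytest.raises(InvariantError, match="q <= p"):
        build_double_control(1, 2, F(1, 4), F(1, 2), F(1, 4), F(1, 2))
    with pytest.raises(InvariantError, match="p' <= q'"):
        build_double_control(1, 2, F(1, 2), F(1, 4), F(1, 2), F(1, 4))
    with pytest.raises(InvariantError, match="0 <= p"):
        build_double_control(1, 2, 2, F(1, 4), F(1, 4), F(1, 2))
    with pytest.raises(InvariantError, match="degenerate"):
        build_double_control(1, 2, F(1, 2), F(1, 2), F(1, 2), F(1, 2))


def test_double_control_equal_payoff_parameters_flagged():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = build_double_control(1, 1, F(1, 2), F(1, 4), F(1, 4), F(1, 2))
    assert res.degenerate_payoffs


def test_symmetric_corollary_relations_force_equal_payoffs(double_control):
    # in the symmetric 3x3 game any dim-2 ZD subspace solves to e_1 = e_2 (= 0)
    game = double_control.game
    report = compute_zd_subspace(double_control.strategy, game)
    res = check_consistency([report], game)
    e = res.solution.particular
    assert res.solution.solution_dim == 0
    assert e[0] == e[1]
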