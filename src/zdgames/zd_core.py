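"""Zero-determinant strategy analyses.

A strategy of player ``n`` is zero-determinant (ZD) when the column space
of its Press-Dyson matrix meets ``span(1_M, s_1, ..., s_N)`` nontrivially;
each intersection direction enforces one linear relation
``alpha_0 + sum_n alpha_n e_n = 0`` on the long-run average payoffs.
This module detects ZD strategies and their enforced relations, decides
consistency and independence of ZD sets, searches for ZD existence in a
given game, checks game symmetry, and builds the two-relation
simultaneous-control example in the 3x3 game.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from ._numeric import DEFAULT_TOL, exact_array, float_array, frac, is_exact, zeros_exact
from .exact_linalg import (RoucheCapelliResult, Subspace, column_space,
                           intersect, matrix_rank, nullspace, rouche_capelli,
                           solve_linear)
from .game_model import (Game, InvariantError, all_states, index_to_state,
                         payoff_matrix, state_index, two_relation_game)
from .strategy_model import (MemoryOneStrategy, press_dyson, random_strategy,
                             strategy_from_marginal, validate_strategy)

__all__ = [
    "LinearRelation",
    "ZDReport",
    "ConsistencyReport",
    "IndependenceResult",
    "ExistenceResult",
    "DoubleControlResult",
    "compute_zd_subspace",
    "enforced_relations",
    "check_consistency",
    "check_independence",
    "zd_existence",
    "check_symmetry",
    "build_double_control",
    "random_zd_instance",
]


# ---------------------------------------------------------------------------
# reports

@dataclass
class LinearRelation:
    """``alpha_0 + sum_n alpha_n e_n = 0`` with canonical scaling.

    The first nonzero coefficient is scaled to +1.  When the payoff-state
    matrix S is rank deficient, ``alpha`` is determined only up to
    ``null(S)``; that ambiguity basis is carried along explicitly.
    """

    alpha: np.ndarray  # length N+1
    ambiguity: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0), dtype=object))

    @property
    def ambiguous(self) -> bool:
        return self.ambiguity.shape[1] > 0

    def __post_init__(self) -> None:
        if all(x == 0 for x in self.alpha):
            raise InvariantError("a linear relation needs a nonzero coefficient")

    @classmethod
    def canonical(cls, alpha: np.ndarray, ambiguity=None) -> "LinearRelation":
        lead = next(x for x in alpha if x != 0)
        scaled = np.array([x / lead for x in alpha], dtype=alpha.dtype)
        if ambiguity is None:
            ambiguity = np.empty((alpha.shape[0], 0), dtype=object)
        return cls(alpha=scaled, ambiguity=ambiguity)


@dataclass
class ZDReport:
    """Subspace ``V_n`` with certificates for each basis direction.

    ``basis[:, k]`` equals both ``press_dyson . combination_certs[k]`` and
    ``S . relation_certs[k]`` (re-multiplication is exact in rational
    mode).
    """

    player: int
    dim: int
    basis: np.ndarray                       # (M, dim)
    combination_certs: list[np.ndarray]     # c_k, length M_n each
    relation_certs: list[np.ndarray]        # alpha_k, length N+1 each
    relation_ambiguity: np.ndarray          # basis of null(S), (N+1, d)
    is_zd: bool
    press_dyson_has_zeros: bool


@dataclass
class ConsistencyReport:
    """Rouché-Capelli data for a pooled set of enforced relations."""

    a_full: np.ndarray      # (N+1, K): columns alpha_k (matrix A)
    a_bar: np.ndarray       # (N, K): payoff-coefficient rows
    b: np.ndarray           # length K: constant coefficients
    rank_a: int
    rank_a_bar: int
    consistent: bool
    solution: RoucheCapelliResult  # affine set E in (e_1, ..., e_N)


@dataclass
class IndependenceResult:
    independent: bool
    witness: dict[int, np.ndarray] | None  # per-player nonzero v_n, dependent
    no_zero_hypothesis: bool  # every Press-Dyson column free of zeros


@dataclass
class ExistenceResult:
    exists: bool | None
    witness: MemoryOneStrategy | None
    certificate: dict
    mode: str  # "exact" (perfect monitoring) or "heuristic"

    def __post_init__(self) -> None:
        if self.exists is None and self.mode != "heuristic":
            raise InvariantError("undecided result only allowed in heuristic mode")


@dataclass
class DoubleControlResult:
    game: Game
    strategy: MemoryOneStrategy
    s1_coefficients: tuple[Fraction, Fraction]  # on Ttilde_1(1), Ttilde_1(2)
    s2_coefficients: tuple[Fraction, Fraction]
    dim: int
    degenerate_payoffs: bool


# ---------------------------------------------------------------------------
# detection

def compute_zd_subspace(strategy: MemoryOneStrategy, game: Game,
                        tol: float = DEFAULT_TOL) -> ZDReport:
    """Intersect the strategy's Press-Dyson span with ``span S``."""
    pd = press_dyson(strategy, game)
    s = payoff_matrix(game, tol).matrix
    span_pd = column_space(pd.matrix, tol)
    span_s = column_space(s, tol)
    v = intersect(span_pd, span_s)
    combos, alphas = [], []
    for k in range(v.dim):
        u = v.basis[:, k]
        c = solve_linear(pd.matrix, u, tol)
        alpha = solve_linear(s, u, tol)
        if c is None or alpha is None:
            raise InvariantError("intersection certificate failed to resolve")
        combos.append(c)
        alphas.append(alpha)
    return ZDReport(
        player=strategy.player,
        dim=v.dim,
        basis=v.basis,
        combination_certs=combos,
        relation_certs=alphas,
        relation_ambiguity=nullspace(s, tol),
        is_zd=v.dim >= 1,
        press_dyson_has_zeros=pd.has_zero_elements,
    )


def enforced_relations(report: ZDReport, game: Game) -> list[LinearRelation]:
    """One canonical linear payoff relation per basis direction of V_n."""
    if not report.is_zd:
        return []
    return [LinearRelation.canonical(alpha, report.relation_ambiguity)
            for alpha in report.relation_certs]


# ---------------------------------------------------------------------------
# consistency of a set of ZD strategies

def check_consistency(reports: list[ZDReport], game: Game,
                      tol: float = DEFAULT_TOL) -> ConsistencyReport:
    """Pool the subspaces V_n, extract relations, apply Rouché-Capelli.

    Builds a basis ``u_1..u_K`` of ``span(V_n)_{n in N'}``, writes each as
    ``S alpha_k``, splits the stacked coefficient matrix into the constant
    row ``b`` and payoff rows ``A_bar``, and decides solvability of
    ``e_bar^T A_bar + b^T = 0``.
    """
    for r in reports:
        if not r.is_zd:
            raise InvariantError(f"player {r.player + 1} report is not ZD")
    n = game.n_players
    s = payoff_matrix(game, tol).matrix
    if reports:
        stacked = np.concatenate([r.basis for r in reports], axis=1)
        pooled = column_space(stacked, tol)
    else:
        pooled = column_space(zeros_exact((game.n_states, 0)), tol)
    k = pooled.dim
    exact = pooled.exact
    a_full = zeros_exact((n + 1, k)) if exact else np.zeros((n + 1, k))
    for i in range(k):
        alpha = solve_linear(s, pooled.basis[:, i], tol)
        if alpha is None:
            raise InvariantError("pooled basis vector left span S")
        a_full[:, i] = alpha
    b = a_full[0, :]
    a_bar = a_full[1:, :]
    solution = rouche_capelli(a_bar, b, tol)
    rank_a = matrix_rank(a_full, tol) if k else 0
    return ConsistencyReport(
        a_full=a_full, a_bar=a_bar, b=b,
        rank_a=rank_a, rank_a_bar=solution.rank_coeff,
        consistent=solution.consistent, solution=solution)


# ---------------------------------------------------------------------------
# independence of a set of ZD strategies

def check_independence(reports: list[ZDReport], game: Game,
                       tol: float = DEFAULT_TOL) -> IndependenceResult:
    """Joint independence: no V_n meets the span of the others.

    Equivalent to requiring every selection of one nonzero vector per
    player to be linearly independent.  On dependence, returns a witness
    selection: a vector in the overlap plus its decomposition over the
    other players' subspaces (padded with basis vectors where a player
    contributes nothing).
    """
    for r in reports:
        if not r.is_zd:
            raise InvariantError(f"player {r.player + 1} report is not ZD")
    no_zeros = all(not r.press_dyson_has_zeros for r in reports)
    if len(reports) <= 1:
        return IndependenceResult(True, None, no_zeros)
    for i, rep in enumerate(reports):
        others = [r for j, r in enumerate(reports) if j != i]
        stacked = np.concatenate([r.basis for r in others], axis=1)
        span_others = column_space(stacked, tol)
        v_n = Subspace(game.n_states, rep.basis, tol)
        overlap = intersect(v_n, span_others)
        if overlap.dim >= 1:
            v = overlap.basis[:, 0]
            coeffs = solve_linear(stacked, v, tol)
            witness: dict[int, np.ndarray] = {rep.player: v}
            offset = 0
            for other in others:
                d = other.basis.shape[1]
                part = other.basis.dot(coeffs[offset:offset + d])
                offset += d
                nonzero = any(x != 0 for x in part) if is_exact(other.basis) \
                    else bool(np.any(np.abs(float_array(part)) > tol))
                witness[other.player] = part if nonzero else other.basis[:, 0]
            return IndependenceResult(False, witness, no_zeros)
    return IndependenceResult(True, None, no_zeros)


# ---------------------------------------------------------------------------
# existence search

def zd_existence(game: Game, player: int, heuristic: bool = False,
                 seed: int = 0, restarts: int = 50,
                 tol: float = DEFAULT_TOL) -> ExistenceResult:
    """Decide whether player ``player`` has any ZD strategy in ``game``.

    Perfect monitoring admits an exact decision: a ZD strategy exists iff
    there are ``c`` and ``alpha`` with ``S alpha != 0`` and, at every
    previous state, ``min(c) - c_own <= (S alpha) <= max(c) - c_own``
    (each Press-Dyson row is a probability vector minus the own-action
    indicator, so ``c``-combinations sweep exactly that interval).  The
    search enumerates ordered (argmin, argmax) index pairs of ``c`` and a
    nontriviality coordinate/sign, each a linear program.

    Imperfect monitoring requires ``heuristic=True`` (alternating random
    ``c`` draws over a joint LP in the table and alpha); a negative
    heuristic answer is reported as undecided, never as nonexistence.
    """
    if not 0 <= player < game.n_players:
        raise InvariantError(f"player index {player} out of range")
    if not game.perfect_monitoring:
        if not heuristic:
            raise InvariantError(
                "game has imperfect monitoring: the exact decision procedure "
                "does not apply; pass heuristic=True for a non-exhaustive search")
        return _zd_existence_heuristic(game, player, seed, restarts, tol)
    return _zd_existence_perfect(game, player, tol)


def _own_action_indices(game: Game, player: int) -> list[int]:
    return [index_to_state(j, game)[player] - 1 for j in range(game.n_states)]


def _zd_existence_perfect(game: Game, player: int, tol: float) -> ExistenceResult:
    m_n, m = game.action_counts[player], game.n_states
    n = game.n_players
    s = payoff_matrix(game).matrix
    s_f = float_array(s)
    own = _own_action_indices(game, player)
    n_vars = m_n + (n + 1)  # c then alpha
    lp_count = 0
    for i_star, j_star in itertools.permutations(range(m_n), 2):
        a_ub, b_ub = [], []
        # ordering constraints: c_i* <= c_k <= c_j*
        for k in range(m_n):
            if k != i_star:
                row = np.zeros(n_vars); row[i_star] = 1.0; row[k] = -1.0
                a_ub.append(row); b_ub.append(0.0)
            if k != j_star:
                row = np.zeros(n_vars); row[k] = 1.0; row[j_star] = -1.0
                a_ub.append(row); b_ub.append(0.0)
        # interval constraints per previous state
        for j in range(m):
            up = np.zeros(n_vars)
            up[m_n:] = s_f[j]
            up[own[j]] += 1.0
            up[j_star] -= 1.0
            a_ub.append(up); b_ub.append(0.0)      # u(j) + c_own - c_j* <= 0
            low = np.zeros(n_vars)
            low[m_n:] = -s_f[j]
            low[own[j]] -= 1.0
            low[i_star] += 1.0
            a_ub.append(low); b_ub.append(0.0)     # c_i* - c_own - u(j) <= 0
        a_eq = np.zeros((1, n_vars)); a_eq[0, i_star] = 1.0  # pin translation
        base_ub = np.array(a_ub); base_rhs = np.array(b_ub)
        for coord, sign in itertools.product(range(m), (1.0, -1.0)):
            extra = np.zeros(n_vars)
            extra[m_n:] = -sign * s_f[coord]
            rows = np.vstack([base_ub, extra])
            rhs = np.append(base_rhs, -1.0)       # sign * u(coord) >= 1
            lp_count += 1
            res = linprog(np.zeros(n_vars), A_ub=rows, b_ub=rhs,
                          A_eq=a_eq, b_eq=[0.0],
                          bounds=[(-1e4, 1e4)] * n_vars, method="highs")
            if res.status == 0:
                witness = _reconstruct_witness(game, player, res.x[:m_n],
                                               res.x[m_n:], i_star, j_star, tol)
                certificate = {
                    "decision": "feasible",
                    "pair": (i_star, j_star),
                    "coordinate": coord,
                    "sign": int(sign),
                    "lps_solved": lp_count,
                    "witness_verified": witness is not None,
                }
                return ExistenceResult(True, witness, certificate, "exact")
    return ExistenceResult(False, None,
                           {"decision": "all_lps_infeasible",
                            "lps_solved": lp_count}, "exact")


def _reconstruct_witness(game: Game, player: int, c_f: np.ndarray,
                         alpha_f: np.ndarray, i_star: int, j_star: int,
                         tol: float) -> MemoryOneStrategy | None:
    """Snap the LP point to rationals and rebuild an exact ZD strategy."""
    m_n, m = game.action_counts[player], game.n_states
    s = payoff_matrix(game).matrix
    own = _own_action_indices(game, player)
    for denom_cap in (1, 4, 16, 128, 2048, 10 ** 6, 10 ** 9):
        c = [Fraction(float(x)).limit_denominator(denom_cap) for x in c_f]
        alpha = [Fraction(float(x)).limit_denominator(denom_cap) for x in alpha_f]
        u = [sum(s[j, t] * alpha[t] for t in range(len(alpha))) for j in range(m)]
        if all(x == 0 for x in u):
            continue
        c_lo, c_hi = min(c), max(c)
        if c_hi == c_lo:
            continue
        ok = all(c_lo - c[own[j]] <= u[j] <= c_hi - c[own[j]] for j in range(m))
        if not ok:
            continue
        marginal = zeros_exact((m_n, m))
        for j in range(m):
            v = u[j] + c[own[j]]
            lam = None
            if c[j_star] != c[i_star]:
                lam = (c[j_star] - v) / (c[j_star] - c[i_star])
                lo_idx, hi_idx = i_star, j_star
            if lam is None or not 0 <= lam <= 1:
                # c may attain its extremes off (i*, j*) after snapping
                lam = (c_hi - v) / (c_hi - c_lo)
                lo_idx = c.index(c_lo)
                hi_idx = c.index(c_hi)
            marginal[lo_idx, j] += lam
            marginal[hi_idx, j] += 1 - lam
        strategy = strategy_from_marginal(game, player, marginal)
        report = compute_zd_subspace(strategy, game, tol)
        if report.is_zd:
            return strategy
    return None


def _zd_existence_heuristic(game: Game, player: int, seed: int,
                            restarts: int, tol: float) -> ExistenceResult:
    """Random-c restarts; for fixed c the search over (table, alpha) is an LP."""
    rng = np.random.default_rng(seed)
    m_n, m, b = game.action_counts[player], game.n_states, len(game.signals)
    n = game.n_players
    s_f = float_array(payoff_matrix(game).matrix)
    kernel_f = float_array(game.signal_kernel)
    own = _own_action_indices(game, player)
    n_table = m_n * m_n * b

    def var(a, prev, tau):
        return (a * m_n + prev) * b + tau

    for trial in range(restarts):
        c = rng.standard_normal(m_n)
        c = (c - c.min()) / max(c.max() - c.min(), 1e-12)  # range-1 spread
        # equalities: sum_a c_a T(a|sigma') - c_own - (S alpha)(sigma') = 0
        a_eq, b_eq = [], []
        for j in range(m):
            row = np.zeros(n_table + n + 1)
            for a in range(m_n):
                for tau in range(b):
                    if kernel_f[tau, j]:
                        row[var(a, own[j], tau)] += c[a] * kernel_f[tau, j]
            row[n_table:] = -s_f[j]
            a_eq.append(row); b_eq.append(c[own[j]])
        for prev in range(m_n):
            for tau in range(b):
                row = np.zeros(n_table + n + 1)
                for a in range(m_n):
                    row[var(a, prev, tau)] = 1.0
                a_eq.append(row); b_eq.append(1.0)
        bounds = [(0.0, 1.0)] * n_table + [(-1e4, 1e4)] * (n + 1)
        for coord, sign in itertools.product(range(m), (1.0, -1.0)):
            push = np.zeros(n_table + n + 1)
            push[n_table:] = -sign * s_f[coord]
            res = linprog(np.zeros(n_table + n + 1),
                          A_ub=push.reshape(1, -1), b_ub=[-0.05],
                          A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                          bounds=bounds, method="highs")
            if res.status != 0:
                continue
            table = np.zeros((m_n, m_n, b))
            for a in range(m_n):
                for prev in range(m_n):
                    for tau in range(b):
                        table[a, prev, tau] = res.x[var(a, prev, tau)]
            candidate = MemoryOneStrategy(player=player, table=exact_array(table))
            # float residual check: u = S alpha matched by the c-combination
            alpha = res.x[n_table:]
            u = s_f.dot(alpha)
            pd_f = float_array(press_dyson(candidate, game).matrix)
            residual = float(np.max(np.abs(pd_f.dot(c) - u)))
            if residual <= 1e-6 and np.max(np.abs(u)) > 1e-3:
                return ExistenceResult(
                    True, candidate,
                    {"decision": "heuristic_feasible", "restart": trial,
                     "residual": residual},
                    "heuristic")
    return ExistenceResult(None, None,
                           {"decision": "heuristic_not_found",
                            "restarts": restarts,
                            "note": "non-exhaustive search; existence undecided"},
                           "heuristic")


# ---------------------------------------------------------------------------
# symmetry

def check_symmetry(game: Game, max_players: int = 6) -> dict:
    """All player permutations preserving the payoff structure.

    ``pi`` is a symmetry when ``M_n = M_pi(n)`` for all ``n`` and
    ``s_pi(n)(sigma) = s_n(sigma_pi)`` for every state, where
    ``sigma_pi = (sigma_pi(1), ..., sigma_pi(N))``.  The game is weakly
    symmetric when every ordered player pair is connected by a symmetry.
    """
    n = game.n_players
    if n > max_players:
        raise InvariantError(
            f"symmetry enumeration over {n}! permutations refused for "
            f"N > {max_players}; raise max_players explicitly if intended")
    states = all_states(game)
    symmetries = []
    for pi in itertools.permutations(range(n)):
        if any(game.action_counts[k] != game.action_counts[pi[k]] for k in range(n)):
            continue
        ok = True
        for sigma in states:
            sigma_pi = tuple(sigma[pi[k]] for k in range(n))
            j = state_index(sigma, game)
            j_pi = state_index(sigma_pi, game)
            for k in range(n):
                if game.payoffs[pi[k], j] != game.payoffs[k, j_pi]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            symmetries.append(pi)
    weakly = all(
        any(pi[a] == b for pi in symmetries)
        for a in range(n) for b in range(n))
    return {"symmetric_permutations": symmetries, "weakly_symmetric": weakly}


# ---------------------------------------------------------------------------
# simultaneous two-relation construction

def build_double_control(r1, r2, p, q, p_prime, q_prime,
                         tol: float = DEFAULT_TOL) -> DoubleControlResult:
    """The 3x3 game and the strategy enforcing ``e_1 = e_2 = 0`` at once.

    Parameters must satisfy ``0 <= p, q, p', q' <= 1``, ``q <= p`` and
    ``p' <= q'``; ``p' q != p q'`` is required for the two strategy
    vectors to be independent.  The construction is verified
    algebraically: the stated combinations of the first two strategy
    vectors reproduce ``s_1`` and ``s_2`` exactly, and ``dim V_1 = 2``
    when the payoffs are nondegenerate.
    """
    r1, r2 = frac(r1), frac(r2)
    p, q, pp, qp = frac(p), frac(q), frac(p_prime), frac(q_prime)
    for name, value in (("p", p), ("q", q), ("p_prime", pp), ("q_prime", qp)):
        if not 0 <= value <= 1:
            raise InvariantError(f"parameter {name} = {value} violates 0 <= {name} <= 1")
    if q > p:
        raise InvariantError(f"q = {q} > p = {p} violates q <= p")
    if pp > qp:
        raise InvariantError(f"p_prime = {pp} > q_prime = {qp} violates p' <= q'")
    det = pp * q - p * qp
    if det == 0:
        raise InvariantError("degenerate parameters: p' q = p q' makes the "
                             "strategy vectors dependent")
    degenerate = r1 == r2 or r1 == -r2
    game = two_relation_game(r1, r2)

    zero, one = Fraction(0), Fraction(1)
    marginal = exact_array([
        [one, one - p, one, pp, zero, zero, zero, zero, zero],
        [zero, q, zero, one - qp, one, one, zero, zero, zero],
        [zero, p - q, zero, qp - pp, zero, zero, one, one, one],
    ])
    strategy = strategy_from_marginal(game, 0, marginal)
    report = validate_strategy(strategy, game)
    if not report.ok:
        raise InvariantError("double-control strategy invalid: "
                             + "; ".join(report.failures))

    pd = press_dyson(strategy, game).matrix
    s1 = game.payoffs[0]
    s2 = game.payoffs[1]
    k1 = (qp * r1 + q * r2) / det
    k2 = (pp * r1 + p * r2) / det
    k1p = (qp * r2 + q * r1) / det
    k2p = (pp * r2 + p * r1) / det
    for coeffs, target in (((k1, k2), s1), ((k1p, k2p), s2)):
        combo = coeffs[0] * pd[:, 0] + coeffs[1] * pd[:, 1]
        if any(combo[j] != target[j] for j in range(game.n_states)):
            raise InvariantError("algebraic verification of the printed "
                                 "combinations failed")
    zd = compute_zd_subspace(strategy, game, tol)
    if not degenerate and zd.dim != 2:
        raise InvariantError(f"expected dim V_1 = 2, got {zd.dim}")
    return DoubleControlResult(
        game=game, strategy=strategy,
        s1_coefficients=(k1, k2), s2_coefficients=(k1p, k2p),
        dim=zd.dim, degenerate_payoffs=degenerate)


# ---------------------------------------------------------------------------
# seeded random (game, ZD-strategy-set) instances for property sweeps

def random_zd_instance(rng: np.random.Generator, n_players: int | None = None,
                       n_zd: int | None = None, min_weight: int = 0,
                       cross_terms: bool = True):
    """Random game together with a set of detected ZD strategies.

    Samples strategies first, picks a nonzero Press-Dyson combination
    ``u_n`` per ZD player, then constructs payoffs whose span contains
    every ``u_n`` (via an invertible triangular mixing plus constants), so
    each chosen player is ZD by construction.  ``min_weight >= 1`` keeps
    every Press-Dyson entry nonzero.

    Returns ``(game, strategies, reports)`` with one validated
    :class:`ZDReport` per ZD player (all ``is_zd``).
    """
    from .game_model import build_perfect_monitoring_game
    n = n_players if n_players is not None else int(rng.integers(2, 4))
    action_counts = tuple(int(rng.integers(2, 4)) for _ in range(n))
    m = int(np.prod(action_counts))
    n_zd = n_zd if n_zd is not None else int(rng.integers(1, n + 1))
    zd_players = sorted(rng.choice(n, size=n_zd, replace=False).tolist())

    # placeholder game fixes the state indexing for strategy sampling
    placeholder = build_perfect_monitoring_game(
        action_counts, zeros_exact((n, m)))
    strategies, directions = {}, {}
    for player in zd_players:
        for _ in range(64):
            strat = random_strategy(placeholder, player, rng,
                                    min_weight=min_weight)
            pd = press_dyson(strat, placeholder).matrix
            m_n = action_counts[player]
            c = exact_array([Fraction(int(rng.integers(-4, 5)), 2)
                             for _ in range(m_n)])
            u = pd.dot(c)
            if any(x != 0 for x in u):
                strategies[player] = strat
                directions[player] = u
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to sample a nonzero strategy vector")

    payoffs = zeros_exact((n, m))
    zd_order = list(zd_players)
    for rank_pos, player in enumerate(zd_order):
        vec = directions[player].copy()
        beta = Fraction(int(rng.integers(-3, 4)), 2)
        vec = vec + np.array([beta] * m, dtype=object)
        if cross_terms:
            for earlier in zd_order[:rank_pos]:  # triangular: keeps span intact
                gamma = Fraction(int(rng.integers(-2, 3)), 2)
                if gamma:
                    vec = vec + gamma * directions[earlier]
        payoffs[player] = vec
    for player in range(n):
        if player not in strategies:
            payoffs[player] = exact_array(
                [Fraction(int(x), 2) for x in rng.integers(-6, 7, size=m)])

    game = build_perfect_monitoring_game(action_counts, payoffs)
    reports = []
    for player in zd_players:
        report = compute_zd_subspace(strategies[player], game)
        if not report.is_zd:  # pragma: no cover - construction guarantees ZD
            raise RuntimeError("constructed instance lost the ZD property")
        reports.append(report)
    return game, [strategies[p] for p in zd_players], reports
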