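"""Memory-one strategies under public monitoring.

A strategy of player ``n`` is the table ``That_n(a | prev, tau)``: the
probability of playing ``a`` next given own previous action ``prev`` and
the public signal ``tau``.  From it we derive the marginal transition
``T_n(a | sigma') = sum_tau W(tau | sigma') That_n(a | sigma'_n, tau)``
and the Press-Dyson matrix ``Ttilde_n = T_n - Repeat``, whose columns are
the strategy vectors: their inner product with any stationary
distribution of the induced chain vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from ._numeric import DEFAULT_TOL, exact_array, float_array, frac, is_exact, zeros_exact
from .exact_linalg import nullspace, solve_linear
from .game_model import Game, InvariantError, SchemaError, all_states, index_to_state

__all__ = [
    "MemoryOneStrategy",
    "MarginalTransition",
    "PressDysonMatrix",
    "ValidationReport",
    "RealizeResult",
    "validate_strategy",
    "marginal_transition",
    "press_dyson",
    "realize_marginal",
    "strategy_from_marginal",
    "repeat_strategy",
    "uniform_strategy",
    "tit_for_tat",
    "random_strategy",
    "named_strategy",
]


@dataclass
class MemoryOneStrategy:
    """Table ``That(a | prev, tau)`` for one player.

    ``table`` has shape ``(M_n, M_n, |B|)`` indexed ``[a, prev, tau]``
    with 0-based actions; for every ``(prev, tau)`` the column over ``a``
    is a probability distribution.
    """

    player: int  # 0-based
    table: np.ndarray


@dataclass
class MarginalTransition:
    """``T_n(a | sigma')`` as an ``(M_n, M)`` column-stochastic matrix."""

    player: int
    matrix: np.ndarray


@dataclass
class PressDysonMatrix:
    """``(M, M_n)`` matrix whose columns are the strategy vectors.

    Row sums vanish (the columns sum to the zero vector against 1_{M_n});
    the entry at ``(sigma', a)`` is nonpositive when ``sigma'_n = a`` and
    nonnegative otherwise.
    """

    player: int
    matrix: np.ndarray
    has_zero_elements: bool


@dataclass
class ValidationReport:
    ok: bool
    failures: list[str]


@dataclass
class RealizeResult:
    """Outcome of trying to realize a target marginal under a kernel W."""

    feasible: bool
    strategy: MemoryOneStrategy | None
    status: str
    exact: bool = False


# ---------------------------------------------------------------------------
# validation

def validate_strategy(strategy: MemoryOneStrategy, game: Game,
                      tol: float = DEFAULT_TOL) -> ValidationReport:
    """Report-style check of shape, range and row-stochasticity."""
    failures: list[str] = []
    n = strategy.player
    if not 0 <= n < game.n_players:
        return ValidationReport(False, [f"player index {n} out of range"])
    m_n, b = game.action_counts[n], len(game.signals)
    table = strategy.table
    if table.shape != (m_n, m_n, b):
        return ValidationReport(
            False, [f"table shape {table.shape} != ({m_n}, {m_n}, {b})"])
    exact = is_exact(table)
    for prev in range(m_n):
        for tau in range(b):
            col = table[:, prev, tau]
            total = sum(col) if exact else float(np.sum(col))
            ok = (total == 1) if exact else abs(total - 1.0) <= tol
            if not ok:
                failures.append(
                    f"probabilities for (prev={prev + 1}, tau={tau}) sum to {total}")
            for a in range(m_n):
                x = col[a]
                in_range = (0 <= x <= 1) if exact else -tol <= x <= 1 + tol
                if not in_range:
                    failures.append(
                        f"entry That({a + 1}|{prev + 1}, tau={tau}) = {x} outside [0, 1]")
    return ValidationReport(not failures, failures)


def _require_valid(strategy: MemoryOneStrategy, game: Game) -> None:
    report = validate_strategy(strategy, game)
    if not report.ok:
        raise InvariantError("invalid strategy: " + "; ".join(report.failures[:3]))


# ---------------------------------------------------------------------------
# marginals and Press-Dyson matrices

def marginal_transition(strategy: MemoryOneStrategy, game: Game) -> MarginalTransition:
    """W-average of the strategy table: ``T_n(a | sigma')``."""
    _require_valid(strategy, game)
    n = strategy.player
    m_n, m, b = game.action_counts[n], game.n_states, len(game.signals)
    exact = is_exact(strategy.table) and is_exact(game.signal_kernel)
    table = strategy.table if exact else float_array(strategy.table)
    kernel = game.signal_kernel if exact else float_array(game.signal_kernel)
    out = zeros_exact((m_n, m)) if exact else np.zeros((m_n, m))
    for j in range(m):
        prev = index_to_state(j, game)[n] - 1
        for a in range(m_n):
            acc = Fraction(0) if exact else 0.0
            for t in range(b):
                w = kernel[t, j]
                if w:
                    acc += w * table[a, prev, t]
            out[a, j] = acc
    return MarginalTransition(player=n, matrix=out)


def press_dyson(strategy: MemoryOneStrategy, game: Game) -> PressDysonMatrix:
    """Strategy vectors: marginal transition minus the Repeat indicator."""
    marginal = marginal_transition(strategy, game)
    n = strategy.player
    m_n, m = game.action_counts[n], game.n_states
    exact = is_exact(marginal.matrix)
    out = zeros_exact((m, m_n)) if exact else np.zeros((m, m_n))
    for j in range(m):
        prev = index_to_state(j, game)[n] - 1
        for a in range(m_n):
            delta = 1 if a == prev else 0
            out[j, a] = marginal.matrix[a, j] - delta
    if exact:
        has_zero = any(out[j, a] == 0 for j in range(m) for a in range(m_n))
    else:
        has_zero = bool(np.any(np.abs(out) <= DEFAULT_TOL))
    return PressDysonMatrix(player=n, matrix=out, has_zero_elements=has_zero)


# ---------------------------------------------------------------------------
# constructors

def strategy_from_marginal(game: Game, player: int,
                           marginal: np.ndarray) -> MemoryOneStrategy:
    """Lift a target marginal to a strategy table under perfect monitoring.

    ``marginal`` is ``(M_n, M)`` column-stochastic.  With perfect
    monitoring the signal determines the full previous state, so
    ``That(a | prev, tau) = marginal[a, tau]`` realizes it exactly.
    """
    if not game.perfect_monitoring:
        raise InvariantError(
            "strategy_from_marginal requires perfect monitoring; "
            "use realize_marginal for general kernels")
    m_n, m = game.action_counts[player], game.n_states
    marginal = np.asarray(marginal)
    if marginal.shape != (m_n, m):
        raise InvariantError(f"marginal must be shape ({m_n}, {m})")
    exact = is_exact(marginal)
    table = zeros_exact((m_n, m_n, m)) if exact else np.zeros((m_n, m_n, m))
    for tau in range(m):
        for prev in range(m_n):
            table[:, prev, tau] = marginal[:, tau]
    return MemoryOneStrategy(player=player, table=table)


def repeat_strategy(game: Game, player: int) -> MemoryOneStrategy:
    """Repeat the previous own action with probability one."""
    m_n, b = game.action_counts[player], len(game.signals)
    table = zeros_exact((m_n, m_n, b))
    for prev in range(m_n):
        table[prev, prev, :] = Fraction(1)
    return MemoryOneStrategy(player=player, table=table)


def uniform_strategy(game: Game, player: int) -> MemoryOneStrategy:
    """Play every action with equal probability."""
    m_n, b = game.action_counts[player], len(game.signals)
    table = zeros_exact((m_n, m_n, b))
    table[...] = Fraction(1, m_n)
    return MemoryOneStrategy(player=player, table=table)


def tit_for_tat(game: Game, player: int) -> MemoryOneStrategy:
    """Copy the co-player's previous action (2-player, perfect monitoring)."""
    if game.n_players != 2 or not game.perfect_monitoring:
        raise InvariantError("tit_for_tat needs a 2-player perfect-monitoring game")
    other = 1 - player
    if game.action_counts[player] != game.action_counts[other]:
        raise InvariantError("tit_for_tat needs matching action counts")
    m_n = game.action_counts[player]
    states = all_states(game)
    table = zeros_exact((m_n, m_n, game.n_states))
    for tau, state in enumerate(states):
        copy = state[other] - 1
        table[copy, :, tau] = Fraction(1)
    return MemoryOneStrategy(player=player, table=table)


def random_strategy(game: Game, player: int, rng: np.random.Generator,
                    denominator: int = 12, min_weight: int = 0) -> MemoryOneStrategy:
    """Seeded random strategy with rational entries.

    Each probability column is drawn as integer weights in
    ``[min_weight, denominator]`` normalized to sum 1.  ``min_weight >= 1``
    bounds every entry away from 0 and 1, which makes every Press-Dyson
    entry nonzero (the hypothesis of the independence criterion).
    """
    m_n, b = game.action_counts[player], len(game.signals)
    table = zeros_exact((m_n, m_n, b))
    for prev in range(m_n):
        for tau in range(b):
            weights = [0] * m_n
            while sum(weights) == 0:
                weights = [int(rng.integers(min_weight, denominator + 1))
                           for _ in range(m_n)]
            total = sum(weights)
            for a in range(m_n):
                table[a, prev, tau] = Fraction(weights[a], total)
    return MemoryOneStrategy(player=player, table=table)


def named_strategy(name: str, game: Game, player: int) -> MemoryOneStrategy:
    """Shorthand dispatcher: 'repeat', 'tit_for_tat' or 'uniform'."""
    builders = {"repeat": repeat_strategy, "uniform": uniform_strategy,
                "tit_for_tat": tit_for_tat}
    if name not in builders:
        raise SchemaError(f"unknown strategy shorthand {name!r}")
    return builders[name](game, player)


# ---------------------------------------------------------------------------
# realizability of a target marginal under a given signal kernel

def realize_marginal(target: np.ndarray, game: Game, player: int,
                     tol: float = 1e-9) -> RealizeResult:
    """Find a strategy whose W-marginal equals ``target``, if one exists.

    Feasibility is a linear program over the table entries with the
    marginal equalities and stochasticity constraints.  On success, an
    exact rational table is recovered by projecting the LP point onto the
    exact affine solution set of the equalities; falls back to a
    tolerance-verified float table when the target is attainable only on
    the boundary of the probability box.
    """
    m_n, m, b = game.action_counts[player], game.n_states, len(game.signals)
    target = np.asarray(target)
    if target.shape != (m_n, m):
        raise InvariantError(f"target must be shape ({m_n}, {m})")
    exact_in = is_exact(target) and is_exact(game.signal_kernel)

    n_vars = m_n * m_n * b

    def var(a: int, prev: int, tau: int) -> int:
        return (a * m_n + prev) * b + tau

    # equality system rows: marginal matching + stochasticity
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    kernel = game.signal_kernel if exact_in else exact_array(game.signal_kernel)
    target_e = target if exact_in else exact_array(target)
    for j in range(m):
        prev = index_to_state(j, game)[player] - 1
        for a in range(m_n):
            row = [Fraction(0)] * n_vars
            for tau in range(b):
                if kernel[tau, j]:
                    row[var(a, prev, tau)] += kernel[tau, j]
            rows.append(row)
            rhs.append(frac(target_e[a, j]))
    for prev in range(m_n):
        for tau in range(b):
            row = [Fraction(0)] * n_vars
            for a in range(m_n):
                row[var(a, prev, tau)] = Fraction(1)
            rows.append(row)
            rhs.append(Fraction(1))

    a_eq = exact_array(rows)
    b_eq = exact_array(rhs)

    # max-margin LP: maximize the distance of all entries from {0, 1}
    a_eq_f = float_array(a_eq)
    b_eq_f = float_array(b_eq)
    c = np.zeros(n_vars + 1)
    c[-1] = -1.0  # maximize margin
    a_ub = np.zeros((2 * n_vars, n_vars + 1))
    b_ub = np.zeros(2 * n_vars)
    for i in range(n_vars):
        a_ub[2 * i, i] = -1.0
        a_ub[2 * i, -1] = 1.0          # m - x_i <= 0
        a_ub[2 * i + 1, i] = 1.0
        a_ub[2 * i + 1, -1] = 1.0      # x_i + m <= 1
        b_ub[2 * i + 1] = 1.0
    a_eq_lp = np.concatenate([a_eq_f, np.zeros((a_eq_f.shape[0], 1))], axis=1)
    bounds = [(0.0, 1.0)] * n_vars + [(None, 0.5)]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq_lp, b_eq=b_eq_f,
                  bounds=bounds, method="highs")
    if res.status == 2:
        return RealizeResult(False, None, "infeasible")
    if res.status != 0:
        return RealizeResult(False, None, f"lp_status_{res.status}")

    x_float = res.x[:n_vars]

    def to_table(vec) -> MemoryOneStrategy:
        exact = not isinstance(vec[0], float)
        table = zeros_exact((m_n, m_n, b)) if exact else np.zeros((m_n, m_n, b))
        for a in range(m_n):
            for prev in range(m_n):
                for tau in range(b):
                    table[a, prev, tau] = vec[var(a, prev, tau)]
        return MemoryOneStrategy(player=player, table=table)

    # exact recovery: project the LP point onto the exact affine set
    particular = solve_linear(a_eq, b_eq)
    if particular is not None:
        basis = nullspace(a_eq)
        if basis.shape[1] == 0:
            candidate = particular
        else:
            basis_f = float_array(basis)
            t, *_ = np.linalg.lstsq(basis_f, x_float - float_array(particular),
                                    rcond=None)
            t_exact = exact_array(t)
            candidate = particular + basis.dot(t_exact)
        if all(0 <= v <= 1 for v in candidate):
            return RealizeResult(True, to_table(list(candidate)),
                                 "feasible_exact", exact=True)
    # boundary-tight case: return the float solution, verified within tol
    x_clip = np.clip(x_float, 0.0, 1.0)
    if np.max(np.abs(a_eq_f @ x_clip - b_eq_f)) <= 10 * tol:
        return RealizeResult(True, to_table(list(x_clip)),
                             "feasible_float", exact=False)
    return RealizeResult(False, None, "numerically_indeterminate")
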