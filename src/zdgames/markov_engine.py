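"""The induced joint-action Markov chain and its stationary structure.

The transition matrix is stored orientation ``(to, from)`` so the chain
evolves by left multiplication ``P(t+1) = T P(t)``.  Reducible chains are
first decomposed into recurrent classes (terminal strongly connected
components of the support graph); one stationary distribution is solved
exactly per class, and the full stationary set is their convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np

from ._numeric import DEFAULT_TOL, float_array, is_exact, zeros_exact
from .exact_linalg import nullspace
from .game_model import Game, InvariantError, index_to_state, payoff_matrix
from .strategy_model import MemoryOneStrategy, PressDysonMatrix

__all__ = [
    "TransitionMatrix",
    "StationaryAnalysis",
    "SimulationResult",
    "transition_matrix",
    "stationary_distributions",
    "average_payoffs",
    "verify_akin",
    "simulate_play",
]


@dataclass
class TransitionMatrix:
    """``(M, M)`` column-stochastic matrix, entry ``(to, from)``."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        t = self.matrix
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise InvariantError("transition matrix must be square")
        exact = is_exact(t)
        for j in range(t.shape[1]):
            total = sum(t[:, j]) if exact else float(np.sum(t[:, j]))
            ok = total == 1 if exact else abs(total - 1.0) <= DEFAULT_TOL
            if not ok:
                raise InvariantError(f"column {j} sums to {total}, not 1")


@dataclass
class StationaryAnalysis:
    """Recurrent classes with one stationary distribution each."""

    recurrent_classes: list[list[int]]
    distributions: list[np.ndarray]  # aligned with recurrent_classes, length M
    irreducible: bool


@dataclass
class SimulationResult:
    frequencies: np.ndarray     # empirical state distribution, length M
    payoffs: np.ndarray         # (e_1, ..., e_N) time averages
    visits: np.ndarray          # raw visit counts
    horizon: int


def transition_matrix(game: Game,
                      strategies: list[MemoryOneStrategy]) -> TransitionMatrix:
    """Full chain: signal-average of the product of per-player tables."""
    if len(strategies) != game.n_players:
        raise InvariantError(
            f"need one strategy per player ({game.n_players}), got {len(strategies)}")
    players = sorted(s.player for s in strategies)
    if players != list(range(game.n_players)):
        raise InvariantError(f"strategies cover players {players}, "
                             f"expected 0..{game.n_players - 1}")
    by_player = {s.player: s for s in strategies}
    m, b = game.n_states, len(game.signals)
    exact = game.exact and all(is_exact(s.table) for s in strategies)
    kernel = game.signal_kernel
    out = zeros_exact((m, m)) if exact else np.zeros((m, m))
    states = [index_to_state(i, game) for i in range(m)]
    for j in range(m):
        prev = states[j]
        for tau in range(b):
            w = kernel[tau, j]
            if not w:
                continue
            for i in range(m):
                nxt = states[i]
                prob = w
                for n in range(game.n_players):
                    prob = prob * by_player[n].table[nxt[n] - 1, prev[n] - 1, tau]
                    if not prob:
                        break
                if prob:
                    out[i, j] += prob
    return TransitionMatrix(matrix=out)


def stationary_distributions(t: TransitionMatrix,
                             tol: float = DEFAULT_TOL) -> StationaryAnalysis:
    """Per-recurrent-class stationary distributions of the chain.

    Recurrent classes are the terminal strongly connected components of
    the support digraph; within a class, the stationary vector is the
    normalized null space of ``T_C - I`` (exact in rational mode).
    """
    mat = t.matrix
    m = mat.shape[0]
    exact = is_exact(mat)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(m))
    threshold = 0 if exact else tol
    for j in range(m):
        for i in range(m):
            entry = mat[i, j]
            if (entry != 0) if exact else abs(entry) > threshold:
                graph.add_edge(j, i)
    condensation = nx.condensation(graph)
    classes = []
    for scc_id in condensation.nodes:
        if condensation.out_degree(scc_id) == 0:  # terminal SCC = recurrent
            classes.append(sorted(condensation.nodes[scc_id]["members"]))
    classes.sort()
    distributions = []
    for members in classes:
        sub = mat[np.ix_(members, members)]
        k = len(members)
        eye_minus = sub.copy()
        for i in range(k):
            eye_minus[i, i] = eye_minus[i, i] - 1
        basis = nullspace(eye_minus, tol)
        if basis.shape[1] != 1:
            raise InvariantError(
                f"recurrent class {members} has null-space dimension "
                f"{basis.shape[1]}, expected 1")
        vec = basis[:, 0]
        total = sum(vec) if exact else float(np.sum(vec))
        vec = np.array([v / total for v in vec],
                       dtype=object if exact else float)
        full = zeros_exact((m,)) if exact else np.zeros(m)
        for local, idx in enumerate(members):
            full[idx] = vec[local]
        distributions.append(full)
    return StationaryAnalysis(recurrent_classes=classes,
                              distributions=distributions,
                              irreducible=len(classes) == 1 and
                              len(classes[0]) == m)


def average_payoffs(rho: np.ndarray, game: Game) -> np.ndarray:
    """Expected payoff vector ``e = (1, e_1, ..., e_N) = S^T rho``."""
    rho = np.asarray(rho)
    if rho.shape[0] != game.n_states:
        raise InvariantError("rho length must equal the number of states")
    exact = is_exact(rho)
    total = sum(rho) if exact else float(np.sum(rho))
    ok = total == 1 if exact else abs(total - 1.0) <= DEFAULT_TOL
    neg = any(x < 0 for x in rho) if exact else bool(np.any(rho < -DEFAULT_TOL))
    if not ok or neg:
        raise InvariantError("rho is not a probability distribution")
    s = payoff_matrix(game).matrix
    if exact != is_exact(s):
        s = s if exact else float_array(s)
        rho = rho if not exact else float_array(rho)
    return s.T.dot(rho)


def verify_akin(rho: np.ndarray, pd: PressDysonMatrix,
                transition: TransitionMatrix | None = None,
                tol: float = DEFAULT_TOL):
    """Max absolute ``rho . Ttilde_n(a)`` over actions; 0 for stationary rho.

    If ``transition`` is supplied and ``rho`` is not stationary for it,
    raises with the stationarity residual instead of a misleading answer.
    """
    rho = np.asarray(rho)
    if transition is not None:
        exact = is_exact(transition.matrix) and is_exact(rho)
        diff = transition.matrix.dot(rho) - rho
        residual = (max(abs(x) for x in diff) if exact
                    else float(np.max(np.abs(float_array(diff)))))
        stationary = residual == 0 if exact else residual <= tol
        if not stationary:
            raise InvariantError(
                f"rho is not stationary: max |T rho - rho| = {residual}")
    products = pd.matrix.T.dot(rho)
    if is_exact(pd.matrix) and is_exact(rho):
        return max(abs(x) for x in products)
    return float(np.max(np.abs(float_array(products))))


def simulate_play(game: Game, strategies: list[MemoryOneStrategy],
                  horizon: int, seed: int,
                  initial_state: tuple[int, ...] | int = 0) -> SimulationResult:
    """Monte-Carlo roll-out of the induced chain (reproducible by seed)."""
    if horizon < 1:
        raise InvariantError("horizon must be at least 1")
    from .game_model import state_index
    if isinstance(initial_state, tuple):
        state = state_index(initial_state, game)
    else:
        state = int(initial_state)
        if not 0 <= state < game.n_states:
            raise InvariantError(f"initial state {state} out of range")
    t = float_array(transition_matrix(game, strategies).matrix)
    cumulative = np.cumsum(t, axis=0)
    rng = np.random.default_rng(seed)
    draws = rng.random(horizon)
    visits = np.zeros(game.n_states, dtype=np.int64)
    for step in range(horizon):
        state = int(np.searchsorted(cumulative[:, state], draws[step]))
        visits[state] += 1
    freq = visits / horizon
    payoffs = float_array(game.payoffs).dot(freq)
    return SimulationResult(frequencies=freq, payoffs=payoffs,
                            visits=visits, horizon=horizon)
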