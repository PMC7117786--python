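"""Repeated-game instances: players, actions, payoffs, public signals.

A :class:`Game` bundles the joint-action space, one payoff vector per
player over that space, and the public-signal structure ``W(tau | sigma')``.
States are joint actions ``sigma = (sigma_1, ..., sigma_N)`` with
``sigma_n in {1, ..., M_n}`` (1-based in user-facing I/O), flattened
lexicographically with player 1 most significant and player N fastest
varying.  All fixture payoffs are exact rationals.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from ._numeric import (DEFAULT_TOL, exact_array, fmt_matrix, frac, is_exact,
                       zeros_exact)
from .exact_linalg import matrix_rank

__all__ = [
    "Game",
    "PayoffMatrixS",
    "SchemaError",
    "InvariantError",
    "DegenerateGameWarning",
    "state_index",
    "index_to_state",
    "all_states",
    "payoff_matrix",
    "build_perfect_monitoring_game",
    "fixture_game",
    "iterated_prisoners_dilemma",
    "rock_paper_scissors",
    "two_relation_game",
    "winner_signal_game",
    "random_game",
    "load_game",
    "save_game",
]

FIXTURE_NAMES = (
    "iterated_prisoners_dilemma",
    "rock_paper_scissors",
    "two_relation_game",
    "winner_signal_game",
    "random_game",
)


class SchemaError(ValueError):
    """A configuration file violates the documented schema."""


class InvariantError(ValueError):
    """A structural invariant (stochasticity, dimensions) is violated."""


class DegenerateGameWarning(UserWarning):
    """Fixture parameters produce a degenerate (rank-deficient) game."""


@dataclass
class Game:
    """An N-player repeated game with public monitoring.

    Attributes
    ----------
    action_counts:
        ``(M_1, ..., M_N)``, each at least 2.
    payoffs:
        ``(N, M)`` array, row ``n`` is the payoff vector ``s_n`` over the
        flattened joint-action space (``M = prod(M_n)``).
    signals:
        ordered tuple of hashable public-signal labels ``B``.
    signal_kernel:
        ``(|B|, M)`` column-stochastic table ``W(tau | sigma')``.
    """

    action_counts: tuple[int, ...]
    payoffs: np.ndarray
    signals: tuple
    signal_kernel: np.ndarray
    tol: float = field(default=DEFAULT_TOL, repr=False)

    def __post_init__(self) -> None:
        self.action_counts = tuple(int(m) for m in self.action_counts)
        if len(self.action_counts) < 1:
            raise InvariantError("a game needs at least one player")
        for n, m in enumerate(self.action_counts):
            if m < 2:
                raise InvariantError(f"player {n + 1} needs at least 2 actions, got {m}")
        self.payoffs = np.atleast_2d(np.asarray(self.payoffs))
        self.signal_kernel = np.atleast_2d(np.asarray(self.signal_kernel))
        self.signals = tuple(self.signals)
        if self.payoffs.shape != (self.n_players, self.n_states):
            raise InvariantError(
                f"payoffs must be shape ({self.n_players}, {self.n_states}), "
                f"got {self.payoffs.shape}")
        if self.signal_kernel.shape != (len(self.signals), self.n_states):
            raise InvariantError(
                f"signal kernel must be shape ({len(self.signals)}, {self.n_states}), "
                f"got {self.signal_kernel.shape}")
        self._check_kernel_stochastic()

    def _check_kernel_stochastic(self) -> None:
        exact = is_exact(self.signal_kernel)
        for j in range(self.n_states):
            col = self.signal_kernel[:, j]
            total = sum(col) if exact else float(np.sum(col))
            ok_sum = (total == 1) if exact else abs(total - 1.0) <= self.tol
            if not ok_sum:
                raise InvariantError(
                    f"signal kernel column for state {j} sums to {total}, not 1")
            for w in col:
                low = (w >= 0) if exact else w >= -self.tol
                high = (w <= 1) if exact else w <= 1 + self.tol
                if not (low and high):
                    raise InvariantError(
                        f"signal kernel entry {w} for state {j} outside [0, 1]")

    # -- derived sizes ----------------------------------------------------
    @property
    def n_players(self) -> int:
        return len(self.action_counts)

    @property
    def n_states(self) -> int:
        out = 1
        for m in self.action_counts:
            out *= m
        return out

    @property
    def exact(self) -> bool:
        return is_exact(self.payoffs)

    @property
    def perfect_monitoring(self) -> bool:
        """True iff B = Sigma and W is the indicator kernel."""
        if len(self.signals) != self.n_states:
            return False
        if self.signals != tuple(all_states(self)):
            return False
        exact = is_exact(self.signal_kernel)
        for t in range(self.n_states):
            for j in range(self.n_states):
                expected = 1 if t == j else 0
                w = self.signal_kernel[t, j]
                if exact:
                    if w != expected:
                        return False
                elif abs(float(w) - expected) > self.tol:
                    return False
        return True

    def payoff_vector(self, player: int) -> np.ndarray:
        return self.payoffs[player]


# ---------------------------------------------------------------------------
# state indexing: player 1 most significant, player N fastest varying

def state_index(sigma: tuple[int, ...], game: Game) -> int:
    """Flat 0-based index of a 1-based joint action tuple."""
    if len(sigma) != game.n_players:
        raise InvariantError(
            f"state tuple has {len(sigma)} entries for {game.n_players} players")
    idx = 0
    for n, (a, m) in enumerate(zip(sigma, game.action_counts)):
        if not 1 <= a <= m:
            raise InvariantError(
                f"action {a} of player {n + 1} outside 1..{m}")
        idx = idx * m + (a - 1)
    return idx


def index_to_state(index: int, game: Game) -> tuple[int, ...]:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < game.n_states:
        raise InvariantError(f"state index {index} outside 0..{game.n_states - 1}")
    out = []
    for m in reversed(game.action_counts):
        out.append(index % m + 1)
        index //= m
    return tuple(reversed(out))


def all_states(game: Game) -> list[tuple[int, ...]]:
    """All joint-action tuples in flat-index order."""
    return [tuple(a + 1 for a in t)
            for t in itertools.product(*(range(m) for m in game.action_counts))]


# ---------------------------------------------------------------------------
# the payoff-state matrix S = (1_M, s_1, ..., s_N)

@dataclass
class PayoffMatrixS:
    """The M x (N+1) matrix with columns ``(1_M, s_1, ..., s_N)``."""

    matrix: np.ndarray
    rank: int


def payoff_matrix(game: Game, tol: float = DEFAULT_TOL) -> PayoffMatrixS:
    m = game.n_states
    if game.exact:
        ones = zeros_exact((m, 1))
        ones[:, 0] = Fraction(1)
    else:
        ones = np.ones((m, 1))
    matrix = np.concatenate([ones, game.payoffs.T], axis=1)
    return PayoffMatrixS(matrix=matrix, rank=matrix_rank(matrix, tol))


# ---------------------------------------------------------------------------
# constructors and fixtures

def _perfect_kernel(n_states: int) -> np.ndarray:
    kernel = zeros_exact((n_states, n_states))
    for i in range(n_states):
        kernel[i, i] = Fraction(1)
    return kernel


def build_perfect_monitoring_game(action_counts, payoffs) -> Game:
    """Game whose public signal is the joint action itself."""
    action_counts = tuple(int(m) for m in action_counts)
    n_states = 1
    for m in action_counts:
        n_states *= m
    payoffs = exact_array(payoffs)
    if payoffs.ndim != 2 or payoffs.shape[1] != n_states:
        raise InvariantError(
            f"each payoff vector must have {n_states} entries, got shape {payoffs.shape}")
    # signals are the states themselves, paired with the indicator kernel
    states = tuple(tuple(a + 1 for a in t)
                   for t in itertools.product(*(range(m) for m in action_counts)))
    return Game(action_counts=action_counts, payoffs=payoffs,
                signals=states, signal_kernel=_perfect_kernel(n_states))


def iterated_prisoners_dilemma(R=3, S=0, T=5, P=1) -> Game:
    """2-player 2-action game, s_1 = (R,S,T,P), s_2 = (R,T,S,P)."""
    R, S, T, P = (frac(x) for x in (R, S, T, P))
    return build_perfect_monitoring_game((2, 2), [[R, S, T, P], [R, T, S, P]])


def rock_paper_scissors() -> Game:
    """Two-player three-action symmetric zero-sum game (win 1 / lose -1)."""
    beats = {(1, 3), (2, 1), (3, 2)}  # rock>scissors, paper>rock, scissors>paper
    s1 = []
    for a in (1, 2, 3):
        for b in (1, 2, 3):
            s1.append(Fraction(1) if (a, b) in beats
                      else Fraction(-1) if (b, a) in beats else Fraction(0))
    s2 = [-x for x in s1]
    return build_perfect_monitoring_game((3, 3), [s1, s2])


def two_relation_game(r1, r2) -> Game:
    """The 3x3 symmetric game whose only nonzero payoffs sit at (1,2), (2,1).

    ``s_1 = (0, r1, 0, r2, 0, 0, 0, 0, 0)`` and ``s_2`` with r1, r2 swapped.
    ``1_9, s_1, s_2`` are linearly independent iff ``r1 != r2`` and
    ``r1 != -r2``; degenerate parameters trigger a warning.
    """
    r1, r2 = frac(r1), frac(r2)
    if r1 == r2 or r1 == -r2:
        warnings.warn(
            f"two_relation_game(r1={r1}, r2={r2}) is degenerate: "
            "1_9, s_1, s_2 are linearly dependent", DegenerateGameWarning,
            stacklevel=2)
    zero = Fraction(0)
    s1 = [zero, r1, zero, r2, zero, zero, zero, zero, zero]
    s2 = [zero, r2, zero, r1, zero, zero, zero, zero, zero]
    return build_perfect_monitoring_game((3, 3), [s1, s2])


def winner_signal_game(n_actions: int = 3, value=3) -> Game:
    """Two-player bidding game whose public signal is only the winner.

    Actions are bids ``1..n_actions``; the higher bid wins and earns
    ``value - bid``, the loser earns 0, ties split the surplus.  Signals
    are ``{"p1_wins", "p2_wins", "tie"}``.  This is an artifact-defined
    imperfect-monitoring fixture.
    """
    value = frac(value)
    m = n_actions * n_actions
    s1, s2, winners = [], [], []
    for a in range(1, n_actions + 1):
        for b in range(1, n_actions + 1):
            if a > b:
                s1.append(value - a); s2.append(Fraction(0)); winners.append("p1_wins")
            elif b > a:
                s1.append(Fraction(0)); s2.append(value - b); winners.append("p2_wins")
            else:
                s1.append((value - a) / 2); s2.append((value - b) / 2)
                winners.append("tie")
    signals = ("p1_wins", "p2_wins", "tie")
    kernel = zeros_exact((3, m))
    for j, w in enumerate(winners):
        kernel[signals.index(w), j] = Fraction(1)
    return Game(action_counts=(n_actions, n_actions),
                payoffs=exact_array([s1, s2]),
                signals=signals, signal_kernel=kernel)


def random_game(seed: int, action_counts=(2, 2), payoff_range=(-4, 4),
                denominator: int = 4) -> Game:
    """Seeded random perfect-monitoring game with rational payoffs."""
    rng = np.random.default_rng(seed)
    action_counts = tuple(int(m) for m in action_counts)
    n_states = 1
    for m in action_counts:
        n_states *= m
    lo, hi = payoff_range
    numerators = rng.integers(lo * denominator, hi * denominator + 1,
                              size=(len(action_counts), n_states))
    payoffs = [[Fraction(int(x), denominator) for x in row] for row in numerators]
    return build_perfect_monitoring_game(action_counts, payoffs)


def fixture_game(name: str, **params) -> Game:
    """Named fixture dispatcher; see the individual constructors."""
    builders = {
        "iterated_prisoners_dilemma": iterated_prisoners_dilemma,
        "rock_paper_scissors": rock_paper_scissors,
        "two_relation_game": two_relation_game,
        "winner_signal_game": winner_signal_game,
        "random_game": random_game,
    }
    if name not in builders:
        raise SchemaError(
            f"unknown fixture {name!r}; choose one of {sorted(builders)}")
    return builders[name](**params)


# ---------------------------------------------------------------------------
# structured-text I/O

def save_game(game: Game, path) -> None:
    """Serialize a game to JSON (rationals as 'p/q' strings)."""
    perfect = game.perfect_monitoring
    doc = {
        "n_players": game.n_players,
        "action_counts": list(game.action_counts),
        "payoffs": fmt_matrix(game.payoffs),
        "signals": "perfect" if perfect else [str(s) for s in game.signals],
        "W": "perfect" if perfect else fmt_matrix(game.signal_kernel),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_game(path) -> Game:
    """Load a game saved by :func:`save_game` (exact round trip)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    for key in ("n_players", "action_counts", "payoffs", "W"):
        if key not in doc:
            raise SchemaError(f"missing required field {key!r}")
    action_counts = tuple(int(m) for m in doc["action_counts"])
    if int(doc["n_players"]) != len(action_counts):
        raise SchemaError("n_players does not match len(action_counts)")
    try:
        payoffs = exact_array(doc["payoffs"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"bad payoffs field: {exc}") from exc
    if doc["W"] == "perfect":
        return build_perfect_monitoring_game(action_counts, payoffs)
    signals = tuple(doc.get("signals", range(len(doc["W"]))))
    try:
        kernel = exact_array(doc["W"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"bad W field: {exc}") from exc
    return Game(action_counts=action_counts, payoffs=payoffs,
                signals=signals, signal_kernel=kernel)
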