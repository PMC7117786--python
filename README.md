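# zdgames

Linear-algebraic analysis of **zero-determinant (ZD) strategies** in
N-player, multi-action repeated games with public monitoring.

A memory-one strategy is zero-determinant when the column space of its
Press–Dyson matrix (marginal transition minus the "Repeat" indicator)
meets the span of `(1_M, s_1, …, s_N)` nontrivially. Each intersection
direction unilaterally enforces one linear relation
`α_0 + Σ_n α_n e_n = 0` on the players' long-run average payoffs. This
package detects such strategies, extracts and solves the enforced
relations, checks consistency (Rouché–Capelli) and independence of ZD
sets, searches games for ZD existence, and verifies every claim against
the stationary distributions of the induced Markov chain — in exact
rational arithmetic by default.

## Modules

| module | contents |
|---|---|
| `zdgames.game_model` | `Game` (actions, payoffs, signal kernel `W`), state indexing, fixtures (`iterated_prisoners_dilemma`, `rock_paper_scissors`, `two_relation_game`, `winner_signal_game`, `random_game`), JSON I/O |
| `zdgames.strategy_model` | memory-one strategy tables, marginal transitions, Press–Dyson matrices, realizability of target marginals under a signal kernel (LP) |
| `zdgames.exact_linalg` | exact rational column spaces, subspace intersection, membership, Rouché–Capelli consistency (float fallback with SVD tolerances) |
| `zdgames.zd_core` | ZD detection with certificates, enforced relations, consistency and independence of ZD sets, exact ZD-existence search (perfect monitoring) plus a labelled heuristic for imperfect monitoring, game symmetry, the simultaneous two-relation construction |
| `zdgames.markov_engine` | induced chain, recurrent classes and exact stationary distributions, average payoffs, the stationary-average identity check, seeded Monte-Carlo simulation |
| `zdgames.cli` | `zdgames` command-line tool with JSON reports |

## Quick start

```python
from fractions import Fraction as F
import zdgames as z

ipd = z.iterated_prisoners_dilemma()          # payoffs (3,0,5,1)
tft = z.tit_for_tat(ipd, 0)
report = z.compute_zd_subspace(tft, ipd)      # dim V_1 = 1
z.enforced_relations(report, ipd)             # alpha = (0, 1, -1): e_1 = e_2

# one player enforcing e_1 = e_2 = 0 simultaneously in a 3x3 game
dc = z.build_double_control(1, 2, F(1,2), F(1,4), F(1,4), F(1,2))
dc.dim                                        # 2

z.zd_existence(z.rock_paper_scissors(), 0).exists   # False
```

## CLI

```bash
zdgames detect-zd --fixture iterated_prisoners_dilemma --strategy 1:tit_for_tat
zdgames exists-zd --fixture rock_paper_scissors --player 1
zdgames stationary --fixture two_relation_game --params '{"r1":1,"r2":2}' \
    --strategy 1:eq14.json --strategy 2:uniform
zdgames double-control --params '{"r1":1,"r2":2,"p":"1/2","q":"1/4","p_prime":"1/4","q_prime":"1/2"}'
```

Strategies are given as `PLAYER:shorthand` (`repeat`, `uniform`,
`tit_for_tat`) or `PLAYER:file.json` (signal-major nested table).
Reports are JSON (rationals as `"p/q"`); `--out FILE` also writes a
plain-text summary next to it. Exit codes: 0 success (including
negative findings such as `exists=false`), 1 schema error, 2 invariant
violation.

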