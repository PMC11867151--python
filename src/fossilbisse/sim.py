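"""Event-driven forward simulation of BiSSE trees with binary traits.

A single lineage starts at time 0 in state 0 and the process runs forward:
each lineage in state i waits an exponential time with total rate
lambda_i + mu_i + q_i (q_0 = q01, q_1 = q10), the event type being chosen
proportionally to the rates. The simulation stops at the instant the
speciation event creating the target number of coexisting lineages occurs;
that instant defines the present. Replicates that go fully extinct before
reaching the target are discarded and resimulated.

Neutral traits (symmetric two-state Markov chains unlinked to the rates)
are laid down on the finished tree afterwards, root state 0, states
inherited at speciation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .params import BisseParameters, NeutralTraitSpec

__all__ = [
    "CompleteTree",
    "RejectionBudgetExceeded",
    "simulate_complete_tree",
    "simulate_neutral_trait",
    "FOCAL_TRAIT",
]

FOCAL_TRAIT = "focal"


class RejectionBudgetExceeded(RuntimeError):
    """Raised when too many replicates were discarded before acceptance."""


Trajectory = list  # list[tuple[float, int]]: (time, new state), first entry at birth


@dataclass
class CompleteTree:
    """The simulated truth: every lineage, extinct or extant.

    Lineage ``k`` is born at ``birth[k]`` from ``parent[k]`` (-1 for the
    root) and dies at ``death[k]`` (NaN while extant at the present,
    ``stop_time``). ``traits[name][k]`` is the right-continuous
    piecewise-constant trajectory of a trait on lineage ``k`` as a list of
    (time, state) change points starting at the lineage's birth.
    """

    parent: list[int]
    birth: list[float]
    death: list[float]  # NaN == extant at stop_time
    stop_time: float
    traits: dict[str, list[Trajectory]]
    n_discarded: int = 0

    @property
    def n_lineages(self) -> int:
        return len(self.parent)

    def is_extant(self, k: int) -> bool:
        return np.isnan(self.death[k])

    def end_time(self, k: int) -> float:
        d = self.death[k]
        return self.stop_time if np.isnan(d) else d

    def extant_lineages(self) -> list[int]:
        return [k for k in range(self.n_lineages) if self.is_extant(k)]

    @property
    def n_extant(self) -> int:
        return len(self.extant_lineages())

    def children(self, k: int) -> list[int]:
        return [c for c, p in enumerate(self.parent) if p == k]

    def branch_length(self, k: int) -> float:
        return self.end_time(k) - self.birth[k]

    def total_branch_length(self) -> float:
        return float(sum(self.branch_length(k) for k in range(self.n_lineages)))

    def state_at(self, trait: str, k: int, t: float) -> int:
        """Trait state of lineage ``k`` at absolute time ``t``."""
        traj = self.traits[trait][k]
        if not (self.birth[k] - 1e-12 <= t <= self.end_time(k) + 1e-12):
            raise ValueError(f"time {t} outside lifespan of lineage {k}")
        times = [tp for tp, _ in traj]
        idx = bisect.bisect_right(times, t) - 1
        return traj[max(idx, 0)][1]

    def tip_states(self, trait: str) -> dict[int, int]:
        """States of the extant lineages at the present."""
        return {k: self.state_at(trait, k, self.stop_time) for k in self.extant_lineages()}


def simulate_complete_tree(
    params: BisseParameters,
    n_extant_stop: int,
    rng: np.random.Generator,
    max_rejections: int = 10_000,
    root_state: int = 0,
) -> CompleteTree:
    """Simulate a BiSSE tree until ``n_extant_stop`` lineages coexist.

    The focal trait trajectory is generated jointly with the tree (it
    drives the rates). Fully extinct replicates are discarded internally;
    the number of discards is recorded on the returned tree. The study
    fixes ``root_state`` at 0; calibration runs may draw it.
    """
    if n_extant_stop < 2:
        raise ValueError("n_extant_stop must be >= 2")
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    lam, mu, q = params.lam, params.mu, params.q

    discarded = 0
    while discarded <= max_rejections:
        tree = _attempt(lam, mu, q, n_extant_stop, rng, root_state)
        if tree is not None:
            tree.n_discarded = discarded
            return tree
        discarded += 1
    raise RejectionBudgetExceeded(
        f"discarded {discarded} fully extinct replicates (params={params.as_dict()})"
    )


def _attempt(lam, mu, q, n_stop: int, rng: np.random.Generator,
             root_state: int = 0) -> CompleteTree | None:
    parent = [-1]
    birth = [0.0]
    death = [np.nan]
    focal: list[Trajectory] = [[(0.0, root_state)]]

    # alive lineages partitioned by current state for O(1) event draws
    alive = [[], []]  # state 0 ids, state 1 ids
    alive[root_state].append(0)
    total = (lam[0] + mu[0] + q[0], lam[1] + mu[1] + q[1])
    t = 0.0

    while True:
        n0, n1 = len(alive[0]), len(alive[1])
        rate = n0 * total[0] + n1 * total[1]
        if rate <= 0.0:
            # absorbing: no events can ever occur; the tree can never reach
            # n_stop, treat as a dead replicate
            return None
        t += rng.exponential(1.0 / rate)
        # choose state class, then lineage uniformly within it
        s = 0 if rng.random() * rate < n0 * total[0] else 1
        k = alive[s][rng.integers(len(alive[s]))]
        u = rng.random() * total[s]
        if u < lam[s]:
            # speciation: parent continues, child born in parent's state
            child = len(parent)
            parent.append(k)
            birth.append(t)
            death.append(np.nan)
            focal.append([(t, s)])
            alive[s].append(child)
            if n0 + n1 + 1 == n_stop:
                return CompleteTree(parent, birth, death, t, {FOCAL_TRAIT: focal})
        elif u < lam[s] + mu[s]:
            death[k] = t
            alive[s].remove(k)
            if not alive[0] and not alive[1]:
                return None
        else:
            alive[s].remove(k)
            alive[1 - s].append(k)
            focal[k].append((t, 1 - s))


def simulate_neutral_trait(
    tree: CompleteTree,
    spec: NeutralTraitSpec,
    rng: np.random.Generator,
    name: str | None = None,
) -> str:
    """Simulate a symmetric binary trait along an existing complete tree.

    The trait starts in state 0 at the root and is inherited at
    speciation; along every branch it flips at rate ``spec.q``. The tree's
    event times are untouched. Returns the name under which the trajectory
    was stored in ``tree.traits``.
    """
    name = name or spec.label
    trajs: list[Trajectory] = []
    for k in range(tree.n_lineages):
        p = tree.parent[k]
        t0 = tree.birth[k]
        if p < 0:
            state = 0
        else:
            # parent trajectory already simulated (parents precede children)
            traj_p = trajs[p]
            times = [tp for tp, _ in traj_p]
            state = traj_p[bisect.bisect_right(times, t0) - 1][1]
        traj: Trajectory = [(t0, state)]
        t_end = tree.end_time(k)
        t = t0
        while True:
            t += rng.exponential(1.0 / spec.q) if spec.q > 0 else np.inf
            if t >= t_end:
                break
            state = 1 - state
            traj.append((t, state))
        trajs.append(traj)
    tree.traits[name] = trajs
    return name
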