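"""Independent oracles used by the test suite.

These deliberately avoid the package's ODE/pruning machinery: the
single-type birth-death / fossilized-birth-death likelihood uses the
closed-form propagator (hyperbolic q-function), and the trait likelihood
uses matrix-exponential pruning. With state-independent diversification
rates the two multiply to the full state-dependent likelihood, which the
implementation must reproduce.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

from fossilbisse.fossilize import EXTANT, FOSSIL_TIP, SAMPLED_ANCESTOR, SampledTree


def _c1c2(lam: float, mu: float, psi: float, rho: float) -> tuple[float, float]:
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
    c2 = -(lam - mu - 2 * lam * rho - psi) / c1
    return c1, c2


def fbd_p0(t: float, lam: float, mu: float, psi: float, rho: float) -> float:
    """Probability a lineage of age t leaves no sampled material at all."""
    c1, c2 = _c1c2(lam, mu, psi, rho)
    e = math.exp(-c1 * t)
    return (lam + mu + psi + c1 * (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))) / (
        2 * lam
    )


def fbd_qfun(t: float, lam: float, mu: float, psi: float, rho: float) -> float:
    c1, c2 = _c1c2(lam, mu, psi, rho)
    e = math.exp(-c1 * t)
    return 4 * e / (e * (1 - c2) + (1 + c2)) ** 2


def single_type_loglik(
    tree: SampledTree, lam: float, mu: float, psi: float, rho: float = 1.0
) -> float:
    """Closed-form constant-rate BD/FBD log-likelihood of a fixed tree.

    Matches the pruning normalisation of the implementation with
    conditioning "none": extant tips contribute rho, fossil tips
    psi * p0(age), sampled ancestors psi, bifurcations lam, and each
    branch the propagator q(old) / q(young).
    """
    ll = 0.0
    for node in tree.postorder():
        if node.kind == EXTANT:
            ll += math.log(rho)
        elif node.kind == FOSSIL_TIP:
            ll += math.log(psi * fbd_p0(tree.age(node), lam, mu, psi, rho))
        elif node.kind == SAMPLED_ANCESTOR:
            ll += math.log(psi)
        else:
            ll += math.log(lam)
        length = tree.edge_length(node)
        if length > 0:
            a_young = tree.age(node)
            ll += math.log(
                fbd_qfun(a_young + length, lam, mu, psi, rho)
                / fbd_qfun(a_young, lam, mu, psi, rho)
            )
    return ll


def ctmc_states_loglik(
    tree: SampledTree, q01: float, q10: float, pi0: float, trait: str = "focal"
) -> float:
    """Two-state Markov-chain likelihood of the observed sample states.

    Felsenstein pruning with expm transition matrices; states are
    observed at tips and at sampled-ancestor nodes.
    """
    Q = np.array([[-q01, q01], [q10, -q10]])
    partial: dict[int, np.ndarray] = {}
    logsc = 0.0
    for node in tree.postorder():
        if not node.children:
            p = np.zeros(2)
            p[node.states[trait]] = 1.0
        else:
            p = np.ones(2)
            for c in node.children:
                msg = expm(Q * tree.edge_length(c)) @ partial[id(c)]
                p = p * msg
            if node.kind == SAMPLED_ANCESTOR:
                s = node.states[trait]
                mask = np.zeros(2)
                mask[s] = 1.0
                p = p * mask
        tot = p.sum()
        if tot <= 0:
            return -np.inf
        logsc += math.log(tot)
        partial[id(node)] = p / tot
    root = partial[id(tree.root)]
    return float(math.log(pi0 * root[0] + (1 - pi0) * root[1]) + logsc)


def yule_stop_time_sampler(
    lam: float, n_stop: int, rng: np.random.Generator, n_draws: int
) -> np.ndarray:
    """Independent sampler of the pure-birth time to reach n lineages.

    Sum of exponential waits with rates k * lam, k = 1..n-1; the oracle
    for the simulator's stopping rule.
    """
    ks = np.arange(1, n_stop)
    return np.sum(rng.exponential(1.0 / (ks * lam), size=(n_draws, len(ks))), axis=1)
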