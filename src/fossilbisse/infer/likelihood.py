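"""BiSSE and BiSSE+FBD log-likelihood by per-branch ODE pruning.

Along every branch the standard state-dependent extinction/observation
system is integrated backward in time (age increasing root-ward); for
state i (j = 1 - i):

    dEi/da = mu_i - (lambda_i + mu_i + psi_i + q_ij) Ei
             + lambda_i Ei^2 + q_ij Ej
    dDi/da = -(lambda_i + mu_i + psi_i + q_ij) Di
             + 2 lambda_i Ei Di + q_ij Dj

Ei is the probability that a lineage alive at age a leaves no sampled
material at all (neither extant descendants nor fossils); Di the density
of the observed subtree below the branch conditional on state i. Initial
conditions: extant tip in state s: Di = rho * delta(i, s), Ei = 1 - rho;
fossil tip of age t in state s: Di = psi_s * delta(i, s) * Ei(t) (the
lineage's unobserved continuation beyond its last fossil must leave no
samples); sampled ancestor in state s: Di <- psi_s * delta(i, s) * Di. An
internal bifurcation merges as Di <- lambda_i * Di(left) * Di(right); the
root mixes with weights (pi0, 1 - pi0).

Two integrator backends are provided: a fast adaptive Cash-Karp RK45
compiled with numba (default; the system is non-stiff at study rates) and
scipy's stiff-capable LSODA, used for cross-checks and as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from ..fossilize import EXTANT, FOSSIL_TIP, INTERNAL, SAMPLED_ANCESTOR, SampledTree
from ..params import BisseParameters
from ..sim import FOCAL_TRAIT

__all__ = ["LikelihoodState", "integrate_branch", "tree_loglikelihood", "flatten_tree"]

_CODE = {EXTANT: 0, FOSSIL_TIP: 1, SAMPLED_ANCESTOR: 2, INTERNAL: 3}


@dataclass
class LikelihoodState:
    """(E0, E1, D0, D1) at a point on a branch."""

    E0: float
    E1: float
    D0: float
    D1: float

    def __post_init__(self) -> None:
        for e in (self.E0, self.E1):
            if not -1e-9 <= e <= 1 + 1e-9:
                raise ValueError(f"E components must lie in [0, 1], got {e}")
        if self.D0 < 0 or self.D1 < 0:
            raise ValueError("D components must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.E0, self.E1, self.D0, self.D1])


# ---------------------------------------------------------------------------
# numba core
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _deriv(e0, e1, d0, d1, la0, la1, mu0, mu1, q01, q10, ps0, ps1):
    s0 = la0 + mu0 + ps0 + q01
    s1 = la1 + mu1 + ps1 + q10
    de0 = mu0 - s0 * e0 + la0 * e0 * e0 + q01 * e1
    de1 = mu1 - s1 * e1 + la1 * e1 * e1 + q10 * e0
    dd0 = -s0 * d0 + 2.0 * la0 * e0 * d0 + q01 * d1
    dd1 = -s1 * d1 + 2.0 * la1 * e1 * d1 + q10 * d0
    return de0, de1, dd0, dd1


@njit(cache=True)
def _integrate(e0, e1, d0, d1, T, la0, la1, mu0, mu1, q01, q10, ps0, ps1, rtol, atol):
    """Adaptive Cash-Karp RK4(5) over a segment of length T (age-forward)."""
    if T <= 0.0:
        return e0, e1, d0, d1, True
    t = 0.0
    # initial step: bounded by total rate scale
    scale = la0 + la1 + mu0 + mu1 + q01 + q10 + ps0 + ps1
    h = T if scale <= 0.0 else min(T, 0.1 / scale if scale > 0 else T)
    if h <= 0.0:
        h = T
    max_steps = 1_000_000
    for _ in range(max_steps):
        if t >= T:
            return e0, e1, d0, d1, True
        if t + h > T:
            h = T - t

        k1 = _deriv(e0, e1, d0, d1, la0, la1, mu0, mu1, q01, q10, ps0, ps1)
        y0 = (e0, e1, d0, d1)

        a = (
            y0[0] + h * 0.2 * k1[0],
            y0[1] + h * 0.2 * k1[1],
            y0[2] + h * 0.2 * k1[2],
            y0[3] + h * 0.2 * k1[3],
        )
        k2 = _deriv(a[0], a[1], a[2], a[3], la0, la1, mu0, mu1, q01, q10, ps0, ps1)
        a = (
            y0[0] + h * (0.075 * k1[0] + 0.225 * k2[0]),
            y0[1] + h * (0.075 * k1[1] + 0.225 * k2[1]),
            y0[2] + h * (0.075 * k1[2] + 0.225 * k2[2]),
            y0[3] + h * (0.075 * k1[3] + 0.225 * k2[3]),
        )
        k3 = _deriv(a[0], a[1], a[2], a[3], la0, la1, mu0, mu1, q01, q10, ps0, ps1)
        a = (
            y0[0] + h * (0.3 * k1[0] - 0.9 * k2[0] + 1.2 * k3[0]),
            y0[1] + h * (0.3 * k1[1] - 0.9 * k2[1] + 1.2 * k3[1]),
            y0[2] + h * (0.3 * k1[2] - 0.9 * k2[2] + 1.2 * k3[2]),
            y0[3] + h * (0.3 * k1[3] - 0.9 * k2[3] + 1.2 * k3[3]),
        )
        k4 = _deriv(a[0], a[1], a[2], a[3], la0, la1, mu0, mu1, q01, q10, ps0, ps1)
        c1, c2, c3, c4 = -11.0 / 54.0, 2.5, -70.0 / 27.0, 35.0 / 27.0
        a = (
            y0[0] + h * (c1 * k1[0] + c2 * k2[0] + c3 * k3[0] + c4 * k4[0]),
            y0[1] + h * (c1 * k1[1] + c2 * k2[1] + c3 * k3[1] + c4 * k4[1]),
            y0[2] + h * (c1 * k1[2] + c2 * k2[2] + c3 * k3[2] + c4 * k4[2]),
            y0[3] + h * (c1 * k1[3] + c2 * k2[3] + c3 * k3[3] + c4 * k4[3]),
        )
        k5 = _deriv(a[0], a[1], a[2], a[3], la0, la1, mu0, mu1, q01, q10, ps0, ps1)
        b1, b2, b3, b4, b5 = (
            1631.0 / 55296.0,
            175.0 / 512.0,
            575.0 / 13824.0,
            44275.0 / 110592.0,
            253.0 / 4096.0,
        )
        a = (
            y0[0] + h * (b1 * k1[0] + b2 * k2[0] + b3 * k3[0] + b4 * k4[0] + b5 * k5[0]),
            y0[1] + h * (b1 * k1[1] + b2 * k2[1] + b3 * k3[1] + b4 * k4[1] + b5 * k5[1]),
            y0[2] + h * (b1 * k1[2] + b2 * k2[2] + b3 * k3[2] + b4 * k4[2] + b5 * k5[2]),
            y0[3] + h * (b1 * k1[3] + b2 * k2[3] + b3 * k3[3] + b4 * k4[3] + b5 * k5[3]),
        )
        k6 = _deriv(a[0], a[1], a[2], a[3], la0, la1, mu0, mu1, q01, q10, ps0, ps1)

        # 5th-order solution and embedded 4th-order error estimate
        w1, w3, w4, w6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
        e1_, e3_, e4_, e5_, e6_ = (
            37.0 / 378.0 - 2825.0 / 27648.0,
            250.0 / 621.0 - 18575.0 / 48384.0,
            125.0 / 594.0 - 13525.0 / 55296.0,
            -277.0 / 14336.0,
            512.0 / 1771.0 - 0.25,
        )
        err = 0.0
        y5 = [0.0, 0.0, 0.0, 0.0]
        for i in range(4):
            ks = (k1[i], k2[i], k3[i], k4[i], k5[i], k6[i])
            y5[i] = y0[i] + h * (w1 * ks[0] + w3 * ks[2] + w4 * ks[3] + w6 * ks[5])
            ei = h * (e1_ * ks[0] + e3_ * ks[2] + e4_ * ks[3] + e5_ * ks[4] + e6_ * ks[5])
            tol = atol + rtol * (abs(y0[i]) if abs(y0[i]) > abs(y5[i]) else abs(y5[i]))
            r = abs(ei) / tol
            if r > err:
                err = r
        if err <= 1.0:
            t += h
            e0, e1, d0, d1 = y5[0], y5[1], y5[2], y5[3]
            # keep E within [0,1] against roundoff
            if e0 < 0.0:
                e0 = 0.0
            elif e0 > 1.0:
                if e0 > 1.0 + 1e-6:
                    return e0, e1, d0, d1, False
                e0 = 1.0
            if e1 < 0.0:
                e1 = 0.0
            elif e1 > 1.0:
                if e1 > 1.0 + 1e-6:
                    return e0, e1, d0, d1, False
                e1 = 1.0
            fac = 0.9 * err ** -0.2 if err > 1e-12 else 5.0
            h *= min(5.0, fac)
        else:
            h *= max(0.1, 0.9 * err ** -0.25)
        if h < 1e-14 * T:
            return e0, e1, d0, d1, False
    return e0, e1, d0, d1, False


@njit(cache=True)
def _tree_loglik(
    code,
    length,
    state,
    age,
    left,
    right,
    la0,
    la1,
    mu0,
    mu1,
    q01,
    q10,
    ps0,
    ps1,
    rho,
    pi0,
    cond,
    rtol,
    atol,
):
    n = code.shape[0]
    E = np.empty((n, 2))
    D = np.empty((n, 2))
    logsc = 0.0
    for i in range(n):
        c = code[i]
        if c == 0:  # extant tip
            e0 = 1.0 - rho
            e1 = 1.0 - rho
            d0 = rho if state[i] == 0 else 0.0
            d1 = rho if state[i] == 1 else 0.0
        elif c == 1:  # fossil tip: E at its age, D = psi_s * E_s(age)
            e0, e1, _, _, ok = _integrate(
                1.0 - rho, 1.0 - rho, 0.0, 0.0, age[i],
                la0, la1, mu0, mu1, q01, q10, ps0, ps1, rtol, atol,
            )
            if not ok:
                return np.nan
            d0 = ps0 * e0 if state[i] == 0 else 0.0
            d1 = ps1 * e1 if state[i] == 1 else 0.0
        elif c == 2:  # sampled ancestor (single child)
            j = left[i]
            e0 = E[j, 0]
            e1 = E[j, 1]
            if state[i] == 0:
                d0 = ps0 * D[j, 0]
                d1 = 0.0
            else:
                d0 = 0.0
                d1 = ps1 * D[j, 1]
        else:  # internal bifurcation
            j = left[i]
            k = right[i]
            e0 = E[j, 0]
            e1 = E[j, 1]
            d0 = la0 * D[j, 0] * D[k, 0]
            d1 = la1 * D[j, 1] * D[k, 1]

        s = d0 + d1
        if not np.isfinite(s) or s <= 0.0:
            return -np.inf
        d0 /= s
        d1 /= s
        logsc += np.log(s)

        if length[i] > 0.0:
            e0, e1, d0, d1, ok = _integrate(
                e0, e1, d0, d1, length[i],
                la0, la1, mu0, mu1, q01, q10, ps0, ps1, rtol, atol,
            )
            if not ok:
                return np.nan
            s = d0 + d1
            if not np.isfinite(s) or s <= 0.0:
                return -np.inf
            d0 /= s
            d1 /= s
            logsc += np.log(s)
        E[i, 0] = e0
        E[i, 1] = e1
        D[i, 0] = d0
        D[i, 1] = d1

    r = n - 1
    mix = pi0 * D[r, 0] + (1.0 - pi0) * D[r, 1]
    if mix <= 0.0:
        return -np.inf
    ll = np.log(mix) + logsc
    if cond == 1:  # survival conditioning
        if code[r] == 3:
            denom = pi0 * la0 * (1.0 - E[r, 0]) ** 2 + (1.0 - pi0) * la1 * (1.0 - E[r, 1]) ** 2
        else:
            denom = pi0 * (1.0 - E[r, 0]) + (1.0 - pi0) * (1.0 - E[r, 1])
        if denom <= 0.0:
            return -np.inf
        ll -= np.log(denom)
    return ll


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------


def _ode_rhs(params: BisseParameters, include_psi: bool):
    la0, la1 = params.lam
    mu0, mu1 = params.mu
    q01, q10 = params.q
    ps = params.psi if include_psi else 0.0

    def rhs(_t, y):
        de0, de1, dd0, dd1 = _deriv.py_func(
            y[0], y[1], y[2], y[3], la0, la1, mu0, mu1, q01, q10, ps, ps
        )
        return [de0, de1, dd0, dd1]

    return rhs


def integrate_branch(
    segment_length: float,
    params: BisseParameters,
    initial: LikelihoodState,
    include_psi: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    integrator: str = "ck45",
) -> LikelihoodState:
    """Propagate a likelihood state along a branch segment (age-forward)."""
    if segment_length < 0:
        raise ValueError("segment length must be >= 0")
    if segment_length == 0:
        return LikelihoodState(initial.E0, initial.E1, initial.D0, initial.D1)
    ps = params.psi if include_psi else 0.0
    if integrator == "ck45":
        e0, e1, d0, d1, ok = _integrate(
            initial.E0, initial.E1, initial.D0, initial.D1, segment_length,
            params.lambda0, params.lambda1, params.mu0, params.mu1,
            params.q01, params.q10, ps, ps, rtol, atol,
        )
        if not ok:
            raise ArithmeticError(
                f"branch integration failed (params={params.as_dict()}, "
                f"length={segment_length})"
            )
        return LikelihoodState(min(max(e0, 0.0), 1.0), min(max(e1, 0.0), 1.0), d0, d1)
    sol = solve_ivp(
        _ode_rhs(params, include_psi),
        (0.0, segment_length),
        initial.as_array(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise ArithmeticError(f"LSODA failed: {sol.message} (params={params.as_dict()})")
    y = sol.y[:, -1]
    return LikelihoodState(
        min(max(float(y[0]), 0.0), 1.0), min(max(float(y[1]), 0.0), 1.0),
        float(y[2]), float(y[3]),
    )


def flatten_tree(tree: SampledTree, trait: str = FOCAL_TRAIT):
    """Postorder arrays for the compiled pruning core."""
    order = tree.postorder()
    index = {id(n): i for i, n in enumerate(order)}
    n = len(order)
    code = np.empty(n, dtype=np.int64)
    length = np.empty(n, dtype=np.float64)
    state = np.full(n, -1, dtype=np.int64)
    age = np.empty(n, dtype=np.float64)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    for i, node in enumerate(order):
        code[i] = _CODE[node.kind]
        length[i] = tree.edge_length(node)
        age[i] = tree.age(node)
        if node.is_sample:
            state[i] = node.states[trait]
        if node.children:
            left[i] = index[id(node.children[0])]
            if len(node.children) > 1:
                right[i] = index[id(node.children[1])]
    return code, length, state, age, left, right


def tree_loglikelihood(
    tree: SampledTree,
    params: BisseParameters,
    trait: str = FOCAL_TRAIT,
    include_psi: bool | None = None,
    conditioning: str = "survival",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    integrator: str = "ck45",
    _flat=None,
) -> float:
    """Log-likelihood of a sampled tree (extant or FBD view) under BiSSE(+FBD).

    ``include_psi`` defaults to True for the FBD view and False for the
    extant view; evaluating an FBD view without psi is a configuration
    error. ``conditioning`` is "survival" (on the process leaving observed
    samples on both root lineages) or "none". Returns -inf for parameter
    sets of zero likelihood.
    """
    if include_psi is None:
        include_psi = tree.view == "fbd"
    if tree.view == "fbd" and not include_psi:
        raise ValueError("an FBD view must be evaluated with include_psi=True")
    if tree.view == "extant" and not tree.is_ultrametric(tol=1e-6):
        raise ValueError("extant view is not ultrametric")
    cond = {"survival": 1, "none": 0}[conditioning]
    flat = _flat if _flat is not None else flatten_tree(tree, trait)
    ps = params.psi if include_psi else 0.0
    if integrator == "ck45":
        ll = _tree_loglik(
            *flat,
            params.lambda0, params.lambda1, params.mu0, params.mu1,
            params.q01, params.q10, ps, ps, params.rho, params.pi0,
            cond, rtol, atol,
        )
        if np.isnan(ll):
            raise ArithmeticError(
                f"likelihood integration failed (params={params.as_dict()})"
            )
        return float(ll)
    return _tree_loglik_scipy(tree, params, trait, include_psi, cond, rtol, atol)


def _tree_loglik_scipy(tree, params, trait, include_psi, cond, rtol, atol) -> float:
    """Reference pruning using scipy's LSODA; slow, used for cross-checks."""
    ps = params.psi if include_psi else 0.0
    p = params.with_(psi=ps)
    logsc = 0.0
    ED: dict[int, LikelihoodState] = {}

    def at_node(node) -> LikelihoodState:
        nonlocal logsc
        if node.kind == EXTANT:
            st = LikelihoodState(
                1 - p.rho, 1 - p.rho,
                p.rho if node.states[trait] == 0 else 0.0,
                p.rho if node.states[trait] == 1 else 0.0,
            )
        elif node.kind == FOSSIL_TIP:
            e = integrate_branch(
                tree.age(node), p, LikelihoodState(1 - p.rho, 1 - p.rho, 0, 0),
                include_psi=True, rtol=rtol, atol=atol, integrator="lsoda",
            )
            s = node.states[trait]
            st = LikelihoodState(e.E0, e.E1, ps * e.E0 if s == 0 else 0.0, ps * e.E1 if s == 1 else 0.0)
        elif node.kind == SAMPLED_ANCESTOR:
            child = ED[id(node.children[0])]
            s = node.states[trait]
            st = LikelihoodState(
                child.E0, child.E1,
                ps * child.D0 if s == 0 else 0.0, ps * child.D1 if s == 1 else 0.0,
            )
        else:
            l = ED[id(node.children[0])]
            r = ED[id(node.children[1])]
            st = LikelihoodState(
                l.E0, l.E1, p.lambda0 * l.D0 * r.D0, p.lambda1 * l.D1 * r.D1
            )
        s_ = st.D0 + st.D1
        if s_ <= 0:
            return None
        logsc += np.log(s_)
        st = LikelihoodState(st.E0, st.E1, st.D0 / s_, st.D1 / s_)
        if tree.edge_length(node) > 0:
            st = integrate_branch(
                tree.edge_length(node), p, st, include_psi=include_psi,
                rtol=rtol, atol=atol, integrator="lsoda",
            )
            s_ = st.D0 + st.D1
            if s_ <= 0:
                return None
            logsc += np.log(s_)
            st = LikelihoodState(st.E0, st.E1, st.D0 / s_, st.D1 / s_)
        return st

    for node in tree.postorder():
        st = at_node(node)
        if st is None:
            return -np.inf
        ED[id(node)] = st

    root = tree.root
    st = ED[id(root)]
    mix = p.pi0 * st.D0 + (1 - p.pi0) * st.D1
    if mix <= 0:
        return -np.inf
    ll = np.log(mix) + logsc
    if cond == 1:
        if len(root.children) > 1:
            denom = (
                p.pi0 * p.lambda0 * (1 - st.E0) ** 2
                + (1 - p.pi0) * p.lambda1 * (1 - st.E1) ** 2
            )
        else:
            denom = p.pi0 * (1 - st.E0) + (1 - p.pi0) * (1 - st.E1)
        if denom <= 0:
            return -np.inf
        ll -= np.log(denom)
    return float(ll)
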