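"""Adaptive random-scan Metropolis-Hastings sampler for BiSSE(+FBD).

Each iteration performs a fixed budget of weighted single-parameter moves
(default 29, echoing the study's per-iteration move schedule):
multiplicative scale moves on rates and a reflected slide on the root
probability pi0. Proposal scales are tuned toward ~0.44 acceptance every
tuning interval, during burn-in only, so the retained chain stays
Markovian. The retained trace is thinned post burn-in and the whole run
is reproducible from its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..fossilize import SampledTree
from ..sim import FOCAL_TRAIT
from .likelihood import _tree_loglik, flatten_tree
from .priors import PriorSpec, default_priors, log_prior

__all__ = ["MCMCSettings", "PosteriorTrace", "run_mcmc"]


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 100_000
    moves_per_iteration: int = 29
    tuning_interval: int = 200
    burnin_fraction: float = 0.25
    target_samples: int = 1000
    max_init_restarts: int = 100
    # branch-integration tolerance during sampling; looser than the
    # likelihood default (1e-8) since the induced log L error (~1e-4) is
    # far below MCMC noise
    rtol: float = 1e-7
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.moves_per_iteration <= 0:
            raise ValueError("iterations and moves_per_iteration must be positive")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.tuning_interval <= 0 or self.target_samples <= 0:
            raise ValueError("tuning_interval and target_samples must be positive")

    @property
    def burnin(self) -> int:
        return int(self.iterations * self.burnin_fraction)


@dataclass
class PosteriorTrace:
    """Retained MCMC samples plus run metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        skip = {"iteration", "logprior", "loglik", "logpost"}
        return [c for c in self.df.columns if c not in skip]

    def to_csv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("#meta " + json.dumps(self.meta, sort_keys=True) + "\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: Path) -> "PosteriorTrace":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("#meta "):
                meta = json.loads(line[len("#meta "):])
            else:
                fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(df=df, meta=meta)


_MODEL_PARAMS = {
    "bisse": ["lambda0", "lambda1", "mu0", "mu1", "q01", "q10", "pi0"],
    "bisse_fbd": ["lambda0", "lambda1", "mu0", "mu1", "q01", "q10", "psi", "pi0"],
    "bisse_fbd_2psi": ["lambda0", "lambda1", "mu0", "mu1", "q01", "q10", "psi0", "psi1", "pi0"],
}


def _make_loglik(tree: SampledTree, trait: str, model: str, conditioning: str,
                 rho: float, rtol: float, atol: float):
    if tree.view == "fbd" and model == "bisse":
        raise ValueError("an FBD view must be analysed under bisse_fbd (include psi)")
    if tree.view == "extant" and model != "bisse":
        raise ValueError("an extant view carries no fossil information: use model='bisse'")
    flat = flatten_tree(tree, trait)
    cond = {"survival": 1, "none": 0}[conditioning]
    fbd = model != "bisse"
    two = model == "bisse_fbd_2psi"

    def loglik(v: dict[str, float]) -> float:
        ps0 = (v["psi0"] if two else v["psi"]) if fbd else 0.0
        ps1 = (v["psi1"] if two else v["psi"]) if fbd else 0.0
        ll = _tree_loglik(
            *flat,
            v["lambda0"], v["lambda1"], v["mu0"], v["mu1"],
            v["q01"], v["q10"], ps0, ps1, rho, v["pi0"],
            cond, rtol, atol,
        )
        if math.isnan(ll):
            return -np.inf
        return float(ll)

    return loglik


def run_mcmc(
    tree: SampledTree,
    model: str,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    trait: str = FOCAL_TRAIT,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    conditioning: str = "survival",
    rho: float = 1.0,
    move_weights: dict[str, float] | None = None,
    loglikelihood_fn=None,
) -> PosteriorTrace:
    """Sample the posterior of a BiSSE or BiSSE+FBD analysis of one tree.

    ``model`` is "bisse" (extant view), "bisse_fbd" (shared fossil rate)
    or "bisse_fbd_2psi" (state-specific fossil rates).
    ``loglikelihood_fn`` may replace the tree likelihood (e.g. a constant,
    for prior-recovery checks); it receives a dict of parameter values.
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    priors = priors or default_priors()
    settings = settings or MCMCSettings()
    if rng is None:
        rng = np.random.default_rng(seed)
    names = _MODEL_PARAMS[model]
    weights = np.array([(move_weights or {}).get(n, 1.0) for n in names], float)
    weights /= weights.sum()

    loglik = loglikelihood_fn or _make_loglik(
        tree, trait, model, conditioning, rho, settings.rtol, settings.atol
    )

    # initial state: prior draws until the posterior is finite
    for _ in range(settings.max_init_restarts):
        values = {n: priors[n].sample(rng) for n in names}
        lp = log_prior(values, priors)
        ll = loglik(values) if np.isfinite(lp) else -np.inf
        if np.isfinite(lp + ll):
            break
    else:
        raise RuntimeError(
            f"no finite starting point after {settings.max_init_restarts} prior draws"
        )

    scales = {n: (0.2 if n == "pi0" else 0.8) for n in names}
    accepted = {n: 0 for n in names}
    proposed = {n: 0 for n in names}
    win_acc = {n: 0 for n in names}
    win_prop = {n: 0 for n in names}

    burnin = settings.burnin
    thin = max(1, (settings.iterations - burnin) // settings.target_samples)
    rows = []

    for it in range(settings.iterations):
        ks = rng.choice(len(names), size=settings.moves_per_iteration, p=weights)
        for k in ks:
            name = names[k]
            x = values[name]
            if name == "pi0":
                # reflected slide on [0, 1]: symmetric
                y = x + scales[name] * (rng.random() - 0.5)
                y = abs(y)
                if y > 1.0:
                    y = 2.0 - y
                y = min(max(y, 0.0), 1.0)
                log_hastings = 0.0
            else:
                f = math.exp(scales[name] * (rng.random() - 0.5))
                y = x * f
                log_hastings = math.log(f)
            values[name] = y
            lp_new = log_prior(values, priors)
            ll_new = loglik(values) if np.isfinite(lp_new) else -np.inf
            proposed[name] += 1
            win_prop[name] += 1
            if math.log(rng.random() + 1e-300) < (lp_new + ll_new) - (lp + ll) + log_hastings:
                lp, ll = lp_new, ll_new
                accepted[name] += 1
                win_acc[name] += 1
            else:
                values[name] = x
        # adapt during burn-in only
        if it < burnin and (it + 1) % settings.tuning_interval == 0:
            for n in names:
                if win_prop[n] == 0:
                    continue
                rate = win_acc[n] / win_prop[n]
                scales[n] *= math.exp(rate - 0.44)
                hi = 1.0 if n == "pi0" else 10.0
                scales[n] = min(max(scales[n], 1e-3), hi)
                win_acc[n] = 0
                win_prop[n] = 0
        if it >= burnin and (it - burnin) % thin == 0:
            rows.append(
                [it, lp, ll, lp + ll] + [values[n] for n in names]
            )

    df = pd.DataFrame(rows, columns=["iteration", "logprior", "loglik", "logpost"] + names)
    meta = {
        "model": model,
        "view": getattr(tree, "view", None),
        "trait": trait,
        "conditioning": conditioning,
        "rho": rho,
        "seed": seed,
        "priors": priors.describe(),
        "settings": asdict(settings),
        "burnin": burnin,
        "thin": thin,
        "acceptance": {
            n: (accepted[n] / proposed[n] if proposed[n] else float("nan")) for n in names
        },
        "proposal_scales": scales,
    }
    return PosteriorTrace(df=df, meta=meta)
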