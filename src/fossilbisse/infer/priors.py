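"""Prior specification for the Bayesian BiSSE(+FBD) analyses.

Lognormal priors on the speciation, extinction and fossil-sampling rates,
an exponential prior with mean 0.01 (the simulated focal transition rate)
on the transition rates, and a uniform prior on the root-state
probability pi0. Hyperparameters are not dictated by the study design
beyond giving the truth non-zero density; the defaults below centre the
rate priors near the simulated magnitudes and are overridable per
parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Prior", "PriorSpec", "default_priors", "log_prior"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Prior:
    """A one-dimensional prior: lognormal, exponential or uniform."""

    kind: str  # "lognormal" | "exponential" | "uniform"
    a: float  # location / mean / lower bound
    b: float = 0.0  # scale / unused / upper bound

    def __post_init__(self) -> None:
        if self.kind == "lognormal" and self.b <= 0:
            raise ValueError("lognormal scale must be > 0")
        if self.kind == "exponential" and self.a <= 0:
            raise ValueError("exponential mean must be > 0")
        if self.kind == "uniform" and self.b <= self.a:
            raise ValueError("uniform needs b > a")
        if self.kind not in ("lognormal", "exponential", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")

    def logpdf(self, x: float) -> float:
        if self.kind == "lognormal":
            if x <= 0:
                return -np.inf
            z = (math.log(x) - self.a) / self.b
            return -math.log(x * self.b) - _LOG_SQRT_2PI - 0.5 * z * z
        if self.kind == "exponential":
            if x < 0:
                return -np.inf
            return -math.log(self.a) - x / self.a
        if not self.a <= x <= self.b:
            return -np.inf
        return -math.log(self.b - self.a)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "lognormal":
            return float(math.exp(rng.normal(self.a, self.b)))
        if self.kind == "exponential":
            return float(rng.exponential(self.a))
        return float(rng.uniform(self.a, self.b))


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors for every free parameter, keyed by name."""

    priors: dict[str, Prior] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.priors

    def describe(self) -> dict[str, str]:
        return {
            k: f"{p.kind}({p.a:g}" + (f", {p.b:g})" if p.kind != "exponential" else ")")
            for k, p in self.priors.items()
        }


def default_priors(
    rate_location: float = math.log(0.01),
    rate_scale: float = 2.0,
    psi_location: float = math.log(0.05),
    psi_scale: float = 1.0,
    q_mean: float = 0.01,
) -> PriorSpec:
    """Study defaults; every hyperparameter is overridable.

    The diversification-rate prior is deliberately vague (spanning
    several orders of magnitude, centred below the expected rate scale):
    with extant-only trees the likelihood is nearly flat in the
    extinction rate, and a prior concentrated at large rates would
    dominate those posteriors. See the methods note for the reasoning.
    """
    ln = lambda loc, sc: Prior("lognormal", loc, sc)
    return PriorSpec(
        {
            "lambda0": ln(rate_location, rate_scale),
            "lambda1": ln(rate_location, rate_scale),
            "mu0": ln(rate_location, rate_scale),
            "mu1": ln(rate_location, rate_scale),
            "q01": Prior("exponential", q_mean),
            "q10": Prior("exponential", q_mean),
            "psi": ln(psi_location, psi_scale),
            "psi0": ln(psi_location, psi_scale),
            "psi1": ln(psi_location, psi_scale),
            "pi0": Prior("uniform", 0.0, 1.0),
        }
    )


def log_prior(values: dict[str, float], priors: PriorSpec) -> float:
    """Sum of independent log-densities over the supplied free parameters.

    Parameters not present in ``values`` (fixed quantities such as rho)
    contribute nothing. Out-of-support values yield -inf rather than an
    exception.
    """
    total = 0.0
    for name, x in values.items():
        lp = priors[name].logpdf(x)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total
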