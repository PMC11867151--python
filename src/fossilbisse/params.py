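"""Parameter containers shared by the simulator and the likelihood machinery.

The binary-state speciation-extinction (BiSSE) process is parameterised by
per-state speciation rates (lambda0, lambda1), per-state extinction rates
(mu0, mu1) and trait transition rates (q01: state 0 -> 1, q10: 1 -> 0).
The fossilized birth-death (FBD) extension adds a per-lineage fossil
sampling rate psi; rho is the probability an extant species is sampled at
the present, and pi0 the probability that the root lineage is in state 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = [
    "BisseParameters",
    "Scenario",
    "SCENARIOS",
    "NeutralTraitSpec",
    "NEUTRAL_TRAIT_SPECS",
]


@dataclass(frozen=True)
class BisseParameters:
    """Full rate vector of the BiSSE(+FBD) process.

    All rates are per-lineage, per unit time. ``psi`` is the fossil
    recovery rate of the fossilized birth-death extension (0 for a purely
    neontological model); ``rho`` the extant sampling probability and
    ``pi0`` the root-state-0 probability used at the root of the
    likelihood.
    """

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float
    psi: float = 0.0
    rho: float = 1.0
    pi0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10", "psi"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho!r}")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must be in [0, 1], got {self.pi0!r}")

    # convenient state-indexed views -------------------------------------
    @property
    def lam(self) -> tuple[float, float]:
        return (self.lambda0, self.lambda1)

    @property
    def mu(self) -> tuple[float, float]:
        return (self.mu0, self.mu1)

    @property
    def q(self) -> tuple[float, float]:
        """Rate of leaving state i: (q01, q10)."""
        return (self.q01, self.q10)

    def with_(self, **kwargs: float) -> "BisseParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {
            "lambda0": self.lambda0,
            "lambda1": self.lambda1,
            "mu0": self.mu0,
            "mu1": self.mu1,
            "q01": self.q01,
            "q10": self.q10,
            "psi": self.psi,
            "rho": self.rho,
            "pi0": self.pi0,
        }


# Shared baseline of the four study scenarios.
_BASE = dict(lambda0=0.1, mu1=0.03, q01=0.01)


@dataclass(frozen=True)
class Scenario:
    """One of the four simulation scenarios S1-S4.

    S1 is the constant-rate control (all rates state-independent); S2
    doubles speciation in state 1; S3 doubles extinction in state 0; S4
    halves the 1->0 transition rate. All scenarios share lambda0 = 0.1,
    mu1 = 0.03 and q01 = 0.01.
    """

    id: str
    lambda1_factor: float = 1.0
    mu0_factor: float = 1.0
    q10_factor: float = 1.0

    def parameters(self, psi: float = 0.0, rho: float = 1.0, pi0: float = 0.5) -> BisseParameters:
        return BisseParameters(
            lambda0=_BASE["lambda0"],
            lambda1=_BASE["lambda0"] * self.lambda1_factor,
            mu0=_BASE["mu1"] * self.mu0_factor,
            mu1=_BASE["mu1"],
            q01=_BASE["q01"],
            q10=_BASE["q01"] * self.q10_factor,
            psi=psi,
            rho=rho,
            pi0=pi0,
        )


SCENARIOS: dict[str, Scenario] = {
    "S1": Scenario("S1"),
    "S2": Scenario("S2", lambda1_factor=2.0),
    "S3": Scenario("S3", mu0_factor=2.0),
    "S4": Scenario("S4", q10_factor=0.5),
}


@dataclass(frozen=True)
class NeutralTraitSpec:
    """A symmetric binary trait evolving independently of diversification.

    The study uses slow, medium and fast neutral traits with symmetric
    transition rate q in {0.01, 0.1, 1}; any q > 0 is accepted.
    """

    q: float
    label: str = ""

    def __post_init__(self) -> None:
        # q = 0 (a frozen trait) is permitted for degenerate checks; the
        # study's own specs all have q > 0.
        if not (math.isfinite(self.q) and self.q >= 0):
            raise ValueError(f"neutral trait rate q must be >= 0, got {self.q!r}")
        if not self.label:
            object.__setattr__(self, "label", f"neutral_q{self.q:g}")


NEUTRAL_TRAIT_SPECS: tuple[NeutralTraitSpec, ...] = (
    NeutralTraitSpec(0.01, "slow"),
    NeutralTraitSpec(0.1, "medium"),
    NeutralTraitSpec(1.0, "fast"),
)
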