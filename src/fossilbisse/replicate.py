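"""Orchestration of one simulation replicate.

A replicate is a complete tree plus fossils and the two observable views,
accepted only after rejection filtering: each trait (focal and neutral)
must have both states present in at least 10% of the sampled taxa of the
extant view and, when fossils exist, of the FBD view. A failing focal
trait discards the whole tree (trait and tree are not independent); a
failing neutral trait is resimulated on the accepted tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fossilize import (
    FossilOccurrence,
    SampledTree,
    build_fbd_tree,
    prune_to_extant,
    sample_fossils,
)
from .params import NeutralTraitSpec, Scenario
from .sim import (
    FOCAL_TRAIT,
    CompleteTree,
    RejectionBudgetExceeded,
    simulate_complete_tree,
    simulate_neutral_trait,
)

__all__ = ["ReplicateDataset", "generate_replicate", "passes_frequency_rule"]


def passes_frequency_rule(
    views: list[SampledTree], trait: str, min_freq: float = 0.10
) -> bool:
    """True if both states of ``trait`` reach the minimum tip share in every view.

    "Taxa" are the sampled nodes of a view (extant tips, plus fossil tips
    and sampled ancestors in the FBD view); the threshold is
    ceil(min_freq * count) nodes per state.
    """
    for view in views:
        states = [n.states[trait] for n in view.samples()]
        need = math.ceil(min_freq * len(states))
        n1 = sum(states)
        if n1 < need or len(states) - n1 < need:
            return False
    return True


@dataclass
class ReplicateDataset:
    """One accepted simulation replicate with its observable views."""

    scenario_id: str
    psi: float
    n_extant_stop: int
    complete: CompleteTree
    occurrences: list[FossilOccurrence]
    extant: SampledTree
    fbd: SampledTree | None  # None when psi == 0
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def views(self) -> list[SampledTree]:
        return [self.extant] + ([self.fbd] if self.fbd is not None else [])

    @property
    def trait_names(self) -> list[str]:
        return list(self.complete.traits)


def generate_replicate(
    scenario: Scenario,
    psi: float,
    neutral_specs: list[NeutralTraitSpec],
    n_extant_stop: int,
    rng: np.random.Generator,
    min_freq: float = 0.10,
    max_rejections: int = 10_000,
) -> ReplicateDataset:
    """Simulate until a replicate passes all rejection filters."""
    params = scenario.parameters(psi=psi)
    rejections = {"extinct": 0, "focal": 0}
    for spec in neutral_specs:
        rejections[spec.label] = 0

    for _ in range(max_rejections):
        tree = simulate_complete_tree(params, n_extant_stop, rng, max_rejections)
        rejections["extinct"] += tree.n_discarded
        occurrences = sample_fossils(tree, psi, rng)
        extant = prune_to_extant(tree)
        fbd = build_fbd_tree(tree, occurrences) if psi > 0 else None
        views = [extant] + ([fbd] if fbd is not None else [])
        if not passes_frequency_rule(views, FOCAL_TRAIT, min_freq):
            rejections["focal"] += 1
            continue
        # neutral traits are independent of the tree: resimulate per trait
        ok = True
        for spec in neutral_specs:
            accepted = False
            for _ in range(max_rejections):
                simulate_neutral_trait(tree, spec, rng)
                for view in views:
                    view.stamp_states(tree, spec.label)
                if passes_frequency_rule(views, spec.label, min_freq):
                    accepted = True
                    break
                rejections[spec.label] += 1
            if not accepted:
                ok = False
                break
        if not ok:
            break
        # stamp the accepted neutral-trait states onto the fossil occurrences
        for o in occurrences:
            for spec in neutral_specs:
                o.states[spec.label] = tree.state_at(spec.label, o.lineage, o.time)
        return ReplicateDataset(
            scenario_id=scenario.id,
            psi=psi,
            n_extant_stop=n_extant_stop,
            complete=tree,
            occurrences=occurrences,
            extant=extant,
            fbd=fbd,
            rejections=rejections,
        )
    worst = max(rejections, key=rejections.get)
    raise RejectionBudgetExceeded(
        f"replicate rejection cap exceeded for scenario {scenario.id}, psi={psi}; "
        f"most-rejected component: {worst} ({rejections[worst]} rejections)"
    )
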