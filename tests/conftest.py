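from __future__ import annotations

import numpy as np
import pytest

import fossilbisse as fb


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_replicate():
    """One accepted S1 replicate with fossils, reused across read-only tests."""
    rng = np.random.default_rng(42)
    design = fb.StudyDesign()
    return fb.generate_replicate(
        fb.SCENARIOS["S1"], 0.1, design.neutral_specs, 50, rng
    )


def random_small_dataset(seed: int, n_tips: int | None = None, psi: float = 0.08):
    """A random 5-10 tip replicate (no trait filtering) for likelihood tests."""
    r = np.random.default_rng(seed)
    n = n_tips or int(r.integers(5, 11))
    params = fb.BisseParameters(0.3, 0.3, 0.1, 0.1, 0.05, 0.05, psi=psi)
    tree = fb.simulate_complete_tree(params, n, r)
    occ = fb.sample_fossils(tree, psi, r)
    extant = fb.prune_to_extant(tree)
    fbd = fb.build_fbd_tree(tree, occ) if psi > 0 else None
    return tree, occ, extant, fbd
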