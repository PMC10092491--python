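"""Shared fixtures: tiny lattices, random small masks, and a reusable phantom cohort."""

import numpy as np
import pytest

from cardiospare import Lattice, StructureMask
from cardiospare.synthetic_cohort import generate_cohort


@pytest.fixture
def small_lattice() -> Lattice:
    return Lattice((20, 20, 12), (1.0, 1.0, 3.0))


def random_mask(rng: np.random.Generator, lattice: Lattice, label: str, p: float = 0.05) -> StructureMask:
    """Nonempty random sparse mask (re-draws until at least one voxel)."""
    while True:
        vox = rng.random(lattice.shape) < p
        if vox.any():
            return StructureMask(lattice, vox, label)


@pytest.fixture(scope="session")
def phantom_cohort():
    """Small mixed cohort on the full clinical lattice, shared across tests."""
    bundles, truth = generate_cohort(
        8, {"far": 3, "near_spareable": 3, "near_unspareable": 2}, seed=42
    )
    return bundles, truth
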