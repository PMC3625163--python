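"""Shared fixtures.

The expensive sampling products (folding-temperature estimates, biased
trajectories, free-energy profiles) are session-scoped so the landscape and
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import foldmotif as fm


@pytest.fixture(scope="session")
def hairpin16():
    return fm.make_ideal_fold(16, "hairpin", seed=1)


@pytest.fixture(scope="session")
def hairpin_topology(hairpin16):
    structure, cmap = hairpin16
    return fm.build_topology(structure, cmap)


@pytest.fixture(scope="session")
def toy_topology():
    return fm.make_toy_twostate(seed=0)


@pytest.fixture(scope="session")
def dimer_topology():
    """Two beads joined by one stiff harmonic bond (no other terms)."""
    s = fm.CalphaStructure(
        "dimer", "A", np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]]),
        np.array([1, 2]))
    return fm.build_topology(s, fm.ContactMap([], 2))


@pytest.fixture(scope="session")
def family13():
    """Seeded 13-member synthetic family under the study conditions
    (0.3 A noise, decoy insertions in a minority of members)."""
    template, tmap = fm.make_ideal_fold(24, "hairpin", seed=2)
    fam = fm.make_family(template, tmap, fm.FamilySpec(seed=3))
    return template, tmap, fam


@pytest.fixture(scope="session")
def toy_tf(toy_topology):
    """Folding-temperature estimate of the toy folder (seed 1), with
    coordinate saving so route maps can be built from the same run."""
    return fm.estimate_tf(toy_topology, seed=1, save_coords=True)


@pytest.fixture(scope="session")
def toy_sample(toy_topology, toy_tf):
    return toy_tf.sample


@pytest.fixture(scope="session")
def toy_profile(toy_tf):
    return toy_tf.profile


@pytest.fixture(scope="session")
def toy_tf_seeds(toy_topology, toy_tf):
    """Folding-temperature estimates across five independent seeds (the
    seed-1 estimate is shared with the ``toy_tf`` fixture)."""
    return [toy_tf] + [fm.estimate_tf(toy_topology, seed=seed)
                       for seed in (2, 3, 4, 5)]


@pytest.fixture(scope="session")
def toy_tf_scaled(toy_topology):
    """T_f estimate of the toy with every epsilon-type constant scaled by
    1.5, same seed and protocol as ``toy_tf``."""
    scaled = toy_topology.with_params(toy_topology.params.scaled(1.5))
    return fm.estimate_tf(scaled, seed=1)


@pytest.fixture(scope="session")
def double_well():
    """1-D double well on [0, 1]: minima at 0.25 / 0.75, barrier 6 epsilon."""
    height = 6.0

    def u(x):
        return height * (1.0 - ((x - 0.5) / 0.25) ** 2) ** 2

    return u, height
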