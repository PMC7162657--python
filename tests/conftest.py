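"""Shared fixtures: small synthetic cohorts and precomputed energies."""

import numpy as np
import pytest

from ctrlenergy.cohort import SyntheticCohortSpec, generate_cohort
from ctrlenergy.control import cohort_energy
from ctrlenergy.network import Connectome


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticCohortSpec(n_subjects=30, n_nodes=32, seed=1234)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_energy(small_cohort):
    return cohort_energy(
        small_cohort.connectomes,
        small_cohort.phenotypes["subject_id"],
        small_cohort.systems,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def random_connectome(rng, n=10, density=1.0, systems=None):
    """Random symmetric nonnegative test connectome."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    keep = rng.random(iu.size) < density
    w[iu[keep], ju[keep]] = rng.lognormal(0.0, 0.7, int(keep.sum()))
    w = w + w.T
    if systems is None:
        systems = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    return Connectome(w, np.array([f"n{i}" for i in range(n)]), np.asarray(systems))
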