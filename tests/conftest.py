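"""Shared fixtures: small schedules, dictionaries and bases.

All fixtures are deterministic (fixed seeds) and sized for fast unit tests;
the heavier study-scale computations live in test_acceptance.py.
"""

import numpy as np
import pytest

from qti.epg import build_dictionary
from qti.recon import compute_basis
from qti.schedule import make_flip_schedule


@pytest.fixture(scope="session")
def sched_small():
    """150-repetition train: long enough for realistic encoding, fast."""
    return make_flip_schedule(150)


@pytest.fixture(scope="session")
def small_dict(sched_small):
    """Coarse 30 x 25 (T1 x T2) dictionary on the small schedule."""
    t1 = np.linspace(50, 3000, 30)
    t2 = np.linspace(20, 1500, 25)
    return build_dictionary(sched_small, t1, t2)


@pytest.fixture(scope="session")
def small_basis(small_dict):
    return compute_basis(small_dict, 10)


@pytest.fixture(scope="session")
def small_proj(small_dict, small_basis):
    """Atoms projected into the subspace (unnormalized), (n_atoms, R)."""
    return small_dict.atoms @ small_basis.basis.conj()
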