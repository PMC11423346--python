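import numpy as np
import pytest

from komet.io import InteractionSet, MoleculeRecord, ProteinRecord, Registry
from komet.kernels import LAKernelParams


@pytest.fixture
def rng():
    # function-scoped: every test sees the same fresh stream, so results do
    # not depend on which tests ran earlier
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_sub_matrix():
    """Small symmetric substitution table over a 3-letter alphabet."""
    letters = "ACD"
    vals = {
        ("A", "A"): 4.0, ("C", "C"): 9.0, ("D", "D"): 6.0,
        ("A", "C"): 0.0, ("A", "D"): -2.0, ("C", "D"): -3.0,
    }
    sub = {}
    for a in letters:
        for b in letters:
            sub[(a, b)] = vals.get((a, b), vals.get((b, a)))
    return sub


@pytest.fixture(scope="session")
def toy_la_params(toy_sub_matrix):
    return LAKernelParams(
        beta=0.5, gap_open=3.0, gap_extend=1.0,
        substitution=toy_sub_matrix, log_transform=False,
    )


def random_fingerprints(n, n_bits, rng, p=0.2):
    F = (rng.random((n, n_bits)) < p).astype(np.uint8)
    for i in np.flatnonzero(F.sum(axis=1) == 0):
        F[i, rng.integers(n_bits)] = 1
    return F


@pytest.fixture
def tiny_dataset():
    """2 molecules x 2 proteins with 3 labeled pairs."""
    mols = Registry(
        [
            MoleculeRecord("m1", fingerprint=np.array([1, 0, 1, 1], dtype=np.uint8)),
            MoleculeRecord("m2", fingerprint=np.array([0, 1, 1, 0], dtype=np.uint8)),
        ]
    )
    prots = Registry(
        [ProteinRecord("p1", "ACDKL"), ProteinRecord("p2", "MNPQR")]
    )
    return InteractionSet(
        mols, prots, np.array([0, 1, 0]), np.array([0, 1, 1]), np.array([1, -1, 1])
    )


@pytest.fixture(scope="session")
def small_world():
    """Small planted world shared by the slower integration tests."""
    from komet.synthetic import make_world

    return make_world(n_M=60, n_P=12, n_bits=256, n_scaffolds=8, n_families=4,
                      seq_len=(20, 30), seed=7)
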