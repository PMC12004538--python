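import numpy as np
import pytest

from stackd.chemstruct import Molecule
from stackd.synthdata import toy_ring


@pytest.fixture
def asym_ring() -> Molecule:
    """Five-membered charged ring with an apex substituent: no in-plane
    symmetry, so canonical frames and pose angles are uniquely defined."""
    return toy_ring(5, 1.37, "alternating", q=0.1, name="asym", apex=True)


@pytest.fixture
def hexagon() -> Molecule:
    return toy_ring(6, 1.39, "alternating", q=0.15, name="hex")


@pytest.fixture
def random_rigid():
    """Factory for seeded random proper rigid transforms (R, t)."""

    def make(seed: int):
        rng = np.random.default_rng(seed)
        # QR of a random matrix, sign-fixed to det +1
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        return q, rng.normal(scale=5.0, size=3)

    return make
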