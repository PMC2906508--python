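import numpy as np
import pytest

from mhcdeform.structures import AtomRecord, Structure
from mhcdeform.synthetic import build_ideal_helix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def helix15() -> Structure:
    return build_ideal_helix(15, chain_id="A")


@pytest.fixture
def toy_structure() -> Structure:
    """Three-residue, CA-only toy chain."""
    atoms = [
        AtomRecord(serial=i + 1, atom_name="CA", element="C", res_name="GLY",
                   chain_id="A", res_seq=i + 1, coords=(float(i) * 3.8, 0.0, 0.0))
        for i in range(3)
    ]
    return Structure(atoms, id="toy")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
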