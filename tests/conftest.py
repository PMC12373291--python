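import numpy as np
import pytest

from cgdna.cg_model import (CGConformation, Sequence, ideal_helix,
                            parse_sequence, reverse_complement)
from cgdna.electrostatics import IonCondition
from cgdna.forcefield import ForceFieldParams


@pytest.fixture(scope="session")
def params() -> ForceFieldParams:
    return ForceFieldParams.load_default()


@pytest.fixture(scope="session")
def ion() -> IonCondition:
    return IonCondition(conc_mono=1.0)


@pytest.fixture(scope="session")
def duplex6() -> CGConformation:
    """Ideal 6-bp CG duplex (single chain with a break after residue 5)."""
    a = parse_sequence("GCGATC")
    return ideal_helix(a, Sequence(reverse_complement(a)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_copy(conf: CGConformation, rng: np.random.Generator) -> CGConformation:
    rot = random_rotation(rng)
    shift = rng.normal(scale=20.0, size=3)
    return CGConformation(conf.sequence, conf.coords @ rot.T + shift,
                          conf.chain_breaks)
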