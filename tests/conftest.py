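import numpy as np
import pytest

from domseg.structio import ProteinChain


def make_test_chain(n: int, seed: int = 0, spread: float = 3.8) -> ProteinChain:
    """Random non-degenerate chain for geometry tests."""
    rng = np.random.default_rng(seed)
    ca = np.cumsum(rng.normal(scale=spread / 1.7, size=(n, 3)), axis=0)
    # local offsets guaranteed non-collinear
    nn = ca + np.array([1.2, 0.6, 0.0]) + rng.normal(scale=0.05, size=(n, 3))
    cc = ca + np.array([-0.4, 1.3, 0.3]) + rng.normal(scale=0.05, size=(n, 3))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return ProteinChain(id=f"test{seed}", sequence=seq, coords_N=nn, coords_CA=ca,
                        coords_C=cc, author_numbering=np.arange(1, n + 1))


def random_rigid(seed: int):
    rng = np.random.default_rng(seed)
    A = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(A) < 0:
        A[:, 0] *= -1
    return A, rng.normal(scale=25.0, size=3)


def transform_chain(chain: ProteinChain, R: np.ndarray, t: np.ndarray) -> ProteinChain:
    return ProteinChain(chain.id, chain.sequence,
                        chain.coords_N @ R.T + t, chain.coords_CA @ R.T + t,
                        chain.coords_C @ R.T + t, chain.author_numbering)


@pytest.fixture
def straight_chain():
    def _make(n: int) -> ProteinChain:
        ca = np.zeros((n, 3))
        ca[:, 0] = np.arange(n) * 3.8
        nn = ca + np.array([0.0, 1.46, 0.0])
        cc = ca + np.array([1.1, -1.0, 0.2])
        return ProteinChain(id="straight", sequence="A" * n, coords_N=nn,
                            coords_CA=ca, coords_C=cc,
                            author_numbering=np.arange(1, n + 1))
    return _make
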