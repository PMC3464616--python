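import numpy as np
import pytest

from solidecc.codebuild import (
    ALT_PROBE_FULL,
    ALT_PROBE_SHORT,
    CodeSpec,
    ECC_PROBE,
    build_block_generator,
    enumerate_probe_generators,
)


@pytest.fixture(scope="session")
def ecc_gen():
    """Block generator for the production ECC probe 1b0b0."""
    return build_block_generator(ECC_PROBE)


@pytest.fixture(scope="session")
def alt_short_gen():
    """Block generator for the short alternative probe 10b00."""
    return build_block_generator(ALT_PROBE_SHORT)


@pytest.fixture(scope="session")
def alt_full_gen():
    """Block generator for the full-syndrome alternative probe 1b010."""
    return build_block_generator(ALT_PROBE_FULL)


@pytest.fixture(scope="session")
def all_probe_generators():
    return enumerate_probe_generators()


@pytest.fixture
def spec10():
    """Two-block code with a zero adapter (simplest full-code instance)."""
    return CodeSpec(read_length=10, adapter_base=0)


@pytest.fixture
def spec50():
    """Production-scale ten-block code with the CSFASTA adapter T."""
    return CodeSpec(read_length=50)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def gf4_mul_scalar(a: int, b: int) -> int:
    """Multiplication in GF(4) = GF(2)[z]/(z^2+z+1) computed from polynomial
    arithmetic (independent of the package's lookup table)."""
    # bits: element = b1*z + b0
    a1, a0 = a >> 1, a & 1
    b1, b0 = b >> 1, b & 1
    # product: (a1 b1) z^2 + (a1 b0 + a0 b1) z + a0 b0, with z^2 = z + 1
    c2 = a1 & b1
    c1 = (a1 & b0) ^ (a0 & b1) ^ c2
    c0 = (a0 & b0) ^ c2
    return (c1 << 1) | c0


def gf4_matmul_naive(A, B):
    A = np.asarray(A)
    B = np.asarray(B)
    out = np.zeros((A.shape[0], B.shape[1]), dtype=np.uint8)
    for i in range(A.shape[0]):
        for j in range(B.shape[1]):
            acc = 0
            for t in range(A.shape[1]):
                acc ^= gf4_mul_scalar(int(A[i, t]), int(B[t, j]))
            out[i, j] = acc
    return out


def gf4_invert_gauss(M):
    """Matrix inverse over GF(4) by Gauss-Jordan elimination (oracle)."""
    M = np.array(M, dtype=np.uint8)
    n = M.shape[0]
    inv_elem = {1: 1, 2: 3, 3: 2}
    aug = np.hstack([M, np.eye(n, dtype=np.uint8)])
    for col in range(n):
        pivot = next(r for r in range(col, n) if aug[r, col] != 0)
        aug[[col, pivot]] = aug[[pivot, col]]
        scale = inv_elem[int(aug[col, col])]
        aug[col] = [gf4_mul_scalar(scale, int(x)) for x in aug[col]]
        for r in range(n):
            if r != col and aug[r, col] != 0:
                factor = int(aug[r, col])
                aug[r] ^= np.array(
                    [gf4_mul_scalar(factor, int(x)) for x in aug[col]], dtype=np.uint8
                )
    return aug[:, n:]


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, max_examples=50)
_hyp_settings.load_profile("deterministic")
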