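"""Construction of the two-base + ECC convolutional code family over GF(4).

The encoder reads a window of five bases, sliding one base at a time, and
emits two streams:

* the **color stream** -- each symbol is the sum of the first two window
  elements (probe generator ``rho1 = 11000``); this is the classic two-base
  encoding, one color per base given one known adapter base;
* the **ECC stream** -- the window dotted with a second probe generator
  (``rho2 = 1b0b0`` for the production Exact Call Chemistry), punctured so
  that only every fifth symbol is emitted.

A read of ``k`` bases (``k`` a multiple of 5) therefore yields ``n = 6k/5``
colors.  Partitioning the read into ``m = k/5`` five-base blocks, each block
is recoverable from five "data" colors (the four within-block adjacent-pair
colors plus the block's ECC color) through an invertible 5x5 block generator;
the remaining colors are the junction colors straddling adjacent blocks and
act as parity checks.  The junction preceding block 1 is the color formed
with the known adapter base.

All matrix conventions are row-vector times matrix: ``colors = bases @ G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

from . import gf4
from .gf4 import gf_matmul, gf_matvec

__all__ = [
    "ProbeGenerator",
    "RHO1",
    "ECC_PROBE",
    "ALT_PROBE_SHORT",
    "ALT_PROBE_FULL",
    "BlockGenerator",
    "NonInvertibleCodeError",
    "build_block_generator",
    "encode_block",
    "decode_block",
    "CodeSpec",
    "EncodedRead",
    "encode_read",
    "naive_decode_colors",
    "FullGenerator",
    "build_full_generator",
    "build_parity_check",
    "is_valid_codeword",
    "enumerate_probe_generators",
]

# Lower-triangular all-ones matrix used by the closed-form block inverse.
_L = np.tril(np.ones((5, 5), dtype=np.uint8))


class NonInvertibleCodeError(ValueError):
    """The probe generator's coefficient sum is zero, so blocks of colors
    cannot be individually inverted and syndrome analysis does not apply."""


@dataclass(frozen=True)
class ProbeGenerator:
    """Five GF(4) coefficients defining a probe set's color as a dot product.

    The color attached to the probe interrogating window ``b`` is ``b . p``.
    Coefficients may be given as a 5-character string over ``{0,1,a,b}`` or
    the color digits ``{0,1,2,3}`` (``a == 2``, ``b == 3``).
    """

    coefficients: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.coefficients) != 5:
            raise ValueError("a probe generator has exactly 5 coefficients")
        if any(c not in (0, 1, 2, 3) for c in self.coefficients):
            raise ValueError("probe coefficients must be GF(4) elements 0-3")

    @classmethod
    def parse(cls, text: str) -> "ProbeGenerator":
        table = {"0": 0, "1": 1, "2": 2, "3": 3, "a": 2, "b": 3, "A": 2, "B": 3}
        try:
            coeffs = tuple(table[c] for c in text)
        except KeyError as exc:
            raise ValueError(f"invalid probe generator character {exc.args[0]!r} in {text!r}") from None
        return cls(coeffs)  # length checked in __post_init__

    def __str__(self) -> str:
        return gf4.gf_to_symbols(np.array(self.coefficients))

    @property
    def coefficient_sum(self) -> int:
        s = 0
        for c in self.coefficients:
            s ^= c
        return s


RHO1 = ProbeGenerator((1, 1, 0, 0, 0))          # two-base chemistry
ECC_PROBE = ProbeGenerator((1, 3, 0, 3, 0))     # production ECC round, "1b0b0"
ALT_PROBE_SHORT = ProbeGenerator((1, 0, 3, 0, 0))  # "10b00"
ALT_PROBE_FULL = ProbeGenerator((1, 3, 0, 1, 0))   # "1b010"


@dataclass(frozen=True)
class BlockGenerator:
    """Invertible 5x5 generator of a single five-base block.

    ``forward`` maps five bases (row vector) to the block's five data colors:
    columns 1-4 form the adjacent-pair sums ``c_j = b_j + b_{j+1}`` and column
    5 holds the second-stream probe coefficients.  ``inverse`` is the exact
    closed form

        G^-1 = [I_4 | x_{1..4} y^-1 ; 0 | y^-1] L

    with ``L`` lower-triangular all-ones, ``x = L p`` and ``y = x_5`` (the
    GF(4) sum of the probe coefficients); it exists iff ``y != 0``.
    """

    probe: ProbeGenerator
    forward: np.ndarray = field(repr=False)
    inverse: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: int = 0


def build_block_generator(probe: ProbeGenerator) -> BlockGenerator:
    """Construct the block generator and its closed-form inverse for a probe.

    Raises
    ------
    NonInvertibleCodeError
        If the GF(4) sum of the probe coefficients is zero.
    """
    p = np.array(probe.coefficients, dtype=np.uint8)
    x = np.bitwise_xor.reduce(gf4.MUL_TABLE[_L, p[None, :]], axis=1)  # x = L p
    y = int(x[4])
    if y == 0:
        raise NonInvertibleCodeError(
            f"probe generator {probe} is not invertible: the GF(4) sum of its "
            "coefficients is zero, so y = 0 and the block inverse does not exist"
        )
    forward = np.zeros((5, 5), dtype=np.uint8)
    for j in range(4):  # adjacent-pair columns
        forward[j, j] = 1
        forward[j + 1, j] = 1
    forward[:, 4] = p
    y_inv = gf4.inverse(y)
    core = np.zeros((5, 5), dtype=np.uint8)
    for i in range(4):
        core[i, i] = 1
        core[i, 4] = gf4.mul(int(x[i]), y_inv)
    core[4, 4] = y_inv
    inv = gf_matmul(core, _L)
    # Defensive: the closed form must invert the forward matrix exactly.
    assert np.array_equal(gf_matmul(forward, inv), np.eye(5, dtype=np.uint8))
    return BlockGenerator(probe=probe, forward=forward, inverse=inv, x=x, y=y)


def encode_block(bases: np.ndarray, gen: BlockGenerator) -> np.ndarray:
    """Five bases -> five data colors (``b @ G_block``)."""
    bases = np.asarray(bases, dtype=np.uint8)
    if bases.shape != (5,):
        raise ValueError("encode_block expects exactly 5 bases")
    return gf_matvec(bases, gen.forward)


def decode_block(colors: np.ndarray, gen: BlockGenerator) -> np.ndarray:
    """Five data colors -> five bases (``c @ G_block^-1``)."""
    colors = np.asarray(colors, dtype=np.uint8)
    if colors.shape != (5,):
        raise ValueError("decode_block expects exactly 5 data colors")
    return gf_matvec(colors, gen.inverse)


@dataclass(frozen=True)
class CodeSpec:
    """Parameters of a full punctured code instance.

    Parameters
    ----------
    read_length
        Number of bases ``k``; must be a positive multiple of the block
        length 5.
    probe
        Second-stream probe generator (the first stream is always the
        two-base ``rho1``).
    adapter_base
        Known base immediately preceding the read; the platform's CSFASTA
        convention uses T.  It affects only the first color of the stream.
    """

    read_length: int
    probe: ProbeGenerator = ECC_PROBE
    adapter_base: int = gf4.BETA  # 'T'

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.read_length % 5 != 0:
            raise ValueError(
                f"read length must be a positive multiple of 5, got {self.read_length}"
            )
        if self.adapter_base not in (0, 1, 2, 3):
            raise ValueError("adapter base must be a GF(4) element 0-3")

    @property
    def k(self) -> int:
        return self.read_length

    @property
    def n_blocks(self) -> int:
        return self.read_length // 5

    @property
    def n(self) -> int:
        """Total number of color calls: k two-base colors plus k/5 ECC colors."""
        return self.read_length + self.n_blocks

    @lru_cache(maxsize=None)
    def block_generator(self) -> BlockGenerator:  # type: ignore[misc]
        return build_block_generator(self.probe)


@dataclass
class EncodedRead:
    """A read in code space: the two-base color stream plus the ECC stream.

    ``color_stream`` has one color per base; its first element is
    ``adapter + b1``.  ``ecc_stream`` has one color per five-base block.
    The block view (data colors ``c1..c5`` per block, junction parities
    between blocks) is a derived reordering of the same symbols.
    """

    color_stream: np.ndarray
    ecc_stream: np.ndarray

    def __post_init__(self) -> None:
        self.color_stream = np.asarray(self.color_stream, dtype=np.uint8)
        self.ecc_stream = np.asarray(self.ecc_stream, dtype=np.uint8)
        if len(self.color_stream) != 5 * len(self.ecc_stream):
            raise ValueError(
                "color stream must contain exactly five colors per ECC color: "
                f"got {len(self.color_stream)} and {len(self.ecc_stream)}"
            )

    @property
    def k(self) -> int:
        return len(self.color_stream)

    @property
    def n_blocks(self) -> int:
        return len(self.ecc_stream)

    def data_colors(self, block: int) -> np.ndarray:
        """Data colors ``c1..c5`` of 1-based ``block`` (c1-c4 from the color
        stream, c5 from the ECC stream)."""
        i = block - 1
        out = np.empty(5, dtype=np.uint8)
        out[:4] = self.color_stream[5 * i + 1: 5 * i + 5]
        out[4] = self.ecc_stream[i]
        return out

    def junction_color(self, j: int) -> int:
        """Junction parity color ``j`` (0-based; junction 0 is the adapter
        junction, junction j>0 straddles blocks j and j+1)."""
        return int(self.color_stream[5 * j])

    def code_layout(self, spec: CodeSpec) -> np.ndarray:
        """Serialize to the code-layout vector of length ``n``:
        per-block data colors, then junction colors with the known adapter
        offset removed (making the vector a pure linear function of the
        source)."""
        m = self.n_blocks
        out = np.empty(6 * m, dtype=np.uint8)
        for i in range(m):
            out[5 * i: 5 * i + 5] = self.data_colors(i + 1)
        out[5 * m] = self.color_stream[0] ^ spec.adapter_base
        for j in range(1, m):
            out[5 * m + j] = self.color_stream[5 * j]
        return out

    @classmethod
    def from_code_layout(cls, vec: np.ndarray, spec: CodeSpec) -> "EncodedRead":
        vec = np.asarray(vec, dtype=np.uint8)
        m = spec.n_blocks
        if len(vec) != 6 * m:
            raise ValueError(f"code-layout vector must have length {6 * m}, got {len(vec)}")
        cs = np.empty(5 * m, dtype=np.uint8)
        ecc = np.empty(m, dtype=np.uint8)
        cs[0] = vec[5 * m] ^ spec.adapter_base
        for i in range(m):
            cs[5 * i + 1: 5 * i + 5] = vec[5 * i: 5 * i + 4]
            ecc[i] = vec[5 * i + 4]
            if i >= 1:
                cs[5 * i] = vec[5 * m + i]
        return cls(color_stream=cs, ecc_stream=ecc)

    def copy(self) -> "EncodedRead":
        return EncodedRead(self.color_stream.copy(), self.ecc_stream.copy())


def encode_read(bases: np.ndarray, spec: CodeSpec) -> EncodedRead:
    """Encode a base sequence into both streams.

    The color stream is ``prev + b_j`` with ``prev`` the adapter base for the
    first position; the ECC stream dots each five-base block with the second
    probe generator.
    """
    bases = np.asarray(bases, dtype=np.uint8)
    if len(bases) != spec.read_length:
        raise ValueError(
            f"read length {len(bases)} does not match the code spec k={spec.read_length}"
        )
    prev = np.empty_like(bases)
    prev[0] = spec.adapter_base
    prev[1:] = bases[:-1]
    color_stream = prev ^ bases
    p = np.array(spec.probe.coefficients, dtype=np.uint8)
    windows = bases.reshape(spec.n_blocks, 5)
    ecc_stream = np.bitwise_xor.reduce(gf4.MUL_TABLE[windows, p[None, :]], axis=1)
    return EncodedRead(color_stream=color_stream, ecc_stream=ecc_stream)


def naive_decode_colors(color_stream: np.ndarray, adapter_base: int) -> np.ndarray:
    """Decode the two-base color stream alone by running-sum integration.

    This is the classic color-to-base translation with no redundancy: a
    single color miscall corrupts every base from that point on.
    """
    cs = np.asarray(color_stream, dtype=np.uint8)
    out = np.empty_like(cs)
    prev = adapter_base
    for j, c in enumerate(cs):
        prev ^= int(c)
        out[j] = prev
    return out


@dataclass(frozen=True)
class FullGenerator:
    """The full ``k x n`` generator ``[G* | P]`` in code layout.

    ``G*`` is block-diagonal in the block generator; ``P`` holds one column
    per junction parity.  The adapter-junction column touches only base 1 of
    block 1 (the adapter itself is a known constant, removed from the
    layout); every interior junction column has exactly two ones, at base 5
    of one block and base 1 of the next.
    """

    matrix: np.ndarray
    spec: CodeSpec

    @property
    def g_star(self) -> np.ndarray:
        return self.matrix[:, : self.spec.read_length]

    @property
    def parity_columns(self) -> np.ndarray:
        return self.matrix[:, self.spec.read_length:]


def build_full_generator(spec: CodeSpec) -> FullGenerator:
    k, m = spec.read_length, spec.n_blocks
    gen = spec.block_generator()
    G = np.zeros((k, 6 * m), dtype=np.uint8)
    for i in range(m):
        G[5 * i: 5 * i + 5, 5 * i: 5 * i + 5] = gen.forward
    G[0, 5 * m] = 1  # adapter junction: u1 on block 1
    for j in range(1, m):
        G[5 * (j - 1) + 4, 5 * m + j] = 1  # u5 of block j
        G[5 * j, 5 * m + j] = 1            # u1 of block j+1
    return FullGenerator(matrix=G, spec=spec)


def build_parity_check(spec: CodeSpec) -> np.ndarray:
    """Parity-check matrix ``H`` (``n x m``) in code layout.

    Built from the factorisation ``H = [G*^-1 P ; I]``: the top part inverts
    the observed data colors block by block and re-derives the expected
    junction parities; the identity adds the observed parities, so ``x @ H``
    is the syndrome and ``G @ H = 0``.
    """
    k, m = spec.read_length, spec.n_blocks
    full = build_full_generator(spec)
    g_star_inv = np.zeros((k, k), dtype=np.uint8)
    inv = spec.block_generator().inverse
    for i in range(m):
        g_star_inv[5 * i: 5 * i + 5, 5 * i: 5 * i + 5] = inv
    H = np.vstack([gf_matmul(g_star_inv, full.parity_columns), np.eye(m, dtype=np.uint8)])
    return H


def is_valid_codeword(read: EncodedRead, spec: CodeSpec) -> tuple[bool, np.ndarray]:
    """Whether the read is a valid codeword, together with its syndrome."""
    if read.k != spec.read_length:
        raise ValueError(
            f"read length {read.k} does not match the code spec k={spec.read_length}"
        )
    H = build_parity_check(spec)
    syndrome = gf_matvec(read.code_layout(spec), H)
    return bool(not syndrome.any()), syndrome


def enumerate_probe_generators(
    require_first_one: bool = True,
    require_last_zero: bool = True,
    require_invertible: bool = True,
) -> list[ProbeGenerator]:
    """Enumerate candidate second-stream probe generators in lexicographic order.

    The canonical restrictions: the first coefficient is 1 (generators
    beginning with alpha or beta are scalar multiples with identical code
    words, and leading zeros are equivalent to a shifted block boundary); the
    last coefficient is 0 (pentamer ligation accuracy degrades when the final
    probe position is interrogated); and the coefficient sum is nonzero so
    the block generator is invertible.  With all three restrictions the
    family has exactly 48 members.
    """
    out: list[ProbeGenerator] = []
    first_choices = [1] if require_first_one else [0, 1, 2, 3]
    last_choices = [0] if require_last_zero else [0, 1, 2, 3]
    for p1 in first_choices:
        for p2 in range(4):
            for p3 in range(4):
                for p4 in range(4):
                    for p5 in last_choices:
                        if require_invertible and (p1 ^ p2 ^ p3 ^ p4 ^ p5) == 0:
                            continue
                        out.append(ProbeGenerator((p1, p2, p3, p4, p5)))
    return out
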