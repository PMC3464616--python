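"""Arithmetic in the four-element finite field GF(4) and its sequencing alphabets.

In two-base ("color-space") sequencing, nucleotides and fluorophore colors are
two labelings of the same four abstract objects: the elements {0, 1, alpha,
beta} of the finite field GF(4).  Addition acts as the "difference" between
adjacent bases (each color is the GF(4) sum of the two bases a probe
interrogates), and multiplication is needed to build and invert the code's
generator matrices.

Elements are represented internally as the integers 0-3 with

    0 <-> 0,  1 <-> 1,  2 <-> alpha,  3 <-> beta.

Because GF(4) has characteristic 2, addition is bitwise XOR on this
representation; multiplication uses a precomputed 4x4 table.  The standard
sequencing alphabets are fixed bijections onto these integers:

    bases   A C G T  <->  0 1 alpha beta
    colors  0 1 2 3  <->  0 1 alpha beta

Additive error offsets carry a biological interpretation when applied to a
base: +beta complements the nucleotide, +alpha is a transition, +1 preserves
amino/keto class ("transcomplement"), and +0 is the identity.  These labels
are pure metadata and never enter the arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ZERO",
    "ONE",
    "ALPHA",
    "BETA",
    "ADD_TABLE",
    "MUL_TABLE",
    "add",
    "mul",
    "inverse",
    "gf_matmul",
    "gf_matvec",
    "ERROR_TYPE_LABELS",
    "error_type_label",
    "BASES",
    "COLORS",
    "GF_SYMBOLS",
    "bases_to_gf",
    "gf_to_bases",
    "colors_to_gf",
    "gf_to_colors",
    "convert",
    "AlphabetError",
]

ZERO, ONE, ALPHA, BETA = 0, 1, 2, 3

# 4x4 Cayley tables.  Addition is XOR (characteristic 2); the multiplication
# table realises the cyclic group of order 3 on {1, alpha, beta}:
# alpha*alpha = beta, alpha*beta = 1, beta*beta = alpha.
ADD_TABLE = np.array(
    [[0, 1, 2, 3],
     [1, 0, 3, 2],
     [2, 3, 0, 1],
     [3, 2, 1, 0]], dtype=np.uint8)

MUL_TABLE = np.array(
    [[0, 0, 0, 0],
     [0, 1, 2, 3],
     [0, 2, 3, 1],
     [0, 3, 1, 2]], dtype=np.uint8)

_INVERSE = {1: 1, 2: 3, 3: 2}


class AlphabetError(ValueError):
    """A character does not belong to the expected alphabet."""


def add(a: int, b: int) -> int:
    """GF(4) addition (== subtraction; the field has characteristic 2)."""
    return a ^ b


def mul(a: int, b: int) -> int:
    """GF(4) multiplication."""
    return int(MUL_TABLE[a, b])


def inverse(a: int) -> int:
    """Multiplicative inverse of a nonzero element.

    Raises
    ------
    ZeroDivisionError
        If ``a`` is the zero element, which has no inverse.
    """
    if a == 0:
        raise ZeroDivisionError("the zero element of GF(4) has no multiplicative inverse")
    return _INVERSE[a]


def gf_matvec(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Row-vector times matrix over GF(4): ``v @ m`` with field arithmetic."""
    v = np.asarray(v, dtype=np.uint8)
    m = np.asarray(m, dtype=np.uint8)
    prod = MUL_TABLE[v[:, None], m]  # (len(v), ncols)
    return np.bitwise_xor.reduce(prod, axis=0)


def gf_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix product over GF(4)."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    prod = MUL_TABLE[a[:, :, None], b[None, :, :]]  # (ra, ca, cb)
    return np.bitwise_xor.reduce(prod, axis=1)


ERROR_TYPE_LABELS = {
    ZERO: "identity",
    ONE: "transcomplement",
    ALPHA: "transition",
    BETA: "complement",
}


def error_type_label(offset: int) -> str:
    """Biological name of the additive error offset (metadata only)."""
    return ERROR_TYPE_LABELS[offset]


# ---------------------------------------------------------------------------
# Alphabet maps
# ---------------------------------------------------------------------------

BASES = "ACGT"
COLORS = "0123"
GF_SYMBOLS = "01ab"  # ASCII rendering of 0, 1, alpha, beta

_BASE_TO_GF = {c: i for i, c in enumerate(BASES)}
_COLOR_TO_GF = {c: i for i, c in enumerate(COLORS)}


def _encode(seq: str, table: dict[str, int], alphabet_name: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for pos, ch in enumerate(seq):
        try:
            out[pos] = table[ch.upper() if alphabet_name == "base" else ch]
        except KeyError:
            raise AlphabetError(
                f"invalid {alphabet_name} character {ch!r} at position {pos + 1}"
            ) from None
    return out


def bases_to_gf(seq: str) -> np.ndarray:
    """Nucleotide string -> GF(4) vector.  Case-insensitive; ambiguity codes rejected."""
    return _encode(seq, _BASE_TO_GF, "base")


def gf_to_bases(vec: np.ndarray) -> str:
    return "".join(BASES[int(x)] for x in vec)


def colors_to_gf(seq: str) -> np.ndarray:
    """Color-digit string -> GF(4) vector."""
    return _encode(seq, _COLOR_TO_GF, "color")


def gf_to_colors(vec: np.ndarray) -> str:
    return "".join(COLORS[int(x)] for x in vec)


def gf_to_symbols(vec) -> str:
    """Render a GF(4) vector in the abstract alphabet ``0 1 a b``."""
    return "".join(GF_SYMBOLS[int(x)] for x in np.atleast_1d(vec))


def convert(symbol: str, alphabet: str, direction: str = "to-field"):
    """Convert a single character between an alphabet and GF(4).

    Parameters
    ----------
    symbol
        One character (or, for ``from-field``, an integer element 0-3).
    alphabet
        ``"base"`` or ``"color"``.
    direction
        ``"to-field"`` maps the character to a field element (int 0-3);
        ``"from-field"`` maps a field element back to the character.
    """
    if alphabet not in ("base", "color"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    letters = BASES if alphabet == "base" else COLORS
    if direction == "to-field":
        table = _BASE_TO_GF if alphabet == "base" else _COLOR_TO_GF
        key = symbol.upper() if alphabet == "base" else symbol
        if key not in table:
            raise AlphabetError(f"invalid {alphabet} character {symbol!r} at position 1")
        return table[key]
    if direction == "from-field":
        return letters[int(symbol)]
    raise ValueError(f"unknown direction {direction!r}")
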