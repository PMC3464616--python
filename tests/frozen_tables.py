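"""Frozen expected values for the published code-analysis tables.

Syndrome pairs are written in the abstract GF(4) alphabet ``0 1 a b``;
positions run p-, c1..c5, p+.  Patterns are per-unit-offset: an error type
``+t`` induces ``t`` times the listed pattern at every affected position.
"""

# GF(4) addition and multiplication tables (element order 0, 1, a, b).
GF4_ADD = [
    [0, 1, 2, 3],
    [1, 0, 3, 2],
    [2, 3, 0, 1],
    [3, 2, 1, 0],
]
GF4_MUL = [
    [0, 0, 0, 0],
    [0, 1, 2, 3],
    [0, 2, 3, 1],
    [0, 3, 1, 2],
]

# Single-error syndromes per generator: {offset: {position: "ud"}}.
SYNDROMES = {
    "1b0b0": {
        3: {"p-": "b0", "c1": "0b", "c2": "a1", "c3": "a1", "c4": "0b", "c5": "bb", "p+": "0b"},
        2: {"p-": "a0", "c1": "0a", "c2": "1b", "c3": "1b", "c4": "0a", "c5": "aa", "p+": "0a"},
        1: {"p-": "10", "c1": "01", "c2": "ba", "c3": "ba", "c4": "01", "c5": "11", "p+": "01"},
    },
    "10b00": {
        3: {"p-": "b0", "c1": "1a", "c2": "1a", "c3": "0b", "c4": "0b", "c5": "aa", "p+": "0b"},
        2: {"p-": "a0", "c1": "b1", "c2": "b1", "c3": "0a", "c4": "0a", "c5": "11", "p+": "0a"},
        1: {"p-": "10", "c1": "ab", "c2": "ab", "c3": "01", "c4": "01", "c5": "bb", "p+": "01"},
    },
    "1b010": {
        3: {"p-": "b0", "c1": "a1", "c2": "1a", "c3": "1a", "c4": "0b", "c5": "11", "p+": "0b"},
        2: {"p-": "a0", "c1": "1b", "c2": "b1", "c3": "b1", "c4": "0a", "c5": "bb", "p+": "0a"},
        1: {"p-": "10", "c1": "ba", "c2": "ab", "c3": "ab", "c4": "01", "c5": "aa", "p+": "01"},
    },
}

# Equivalence-class partitions of the block positions {c1..c5, p+}
# (type-independent: syndromes scale linearly with the offset).
EQUIVALENCE_CLASSES = {
    "1b0b0": [("c5",), ("c2", "c3"), ("c1", "c4", "p+")],
    "10b00": [("c5",), ("c1", "c2"), ("c3", "c4", "p+")],
    "1b010": [("c1",), ("c5",), ("c2", "c3"), ("c4", "p+")],
}

# Unused nonzero syndrome pairs per generator.
UNUSED_SYNDROMES = {
    "1b0b0": {"ab", "b1", "1a"},
    "10b00": {"1b", "a1", "ba"},
    "1b010": set(),
}

# Miscorrection patterns: (true_pos, corrected_pos) -> (multiplicity, unit pattern).
MISCORRECTION_PATTERNS = {
    "1b0b0": {
        ("c2", "c3"): ("single", "00100"),
        ("c4", "p+"): ("single", "00001"),
        ("c1", "c4"): ("triple", "01110"),
        ("c1", "p+"): ("quadruple", "01111"),
    },
    "10b00": {
        ("c1", "c2"): ("single", "01000"),
        ("c3", "c4"): ("single", "00010"),
        ("c3", "p+"): ("double", "00011"),
        ("c4", "p+"): ("single", "00001"),
    },
    "1b010": {
        ("c2", "c3"): ("single", "00100"),
        ("c4", "p+"): ("single", "00001"),
    },
}

# Worked block-encoding example: ACGAT <-> colors 13233 under 1b0b0.
WORKED_BLOCK = ("ACGAT", "13233")

# Printed block generator and inverse for the 1b0b0 probe.
ECC_G_BLOCK = [
    [1, 0, 0, 0, 1],
    [1, 1, 0, 0, 3],
    [0, 1, 1, 0, 0],
    [0, 0, 1, 1, 3],
    [0, 0, 0, 1, 0],
]
ECC_G_BLOCK_INV = [
    [0, 1, 1, 1, 1],
    [3, 3, 2, 2, 2],
    [3, 3, 3, 2, 2],
    [0, 0, 0, 0, 1],
    [1, 1, 1, 1, 1],
]
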