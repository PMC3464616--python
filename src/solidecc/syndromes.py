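"""Syndrome analysis and hard-decision decoding for the block code.

A miscall of additive offset ``t`` at a color position changes at most the
two junction parities overlapping its block, so the error-correcting
behaviour of the whole code reduces to a block-local analysis: each block
sees an (upstream, downstream) syndrome pair, and single-color errors at the
seven positions ``p-, c1..c5, p+`` partition into equivalence classes by the
pair they induce.  Singleton classes are unambiguously correctable;
multi-member classes are detectable but ambiguous, and a wrong choice of
correction induces a characteristic base-space *miscorrection pattern*
``(e1 + e2) G_block^-1`` that never depends on the underlying sequence.

Junction parities are shared between adjacent blocks: the parity upstream of
a block (its ``p-``) is the same physical color as the downstream parity
(``p+``) of the previous block.  Throughout, junction errors are attributed
to the earlier block's ``p+``; the adapter junction preceding block 1 is the
only junction owned as a ``p-`` (by block 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import gf4
from .codebuild import BlockGenerator, CodeSpec, EncodedRead, decode_block

__all__ = [
    "POSITIONS",
    "BLOCK_POSITIONS",
    "NotConfusableError",
    "compute_syndrome",
    "single_error_syndrome",
    "EquivalenceClass",
    "equivalence_classes",
    "unused_syndromes",
    "MiscorrectionPattern",
    "miscorrection_pattern",
    "SyndromeTable",
    "build_syndrome_table",
    "SyndromeDecodeResult",
    "syndrome_decode",
]

# All seven single-error positions a block sees; BLOCK_POSITIONS are the six
# it owns (p- belongs to the previous block, except for block 1).
POSITIONS = ("p-", "c1", "c2", "c3", "c4", "c5", "p+")
BLOCK_POSITIONS = ("c1", "c2", "c3", "c4", "c5", "p+")

MULTIPLICITY_LABELS = {1: "single", 2: "double", 3: "triple", 4: "quadruple", 5: "quintuple"}


class NotConfusableError(ValueError):
    """Two positions do not share a syndrome equivalence class."""


def single_error_syndrome(position: str, offset: int, gen: BlockGenerator) -> tuple[int, int]:
    """(upstream, downstream) syndrome pair induced by one error of additive
    ``offset`` at ``position``.

    A data-color error perturbs the block's putative decoding by ``offset``
    times the corresponding row of the block inverse; only the decoded first
    and last bases enter the two junction checks.  A parity-color error
    leaves the decoding untouched and shows up verbatim in its own check.
    """
    if position not in POSITIONS:
        raise ValueError(f"unknown position {position!r}; expected one of {POSITIONS}")
    if offset not in (0, 1, 2, 3):
        raise ValueError("error offset must be a GF(4) element 0-3")
    if position == "p-":
        return (offset, 0)
    if position == "p+":
        return (0, offset)
    j = int(position[1]) - 1
    row = gen.inverse[j]
    return (gf4.mul(offset, int(row[0])), gf4.mul(offset, int(row[4])))


@dataclass(frozen=True)
class EquivalenceClass:
    """Positions sharing one (upstream, downstream) syndrome pair for one
    error type.  Singleton classes are the unambiguously correctable ones."""

    offset: int
    positions: tuple[str, ...]
    syndrome: tuple[int, int]

    @property
    def label(self) -> str:
        return gf4.error_type_label(self.offset)

    @property
    def ambiguous(self) -> bool:
        return len(self.positions) > 1


def equivalence_classes(gen: BlockGenerator, include_upstream_parity: bool = False) -> list[EquivalenceClass]:
    """Group single-error positions by shared syndrome pair, per error type.

    By default only the six block-owned positions ``c1..c5, p+`` are
    partitioned (``p-`` duplicates the previous block's ``p+``).
    """
    positions = POSITIONS if include_upstream_parity else BLOCK_POSITIONS
    out: list[EquivalenceClass] = []
    for offset in (3, 2, 1):  # complement, transition, transcomplement
        groups: dict[tuple[int, int], list[str]] = {}
        for pos in positions:
            pair = single_error_syndrome(pos, offset, gen)
            groups.setdefault(pair, []).append(pos)
        for pair in sorted(groups):
            out.append(EquivalenceClass(offset=offset, positions=tuple(groups[pair]), syndrome=pair))
    return out


def unused_syndromes(gen: BlockGenerator) -> set[tuple[int, int]]:
    """The nonzero (upstream, downstream) pairs no single-color error produces.

    Of the 15 nonzero pairs, a code that leaves some unused wastes syndrome
    space it could have spent splitting ambiguous classes.
    """
    seen = {
        single_error_syndrome(pos, offset, gen)
        for pos in POSITIONS
        for offset in (1, 2, 3)
    }
    all_pairs = {(u, d) for u in range(4) for d in range(4)} - {(0, 0)}
    return all_pairs - seen


@dataclass(frozen=True)
class MiscorrectionPattern:
    """Base-space error pattern induced by correcting at the wrong position."""

    pattern: tuple[int, int, int, int, int]
    offset: int
    positions: tuple[str, str]

    @property
    def weight(self) -> int:
        return sum(1 for x in self.pattern if x)

    @property
    def multiplicity(self) -> str:
        return MULTIPLICITY_LABELS[self.weight]

    def __str__(self) -> str:
        return gf4.gf_to_symbols(np.array(self.pattern))


def _data_color_difference(position: str, offset: int) -> np.ndarray:
    d = np.zeros(5, dtype=np.uint8)
    if position.startswith("c"):
        d[int(position[1]) - 1] = offset
    return d


def miscorrection_pattern(
    true_pos: str, corrected_pos: str, offset: int, gen: BlockGenerator
) -> MiscorrectionPattern:
    """Pattern of base errors left behind when an error of type ``offset`` at
    ``true_pos`` is "corrected" at ``corrected_pos`` of the same equivalence
    class.

    The data-color difference ``d = e1 + e2`` passes through the block
    inverse: ``pattern = d @ G_block^-1``.  Parity positions contribute
    nothing to ``d`` (they are not used to call the block), and the result is
    independent of the underlying sequence.
    """
    if offset == 0:
        raise ValueError("the identity offset induces no pattern")
    s1 = single_error_syndrome(true_pos, offset, gen)
    s2 = single_error_syndrome(corrected_pos, offset, gen)
    if true_pos == corrected_pos or s1 != s2:
        raise NotConfusableError(
            f"positions {true_pos} and {corrected_pos} are not confusable for "
            f"error type +{gf4.GF_SYMBOLS[offset]} (syndromes "
            f"{gf4.gf_to_symbols(np.array(s1))} vs {gf4.gf_to_symbols(np.array(s2))})"
        )
    d = _data_color_difference(true_pos, offset) ^ _data_color_difference(corrected_pos, offset)
    pattern = gf4.gf_matvec(d, gen.inverse)
    return MiscorrectionPattern(
        pattern=tuple(int(x) for x in pattern),
        offset=offset,
        positions=(true_pos, corrected_pos),
    )


# ---------------------------------------------------------------------------
# Syndrome table and hard-decision decoding
# ---------------------------------------------------------------------------

ErrorAssignment = tuple[tuple[str, int], ...]  # ((position, offset), ...)


@dataclass
class SyndromeTable:
    """Block-local map from (upstream, downstream) syndrome pairs to the
    minimal-weight in-block error assignments producing them.

    Built by enumerating all single errors over the seven block positions,
    then doublets, up to ``max_weight``; an entry keeps only the assignments
    of minimal weight and is flagged ambiguous when several remain.
    """

    gen: BlockGenerator
    max_weight: int
    entries: dict[tuple[int, int], list[ErrorAssignment]] = field(default_factory=dict)

    def candidates(self, pair: tuple[int, int]) -> list[ErrorAssignment]:
        return self.entries.get(pair, [])

    def is_ambiguous(self, pair: tuple[int, int]) -> bool:
        return len(self.entries.get(pair, [])) > 1

    def weight(self, pair: tuple[int, int]) -> int | None:
        cands = self.entries.get(pair)
        return len(cands[0]) if cands else None


def _assignment_syndrome(assignment: ErrorAssignment, gen: BlockGenerator) -> tuple[int, int]:
    u = d = 0
    for pos, t in assignment:
        su, sd = single_error_syndrome(pos, t, gen)
        u ^= su
        d ^= sd
    return (u, d)


def build_syndrome_table(spec: CodeSpec | BlockGenerator, max_weight: int = 2) -> SyndromeTable:
    """Enumerate in-block errors of weight 1..``max_weight`` and index them by
    syndrome pair, keeping minimal-weight assignments only."""
    gen = spec if isinstance(spec, BlockGenerator) else spec.block_generator()
    if max_weight < 1:
        raise ValueError("max_weight must be at least 1")
    table = SyndromeTable(gen=gen, max_weight=max_weight)
    table.entries[(0, 0)] = [()]  # clean block: the empty error, unambiguous
    for weight in range(1, max_weight + 1):
        for pos_combo in combinations(POSITIONS, weight):
            for offsets in np.ndindex(*(3,) * weight):
                assignment = tuple((p, int(t) + 1) for p, t in zip(pos_combo, offsets))
                pair = _assignment_syndrome(assignment, gen)
                existing = table.entries.get(pair)
                if existing is None:
                    table.entries[pair] = [assignment]
                elif len(existing[0]) == weight:
                    existing.append(assignment)
                # heavier than an existing entry: not minimal, drop
    return table


@dataclass
class SyndromeDecodeResult:
    """Outcome of hard-decision decoding of one read."""

    read: EncodedRead                 # corrected color streams
    bases: np.ndarray                 # decoded base sequence, length k
    block_status: list[str]           # per block: clean|corrected|ambiguous|uncorrectable
    block_candidates: list[list[ErrorAssignment]]
    syndrome: np.ndarray              # syndrome of the *observed* read

    @property
    def is_valid(self) -> bool:
        return all(s != "uncorrectable" for s in self.block_status)


def compute_syndrome(read: EncodedRead, spec: CodeSpec) -> np.ndarray:
    """Syndrome of an observed read: one GF(4) component per junction parity.

    Component ``j`` compares the observed junction color with the one
    recomputed from the block-wise putative decoding (the adapter junction,
    ``j = 0``, uses the known adapter base).  All components are zero iff the
    read is a valid codeword.
    """
    if read.k != spec.read_length:
        raise ValueError(
            f"read length {read.k} does not match the code spec k={spec.read_length}"
        )
    gen = spec.block_generator()
    m = spec.n_blocks
    putative = [decode_block(read.data_colors(i + 1), gen) for i in range(m)]
    syndrome = np.empty(m, dtype=np.uint8)
    syndrome[0] = read.junction_color(0) ^ spec.adapter_base ^ int(putative[0][0])
    for j in range(1, m):
        syndrome[j] = read.junction_color(j) ^ int(putative[j - 1][4]) ^ int(putative[j][0])
    return syndrome


def _apply_correction(read: EncodedRead, block: int, assignment: ErrorAssignment) -> None:
    """Subtract an in-block error assignment from the observed colors
    (GF(4) subtraction == addition).  ``block`` is 1-based."""
    i = block - 1
    for pos, t in assignment:
        if pos == "p-":
            read.color_stream[5 * i] ^= t
        elif pos == "p+":
            read.color_stream[5 * (i + 1)] ^= t
        elif pos == "c5":
            read.ecc_stream[i] ^= t
        else:
            read.color_stream[5 * i + int(pos[1])] ^= t


_SIG_CACHE: dict[tuple, dict] = {}


def _inblock_signatures(probe_coeffs: tuple[int, ...], max_weight: int, gen: BlockGenerator):
    """Map (upstream, downstream) signature -> (weight, minimal data-color-only
    assignments over c1..c5).  Junction errors are handled separately by the
    chain decoder, so only in-block data errors appear here."""
    key = (probe_coeffs, max_weight)
    if key in _SIG_CACHE:
        return _SIG_CACHE[key]
    sigs: dict[tuple[int, int], tuple[int, list[ErrorAssignment]]] = {(0, 0): (0, [()])}
    data_positions = ("c1", "c2", "c3", "c4", "c5")
    for weight in range(1, max_weight + 1):
        for pos_combo in combinations(data_positions, weight):
            for offsets in np.ndindex(*(3,) * weight):
                a = tuple((p, int(t) + 1) for p, t in zip(pos_combo, offsets))
                pair = _assignment_syndrome(a, gen)
                entry = sigs.get(pair)
                if entry is None:
                    sigs[pair] = (weight, [a])
                elif entry[0] == weight:
                    entry[1].append(a)
    _SIG_CACHE[key] = sigs
    return sigs


def _pair_candidates(
    table: SyndromeTable, pair: tuple[int, int] | None, up: int, block: int, m: int
) -> list[ErrorAssignment]:
    """Single-block candidate list for status reporting (the Table-2 view)."""
    if pair is not None:
        cands = table.candidates(pair)
    else:
        # Final block: match on the upstream component alone; p+ does not exist.
        best_w: int | None = None
        cands = []
        for p, assigns in sorted(table.entries.items()):
            if p[0] != up:
                continue
            for a in assigns:
                if any(pos == "p+" for pos, _ in a):
                    continue
                if best_w is None or len(a) < best_w:
                    best_w, cands = len(a), [a]
                elif len(a) == best_w:
                    cands.append(a)
    if block > 1:  # p- duplicates the previous block's p+
        cands = [a for a in cands if all(pos != "p-" for pos, _ in a)]
    return cands


def syndrome_decode(
    read: EncodedRead,
    spec: CodeSpec,
    table: SyndromeTable | None = None,
    qualities: np.ndarray | None = None,
) -> SyndromeDecodeResult:
    """Hard-decision decoding: find the minimal-weight error explaining the
    observed syndrome and subtract it.

    Because in-block errors couple the two junction parities flanking their
    block, the minimal-weight explanation is found by dynamic programming
    along the junction chain (state: the downstream syndrome contribution of
    the current block's in-block errors; junction miscalls are free variables
    of weight 1).  This corrects errors in distinct blocks independently and
    attributes each junction error to the earlier block's ``p+``.

    Weight ties are the hard-information ambiguity of the code.  When
    ``qualities`` (per-color error probabilities, color stream then ECC
    stream) are supplied, ties are broken toward the explanation whose
    touched colors were most likely to be miscalled (maximum summed log
    odds); otherwise the first candidate in deterministic position order is
    applied.  Either way the result is a valid codeword.

    Per-block status: ``clean`` (no correction owned by the block),
    ``corrected`` (unique single-block explanation), ``ambiguous``
    (equivalence class with several members — the full candidate set is
    reported), or ``uncorrectable`` (the block's syndrome pair matches no
    table entry at the table's maximum weight; a best-effort correction is
    still applied).  The final block has only an upstream syndrome, so
    errors there whose upstream component is zero are invisible.
    """
    if table is None:
        table = build_syndrome_table(spec)
    observed_syndrome = compute_syndrome(read, spec)
    corrected = read.copy()
    gen = spec.block_generator()
    m = spec.n_blocks
    k = spec.read_length

    if not observed_syndrome.any():
        bases = np.concatenate(
            [decode_block(corrected.data_colors(i + 1), gen) for i in range(m)]
        )
        return SyndromeDecodeResult(
            read=corrected,
            bases=bases,
            block_status=["clean"] * m,
            block_candidates=[[()] for _ in range(m)],
            syndrome=observed_syndrome,
        )

    sigs = _inblock_signatures(spec.probe.coefficients, table.max_weight, gen)
    sigma = [int(s) for s in observed_syndrome]

    if qualities is not None:
        eps = np.clip(np.asarray(qualities, dtype=float), 1e-12, 1 - 1e-12)
        log_odds = np.log(eps / (1.0 - eps))
    else:
        log_odds = np.zeros(k + m)

    def assignment_gain(block: int, a: ErrorAssignment) -> float:
        i = block - 1
        g = 0.0
        for pos, _ in a:
            g += log_odds[k + i] if pos == "c5" else log_odds[5 * i + int(pos[1])]
        return g

    INF = float("inf")

    # Backward pass, weight only: B[i][d] = min weight for blocks i+1..m given
    # that block i's in-block errors contribute d to junction i.
    B = [[0] * 4 for _ in range(m + 1)]  # B[m][d] = 0
    sig_items = sorted(sigs.items())
    for i in range(m - 1, 0, -1):
        for d in range(4):
            best = INF
            for (u, d2), (w, _) in sig_items:
                t = sigma[i] ^ d ^ u
                c = w + (1 if t else 0) + B[i + 1][d2]
                if c < best:
                    best = c
            B[i][d] = best

    # Forward pass with full cost (weight, -gain); backpointers per state.
    # F maps state d -> (weight, neg_gain, backptr) where backptr is
    # (prev_d, assignment, junction_t_before_block).
    F: list[dict[int, tuple[float, float, tuple | None]]] = [dict() for _ in range(m + 1)]
    F[0] = {0: (0.0, 0.0, None)}
    for i in range(1, m + 1):
        cur: dict[int, tuple[float, float, tuple | None]] = {}
        for prev_d, (pw, pg, _) in sorted(F[i - 1].items()):
            for (u, d2), (w, assigns) in sig_items:
                t = sigma[i - 1] ^ prev_d ^ u
                base_w = pw + w + (1 if t else 0)
                jg = -log_odds[5 * (i - 1)] if t else 0.0
                for a in assigns:
                    cost = (base_w, pg + jg - assignment_gain(i, a))
                    old = cur.get(d2)
                    if old is None or cost < (old[0], old[1]):
                        cur[d2] = (cost[0], cost[1], (prev_d, a, t))
        F[i] = cur

    final_d = min(F[m], key=lambda d: (F[m][d][0], F[m][d][1], d))
    opt_weight = F[m][final_d][0]

    # Backtrack the chosen solution.
    chosen_a: list[ErrorAssignment] = [()] * (m + 1)  # 1-based blocks
    junction_t = [0] * m
    d = final_d
    for i in range(m, 0, -1):
        _, _, bp = F[i][d]
        prev_d, a, t = bp
        chosen_a[i] = a
        junction_t[i - 1] = t
        d = prev_d

    # Apply corrections.
    for i in range(1, m + 1):
        _apply_correction(corrected, i, chosen_a[i])
    for j, t in enumerate(junction_t):
        if t:
            corrected.color_stream[5 * j] ^= t

    # Per-block status and candidate reporting (single-block, Table-2 view).
    statuses: list[str] = []
    all_candidates: list[list[ErrorAssignment]] = []
    for i in range(1, m + 1):
        owned: list[tuple[str, int]] = list(chosen_a[i])
        if i == 1 and junction_t[0]:
            owned.append(("p-", junction_t[0]))
        if i < m and junction_t[i]:
            owned.append(("p+", junction_t[i]))
        up = sigma[i - 1]
        pair = (up, sigma[i]) if i < m else None
        if not owned:
            statuses.append("clean")
            all_candidates.append([()])
            continue
        cands = _pair_candidates(table, pair, up, i, m)
        if not cands:
            statuses.append("uncorrectable")
        elif len(cands) > 1:
            statuses.append("ambiguous")
        else:
            statuses.append("corrected")
        all_candidates.append(cands)

    bases = np.concatenate(
        [decode_block(corrected.data_colors(i + 1), gen) for i in range(m)]
    )
    return SyndromeDecodeResult(
        read=corrected,
        bases=bases,
        block_status=statuses,
        block_candidates=all_candidates,
        syndrome=observed_syndrome,
    )
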