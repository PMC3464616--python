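"""Soft-information decoding on the encoder trellis.

The encoder is a finite-state machine whose state is the last four bases of
the source sequence (256 states): appending a base emits the two-base color
(with the previous base, or the known adapter base at the first position)
and, every fifth step, the ECC color of the just-completed block.  Decoding
is dynamic programming on this trellis:

* ``viterbi_decode`` returns the single base sequence maximising the joint
  likelihood of all ``k + k/5`` observed colors (maximum likelihood);
* ``posterior_decode`` runs the forward-backward algorithm to obtain, for
  every position, the exact marginal posterior over the four bases under a
  uniform prior on source sequences (per-position maximum a posteriori).

The observation model treats each color call independently: a call of
quality ``Q`` is wrong with probability ``eps = 10^(-Q/10)``, and a wrong
call is uniform over the three other colors.  Missing calls (rendered ``.``
in CSFASTA) contribute a flat likelihood.  All accumulation is in the log
domain; error probabilities are clamped to ``[1e-10, 1 - 1e-10]`` so that
degenerate qualities cannot produce infinite log terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codebuild import CodeSpec, EncodedRead, encode_read

__all__ = [
    "MISSING",
    "ObservationModel",
    "PosteriorCall",
    "viterbi_decode",
    "posterior_decode",
    "posterior_to_phred",
    "sequence_loglik",
]

MISSING = 4  # sentinel color value for a '.' (no-call) in the observed read

_EPS_FLOOR = 1e-10
PHRED_CAP = 60


@dataclass
class ObservationModel:
    """Per-color error probabilities for one read.

    ``color_eps`` has one entry per two-base-stream color (length k) and
    ``ecc_eps`` one per ECC color (length k/5).  The likelihood of observing
    color ``o`` when ``e`` was emitted is ``1 - eps`` if ``o == e`` and
    ``eps / 3`` otherwise.
    """

    color_eps: np.ndarray
    ecc_eps: np.ndarray

    def __post_init__(self) -> None:
        self.color_eps = np.clip(np.asarray(self.color_eps, dtype=float), _EPS_FLOOR, 1 - _EPS_FLOOR)
        self.ecc_eps = np.clip(np.asarray(self.ecc_eps, dtype=float), _EPS_FLOOR, 1 - _EPS_FLOOR)
        if len(self.color_eps) != 5 * len(self.ecc_eps):
            raise ValueError("color_eps must contain five entries per ecc_eps entry")

    @classmethod
    def from_phred(cls, color_quals: np.ndarray, ecc_quals: np.ndarray) -> "ObservationModel":
        """Build from Phred qualities: ``eps = 10^(-Q/10)``."""
        return cls(
            color_eps=10.0 ** (-np.asarray(color_quals, dtype=float) / 10.0),
            ecc_eps=10.0 ** (-np.asarray(ecc_quals, dtype=float) / 10.0),
        )

    @classmethod
    def uniform(cls, k: int, quality: float) -> "ObservationModel":
        eps = 10.0 ** (-quality / 10.0)
        return cls(color_eps=np.full(k, eps), ecc_eps=np.full(k // 5, eps))

    def concatenated_eps(self) -> np.ndarray:
        """Error probabilities in stream order (color stream, then ECC stream),
        as consumed by the quality-aware syndrome decoder."""
        return np.concatenate([self.color_eps, self.ecc_eps])


def _emission_tables(
    observed: EncodedRead, model: ObservationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood of each possible emitted color, per observed position.

    Returns ``(color_ll, ecc_ll)`` of shapes (k, 4) and (m, 4); missing
    observations get a flat 0 row.
    """

    def table(obs: np.ndarray, eps: np.ndarray) -> np.ndarray:
        ll = np.empty((len(obs), 4))
        miss = np.log(eps / 3.0)
        hit = np.log1p(-eps)
        ll[:] = miss[:, None]
        present = obs != MISSING
        ll[present, obs[present]] = hit[present]
        ll[~present, :] = 0.0
        return ll

    return table(observed.color_stream, model.color_eps), table(observed.ecc_stream, model.ecc_eps)


def _check_lengths(observed: EncodedRead, model: ObservationModel, spec: CodeSpec) -> None:
    if observed.k != spec.read_length or len(model.color_eps) != spec.read_length:
        raise ValueError(
            f"observed read ({observed.k} colors), model ({len(model.color_eps)}) and "
            f"code spec (k={spec.read_length}) disagree on read length"
        )


def viterbi_decode(
    observed: EncodedRead, model: ObservationModel, spec: CodeSpec
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood base sequence and its log-likelihood.

    Ties (which require exactly equal floating-point path scores) are broken
    toward the lexicographically smallest sequence under A < C < G < T, so
    decoding is fully deterministic.
    """
    _check_lengths(observed, model, spec)
    color_ll, ecc_ll = _emission_tables(observed, model)
    probe = spec.probe.coefficients
    from .gf4 import MUL_TABLE

    # state -> (score, path); state is the tuple of the last up-to-4 bases
    states: dict[tuple[int, ...], tuple[float, tuple[int, ...]]] = {(): (0.0, ())}
    for j in range(spec.read_length):
        nxt: dict[tuple[int, ...], tuple[float, tuple[int, ...]]] = {}
        block_end = (j + 1) % 5 == 0
        for state in sorted(states):
            score, path = states[state]
            prev = state[-1] if state else spec.adapter_base
            for b in range(4):
                s = score + color_ll[j, prev ^ b]
                if block_end:
                    window = path[-4:] + (b,)
                    ecc = 0
                    for base, coeff in zip(window, probe):
                        ecc ^= MUL_TABLE[base, coeff]
                    s += ecc_ll[j // 5, ecc]
                key = (state + (b,))[-4:]
                new_path = path + (b,)
                best = nxt.get(key)
                if best is None or s > best[0] or (s == best[0] and new_path < best[1]):
                    nxt[key] = (s, new_path)
        states = nxt
    score, path = max(states.values(), key=lambda sp: (sp[0], tuple(-x for x in sp[1])))
    return np.array(path, dtype=np.uint8), score


@dataclass
class PosteriorCall:
    """Per-position posterior distributions, calls, and Phred qualities."""

    probabilities: np.ndarray  # (k, 4), rows sum to 1
    calls: np.ndarray          # argmax base per position
    quals: np.ndarray          # Phred-scaled quality of each call


def posterior_decode(
    observed: EncodedRead, model: ObservationModel, spec: CodeSpec
) -> PosteriorCall:
    """Exact per-position marginal posteriors by forward-backward.

    The prior over source sequences is uniform, so posteriors are the
    likelihood-weighted fraction of the 4^k sequences carrying each base at
    each position; the trellis computes this exactly in O(k * 256 * 4).
    """
    _check_lengths(observed, model, spec)
    color_ll, ecc_ll = _emission_tables(observed, model)
    probe = spec.probe.coefficients
    from .gf4 import MUL_TABLE
    k = spec.read_length

    def step_scores(j: int, state: tuple[int, ...]) -> list[tuple[tuple[int, ...], float]]:
        prev = state[-1] if state else spec.adapter_base
        block_end = (j + 1) % 5 == 0
        out = []
        for b in range(4):
            s = color_ll[j, prev ^ b]
            if block_end:
                window = state[-4:] + (b,)
                ecc = 0
                for base, coeff in zip(window, probe):
                    ecc ^= MUL_TABLE[base, coeff]
                s += ecc_ll[j // 5, ecc]
            out.append(((state + (b,))[-4:], s))
        return out

    # Forward pass: fw[j][state] = logsum over prefixes of length j+1 ending in state.
    fw: list[dict[tuple[int, ...], float]] = []
    cur: dict[tuple[int, ...], float] = {(): 0.0}
    for j in range(k):
        nxt: dict[tuple[int, ...], float] = {}
        for state, lp in cur.items():
            for key, s in step_scores(j, state):
                tot = lp + s
                if key in nxt:
                    nxt[key] = np.logaddexp(nxt[key], tot)
                else:
                    nxt[key] = tot
        fw.append(nxt)
        cur = nxt

    # Backward pass: bw[j][state] = logsum over suffixes after position j,
    # given the state (last <=4 bases) at time j+1.
    bw: list[dict[tuple[int, ...], float]] = [dict.fromkeys(fw[-1], 0.0)]
    for j in range(k - 1, 0, -1):
        prev_states = fw[j - 1]
        cur_bw = bw[0]
        nxt_bw: dict[tuple[int, ...], float] = {}
        for state, _ in prev_states.items():
            acc = -np.inf
            for key, s in step_scores(j, state):
                acc = np.logaddexp(acc, s + cur_bw[key])
            nxt_bw[state] = acc
        bw.insert(0, nxt_bw)

    probs = np.empty((k, 4))
    for j in range(k):
        log_marg = np.full(4, -np.inf)
        for state, lp in fw[j].items():
            b = state[-1]
            log_marg[b] = np.logaddexp(log_marg[b], lp + bw[j][state])
        log_marg -= log_marg.max()
        p = np.exp(log_marg)
        probs[j] = p / p.sum()

    calls = probs.argmax(axis=1).astype(np.uint8)
    quals = np.array(
        [posterior_to_phred(probs[j, calls[j]]) for j in range(k)], dtype=int
    )
    return PosteriorCall(probabilities=probs, calls=calls, quals=quals)


def posterior_to_phred(p_max: float) -> int:
    """Phred-scale a posterior call probability: ``-10 log10(1 - p_max)``,
    rounded to the nearest integer and capped at 60."""
    if not 0.0 <= p_max <= 1.0:
        raise ValueError("posterior probability must lie in [0, 1]")
    if p_max >= 1.0 - 10.0 ** (-PHRED_CAP / 10.0):
        return PHRED_CAP
    return min(PHRED_CAP, int(round(-10.0 * np.log10(1.0 - p_max))))


def sequence_loglik(
    bases: np.ndarray, observed: EncodedRead, model: ObservationModel, spec: CodeSpec
) -> float:
    """Log-likelihood of the observed colors given a candidate source sequence."""
    emitted = encode_read(np.asarray(bases, dtype=np.uint8), spec)
    color_ll, ecc_ll = _emission_tables(observed, model)
    total = float(color_ll[np.arange(spec.read_length), emitted.color_stream].sum())
    total += float(ecc_ll[np.arange(spec.n_blocks), emitted.ecc_stream].sum())
    return total
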