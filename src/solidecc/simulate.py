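"""Read simulation and truth-based evaluation of the code family.

The simulator emulates a color-space sequencing run end to end:

1. sample fragments uniformly from the positive strand of a reference;
2. mutate fragment bases independently at the generalised-error rate
   (template errors such as polymerase misincorporation during sample
   preparation -- these occur before encoding, so no code can correct them);
3. encode the mutated fragment into the two-base and ECC color streams;
4. assign a Phred quality to every color call from a per-cycle profile;
5. miscall each color independently with probability ``10^(-Q/10)``, the
   wrong color drawn uniformly from the three alternatives.

Defaults follow the production operating point: 50-base fragments and a
generalised-error rate equivalent to Q34 (``10^-3.4``).  Because no public
per-cycle quality profile exists, the synthetic profile declines linearly
from Q30 at the first cycle to Q15 at the last, with configurable per-round
offsets; real QUAL files may be supplied instead through the io module.
Insertions and deletions are not simulated.

Evaluation compares decoder output directly against the known truth
(Hamming distance in color space and base space) rather than mapping reads
to a genome, binning reads by their error count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gf4
from .codebuild import (
    CodeSpec,
    ECC_PROBE,
    EncodedRead,
    ProbeGenerator,
    encode_read,
    naive_decode_colors,
)
from .syndromes import build_syndrome_table, syndrome_decode
from .trellis import ObservationModel, posterior_decode, viterbi_decode

__all__ = [
    "SimConfig",
    "SimRecord",
    "synth_reference",
    "default_quality_profile",
    "simulate_reads",
    "run_experiment",
    "summarize_error_counts",
    "DECODERS",
]

DECODERS = ("none", "syndrome", "viterbi", "map")

#: Generalised-error rate equivalent to Q34, the production operating point.
Q34_RATE = 10.0 ** -3.4


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    The seed is mandatory: every random draw flows from it, making reruns
    byte-identical.
    """

    seed: int
    n_fragments: int = 1000
    fragment_length: int = 50
    reference_length: int = 100_000
    generalized_error_rate: float = Q34_RATE
    probe: ProbeGenerator = ECC_PROBE
    adapter_base: int = gf4.BETA
    quality_start: float = 30.0
    quality_end: float = 15.0
    round_offsets: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    ecc_round_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.generalized_error_rate <= 1.0:
            raise ValueError("generalized error rate must be a probability")
        if self.fragment_length > self.reference_length:
            raise ValueError("fragment length cannot exceed reference length")
        if self.fragment_length % 5 != 0 or self.fragment_length <= 0:
            raise ValueError("fragment length must be a positive multiple of 5")

    @property
    def code_spec(self) -> CodeSpec:
        return CodeSpec(
            read_length=self.fragment_length,
            probe=self.probe,
            adapter_base=self.adapter_base,
        )


@dataclass
class SimRecord:
    """One simulated read with full ground truth."""

    start: int
    true_fragment: np.ndarray      # reference bases, pre-mutation
    mutated_fragment: np.ndarray   # template actually sequenced (post step 2)
    clean: EncodedRead             # error-free encoding of the mutated fragment
    observed: EncodedRead          # encoding after per-color miscalls
    color_quals: np.ndarray        # Phred quality per two-base color
    ecc_quals: np.ndarray          # Phred quality per ECC color

    def observation_model(self) -> ObservationModel:
        return ObservationModel.from_phred(self.color_quals, self.ecc_quals)


def synth_reference(
    length: int,
    seed: int,
    base_composition: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Generate an i.i.d. synthetic reference sequence (GF(4) base vector)."""
    if length < 1:
        raise ValueError("reference length must be at least 1")
    comp = (0.25, 0.25, 0.25, 0.25) if base_composition is None else base_composition
    if abs(sum(comp) - 1.0) > 1e-9:
        raise ValueError("base composition must sum to 1")
    rng = np.random.default_rng(seed)
    return rng.choice(4, size=length, p=comp).astype(np.uint8)


def default_quality_profile(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle integer Phred qualities for the two streams.

    Two-base colors decline linearly from ``quality_start`` to
    ``quality_end`` over the read, with a per-round additive offset (color
    ``j`` belongs to round ``j mod 5``); ECC colors use the same decline
    over the block cycles plus ``ecc_round_offset``.
    """
    k = config.fragment_length
    m = k // 5
    ramp = np.linspace(config.quality_start, config.quality_end, k)
    rounds = np.arange(k) % 5
    color_q = ramp + np.asarray(config.round_offsets)[rounds]
    ecc_q = np.linspace(config.quality_start, config.quality_end, m) + config.ecc_round_offset
    return np.round(color_q).astype(int), np.round(ecc_q).astype(int)


def _mutate(vec: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each element independently with probability ``rate``; the
    replacement is uniform over the three alternatives (a nonzero GF(4)
    offset drawn uniformly)."""
    out = vec.copy()
    hits = rng.random(vec.shape) < rate
    offsets = rng.integers(1, 4, size=vec.shape).astype(np.uint8)
    out[hits] ^= offsets[hits]
    return out


def simulate_reads(ref: np.ndarray, config: SimConfig) -> list[SimRecord]:
    """Run the five-step simulation scheme against a reference sequence."""
    rng = np.random.default_rng(config.seed)
    spec = config.code_spec
    k = config.fragment_length
    color_q, ecc_q = default_quality_profile(config)
    color_eps = 10.0 ** (-color_q / 10.0)
    ecc_eps = 10.0 ** (-ecc_q / 10.0)

    records: list[SimRecord] = []
    starts = rng.integers(0, len(ref) - k + 1, size=config.n_fragments)
    for start in starts:
        fragment = ref[start: start + k]
        mutated = _mutate(fragment, config.generalized_error_rate, rng)
        clean = encode_read(mutated, spec)
        observed = EncodedRead(
            color_stream=_mutate_eps(clean.color_stream, color_eps, rng),
            ecc_stream=_mutate_eps(clean.ecc_stream, ecc_eps, rng),
        )
        records.append(
            SimRecord(
                start=int(start),
                true_fragment=fragment.copy(),
                mutated_fragment=mutated,
                clean=clean,
                observed=observed,
                color_quals=color_q.copy(),
                ecc_quals=ecc_q.copy(),
            )
        )
    return records


def _mutate_eps(vec: np.ndarray, eps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = vec.copy()
    hits = rng.random(vec.shape) < eps
    offsets = rng.integers(1, 4, size=vec.shape).astype(np.uint8)
    out[hits] ^= offsets[hits]
    return out


def _decode_records(
    records: list[SimRecord], spec: CodeSpec, decoder: str
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per read: (decoded bases, two-base color stream implied by the call)."""
    bases_out: list[np.ndarray] = []
    colors_out: list[np.ndarray] = []
    if decoder == "syndrome":
        table = build_syndrome_table(spec)
    for rec in records:
        if decoder == "none":
            bases = naive_decode_colors(rec.observed.color_stream, spec.adapter_base)
            colors = rec.observed.color_stream
        elif decoder == "syndrome":
            model = rec.observation_model()
            res = syndrome_decode(
                rec.observed, spec, table=table, qualities=model.concatenated_eps()
            )
            bases = res.bases
            colors = res.read.color_stream
        elif decoder == "viterbi":
            bases, _ = viterbi_decode(rec.observed, rec.observation_model(), spec)
            colors = encode_read(bases, spec).color_stream
        elif decoder == "map":
            call = posterior_decode(rec.observed, rec.observation_model(), spec)
            bases = call.calls
            colors = encode_read(bases, spec).color_stream
        else:
            raise ValueError(f"unknown decoder {decoder!r}; expected one of {DECODERS}")
        bases_out.append(bases)
        colors_out.append(colors)
    return bases_out, colors_out


def summarize_error_counts(errors: np.ndarray, max_bin: int = 5) -> dict[str, float]:
    """Fractions of reads with 0..max_bin errors, plus an overflow bin."""
    n = len(errors)
    out = {str(i): float(np.mean(errors == i)) for i in range(max_bin + 1)}
    out[f">{max_bin}"] = float(np.mean(errors > max_bin))
    out["n_reads"] = n
    return out


def run_experiment(
    config: SimConfig,
    decoder: str = "syndrome",
    ref: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate, decode, and tally truth-based error counts.

    Truth is the sequenced template (the post-mutation fragment): errors
    counted here are the calling errors a decoder could in principle fix,
    not the generalised errors it cannot.  Color-space errors are Hamming
    distances over the k two-base colors; base-space errors over the k
    decoded bases.  Returns a DataFrame with one row per space.
    """
    if decoder not in DECODERS:
        raise ValueError(f"unknown decoder {decoder!r}; expected one of {DECODERS}")
    spec = config.code_spec
    if ref is None:
        ref = synth_reference(config.reference_length, seed=config.seed)
    records = simulate_reads(ref, config)
    bases, colors = _decode_records(records, spec, decoder)
    base_errors = np.array(
        [int(np.count_nonzero(b != r.mutated_fragment)) for b, r in zip(bases, records)]
    )
    color_errors = np.array(
        [int(np.count_nonzero(c != r.clean.color_stream)) for c, r in zip(colors, records)]
    )
    rows = {
        "color": summarize_error_counts(color_errors),
        "base": summarize_error_counts(base_errors),
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "space"
    df.insert(0, "decoder", decoder)
    df.insert(1, "probe", str(config.probe))
    return df
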