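"""Readers and writers for the formats the toolkit touches.

Dialects:

* **FASTA** -- nucleotide references and decoded reads (via Biopython);
  case-insensitive on input, IUPAC ambiguity codes rejected with position.
* **CSFASTA** -- color-space reads: ``#`` comment lines, ``>`` headers, and a
  sequence line whose first character is the primer (adapter) base followed
  by one color digit ``0-3`` per call, with ``.`` marking a missing call.
* **QUAL** -- companion per-call Phred qualities, same headers, whitespace-
  separated integers (``-1`` for missing calls).
* **ECC companion** -- there is no standard container for the punctured
  second-stream colors, so they are stored in a CSFASTA-like file with the
  same headers, one color per five-base block, and no primer base.
* **FASTQ** (Sanger, Phred+33) -- decoded bases with per-base qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import gf4
from .codebuild import EncodedRead
from .trellis import MISSING

__all__ = [
    "ColorReadRecord",
    "CsfastaParseError",
    "read_fasta",
    "write_fasta",
    "read_csfasta",
    "write_csfasta",
    "read_ecc_companion",
    "write_ecc_companion",
    "write_fastq",
    "record_to_read",
    "read_to_record",
]


class CsfastaParseError(ValueError):
    """Malformed CSFASTA/QUAL content, annotated with file and line number."""


@dataclass
class ColorReadRecord:
    """One color-space read: identifier, primer base, color calls, qualities."""

    name: str
    primer: str
    colors: str                      # digits 0-3, '.' for a missing call
    quals: list[int] | None = None   # one integer per color when present

    def __post_init__(self) -> None:
        if self.primer.upper() not in gf4.BASES:
            raise CsfastaParseError(
                f"record {self.name!r}: primer base {self.primer!r} is not a nucleotide"
            )
        bad = [c for c in self.colors if c not in "0123."]
        if bad:
            raise CsfastaParseError(
                f"record {self.name!r}: invalid color character {bad[0]!r}"
            )
        if self.quals is not None and len(self.quals) != len(self.colors):
            raise CsfastaParseError(
                f"record {self.name!r}: {len(self.quals)} qualities for "
                f"{len(self.colors)} colors"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read base sequences as (name, GF(4) vector) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            vec = gf4.bases_to_gf(str(rec.seq))
        except gf4.AlphabetError as exc:
            raise gf4.AlphabetError(f"{path}, record {rec.id!r}: {exc}") from None
        out.append((rec.id, vec))
    return out


def write_fasta(records: Iterable[tuple[str, np.ndarray]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(gf4.gf_to_bases(vec)), id=name, description="")
        for name, vec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# CSFASTA + QUAL
# ---------------------------------------------------------------------------

def _parse_headed_file(path: str | Path) -> list[tuple[str, str, int]]:
    """(header, payload, line_number) triples; '#' comments skipped.
    Payload lines between headers are concatenated with spaces."""
    entries: list[tuple[str, list[str], int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                entries.append((line[1:].strip(), [], lineno))
            elif not entries:
                raise CsfastaParseError(f"{path}:{lineno}: sequence data before any header")
            else:
                entries[-1][1].append(line)
    return [(name, " ".join(chunks), lineno) for name, chunks, lineno in entries]


def _parse_qual(path: str | Path) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for name, payload, lineno in _parse_headed_file(path):
        try:
            out[name] = [int(tok) for tok in payload.split()]
        except ValueError:
            raise CsfastaParseError(
                f"{path}:{lineno}: non-integer quality value for record {name!r}"
            ) from None
    return out


def read_csfasta(path: str | Path, qual_path: str | Path | None = None) -> list[ColorReadRecord]:
    """Read color-space reads, optionally pairing a QUAL file by identifier."""
    quals = _parse_qual(qual_path) if qual_path is not None else None
    records = []
    for name, payload, lineno in _parse_headed_file(path):
        seq = payload.replace(" ", "")
        if len(seq) < 2:
            raise CsfastaParseError(f"{path}:{lineno}: record {name!r} has no color calls")
        q = None
        if quals is not None:
            if name not in quals:
                raise CsfastaParseError(
                    f"{qual_path}: no quality entry for record {name!r}"
                )
            q = quals[name]
        try:
            records.append(ColorReadRecord(name=name, primer=seq[0], colors=seq[1:], quals=q))
        except CsfastaParseError as exc:
            raise CsfastaParseError(f"{path}:{lineno}: {exc}") from None
    return records


def write_csfasta(
    records: Sequence[ColorReadRecord],
    path: str | Path,
    qual_path: str | Path | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("# color-space reads\n")
        for rec in records:
            fh.write(f">{rec.name}\n{rec.primer}{rec.colors}\n")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            fh.write("# per-color Phred qualities\n")
            for rec in records:
                if rec.quals is None:
                    raise ValueError(f"record {rec.name!r} has no qualities to write")
                fh.write(f">{rec.name}\n{' '.join(str(q) for q in rec.quals)}\n")


# ---------------------------------------------------------------------------
# ECC companion stream
# ---------------------------------------------------------------------------

def write_ecc_companion(
    names: Sequence[str], ecc_streams: Sequence[np.ndarray], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# punctured second-stream (ECC) colors, one per five-base block\n")
        for name, ecc in zip(names, ecc_streams):
            fh.write(f">{name}\n{gf4.gf_to_colors(ecc)}\n")


def read_ecc_companion(
    path: str | Path, expected_names: Sequence[str] | None = None
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, payload, lineno in _parse_headed_file(path):
        seq = payload.replace(" ", "")
        try:
            out[name] = gf4.colors_to_gf(seq)
        except gf4.AlphabetError as exc:
            raise CsfastaParseError(f"{path}:{lineno}: {exc}") from None
    if expected_names is not None:
        missing = [n for n in expected_names if n not in out]
        if missing or len(out) != len(expected_names):
            detail = f"missing {missing[:3]!r}" if missing else "extra records present"
            raise CsfastaParseError(
                f"{path}: ECC companion does not match the main file "
                f"({len(out)} records vs {len(expected_names)} expected; {detail})"
            )
    return out


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(
    records: Iterable[tuple[str, np.ndarray, Sequence[int]]], path: str | Path
) -> None:
    """Write (name, base vector, per-base Phred qualities) triples as Sanger FASTQ."""
    seq_records = []
    for name, vec, quals in records:
        rec = SeqRecord(Seq(gf4.gf_to_bases(vec)), id=name, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Record <-> EncodedRead conversion
# ---------------------------------------------------------------------------

def record_to_read(record: ColorReadRecord, ecc_colors: np.ndarray) -> EncodedRead:
    """Assemble an :class:`EncodedRead` from a CSFASTA record and its ECC colors.
    Missing calls ('.') become the trellis ``MISSING`` sentinel."""
    cs = np.array(
        [MISSING if c == "." else int(c) for c in record.colors], dtype=np.uint8
    )
    return EncodedRead(color_stream=cs, ecc_stream=np.asarray(ecc_colors, dtype=np.uint8))


def read_to_record(
    name: str, read: EncodedRead, primer_base: int, quals: Sequence[int] | None = None
) -> ColorReadRecord:
    colors = "".join(
        "." if c == MISSING else gf4.COLORS[int(c)] for c in read.color_stream
    )
    return ColorReadRecord(
        name=name,
        primer=gf4.BASES[primer_base],
        colors=colors,
        quals=list(quals) if quals is not None else None,
    )
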