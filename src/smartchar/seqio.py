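"""Sequence I/O and alphabet utilities.

Every assay module consumes :class:`SeqRecord` streams produced here. FASTQ is
the 4-line Phred+33 dialect (Phred+64 input is rejected); FASTA is wrapped at
60 columns on write. Lowercase input is uppercased and ``U`` is mapped to ``T``
in nucleotide mode, so downstream code only ever sees the DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SeqRecord",
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "quality_filter",
    "reverse_complement",
    "iupac_match",
    "IUPAC_SETS",
]


class FastqParseError(ValueError):
    """A FASTQ record could not be parsed; the message names the offending line."""


#: IUPAC nucleotide degeneracy sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: degeneracy set -> IUPAC code.
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)
_IUPAC_CHARS = frozenset(_COMPLEMENT)

# Decoded Phred scores above this are taken as evidence of Phred+64 input:
# modern Phred+33 data tops out around Q42 ('K'); Phred+64 data starts at '@'.
_MAX_PLAUSIBLE_PHRED33 = 45


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred quality scores.

    ``sequence`` is a nucleotide string over {A,C,G,T,N} (plus IUPAC codes for
    degenerate patterns) or a protein string over the 20 canonical residues
    plus ``X``; the two alphabets are never mixed in one record.
    """

    id: str
    sequence: str
    quality: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if self.quality is None:
            raise ValueError(f"record {self.id!r} carries no quality scores")
        if not self.quality:
            return 0.0
        return sum(self.quality) / len(self.quality)


def _normalize_nt(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a 4-line Phred+33 FASTQ file.

    Malformed records raise :class:`FastqParseError` naming the line where the
    offending record starts. An empty file yields an empty stream.
    """
    path = Path(path)
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython's structural checks
                raise FastqParseError(
                    f"{path}: malformed FASTQ record near line {4 * index + 1}: {exc}"
                ) from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record near line {4 * index + 1} "
                    f"({title.split()[0] if title else '?'!s}): sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            scores = [ord(c) - 33 for c in qual]
            if any(s < 0 for s in scores):
                raise FastqParseError(
                    f"{path}: record near line {4 * index + 1}: quality character "
                    "below '!' (not Phred+33)"
                )
            if scores and max(scores) > _MAX_PLAUSIBLE_PHRED33:
                raise FastqParseError(
                    f"{path}: record near line {4 * index + 1}: quality scores up to "
                    f"{max(scores)} look like Phred+64 encoding; only Phred+33 is supported"
                )
            yield SeqRecord(id=title.split()[0], sequence=_normalize_nt(seq), quality=scores)
            index += 1


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    """Write records as 4-line Phred+33 FASTQ (no line wrapping). Returns count."""
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.quality)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> Iterator[SeqRecord]:
    """Stream records from a FASTA file.

    ``alphabet`` is ``"nucleotide"`` (uppercased, U->T) or ``"protein"``
    (uppercased only).
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
        yield SeqRecord(id=rec.id, sequence=seq)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> int:
    """Write records as FASTA wrapped at ``wrap`` columns (0 = no wrap)."""
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            if wrap:
                for i in range(0, len(rec.sequence), wrap):
                    handle.write(rec.sequence[i : i + wrap] + "\n")
            else:
                handle.write(rec.sequence + "\n")
            n += 1
    return n


def quality_filter(
    records: Iterable[SeqRecord], min_mean_q: float = 20.0
) -> Iterator[SeqRecord]:
    """Retain records whose MEAN Phred quality is strictly greater than ``min_mean_q``.

    The read-quality filter applied before PAM extraction. Order is preserved
    and the filter is idempotent. Records without quality raise ``ValueError``.
    """
    for rec in records:
        if rec.quality is None:
            raise ValueError(f"record {rec.id!r} carries no quality scores")
        if rec.mean_quality > min_mean_q:
            yield rec


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string, honouring IUPAC degeneracy codes."""
    bad = set(seq) - _IUPAC_CHARS
    if bad:
        raise ValueError(f"non-IUPAC nucleotide character(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of ``seq`` lies in the degeneracy set of ``pattern``.

    Both strings must have equal length; used e.g. to compare a called PAM
    consensus (like ``NGG``) against concrete 8-mers.
    """
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    for p, b in zip(pattern, seq):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern") from None
        if b not in allowed:
            return False
    return True
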