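"""Amplicon-NGS editing quantification: per-position conversions and indel fraction.

Reads are globally aligned to the amplicon reference with an affine-gap
Gotoh aligner (match 2, mismatch -3, gap open -8, gap extend -1 by default;
gap open is the cost of the first gap base). Alignments below 60% identity
are rejected as off-target amplicons or primer dimers. From accepted
alignments the module tabulates, per reference position, the fraction of
reads whose base differs (broken down by target base) -- the per-position
edit heatmap readout -- and the fraction of reads carrying an insertion or
deletion overlapping the editing window (the nuclease indel readout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .seqio import SeqRecord

__all__ = [
    "AmpliconRef",
    "Alignment",
    "EditMatrix",
    "DEFAULT_SCORES",
    "align_read",
    "quantify",
    "heatmap_table",
]

DEFAULT_SCORES = (2.0, -3.0, -8.0, -1.0)  # match, mismatch, gap open, gap extend

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

# op codes in the kernel output
_OP_MATCH, _OP_MISMATCH, _OP_INS, _OP_DEL = 0, 1, 2, 3
_OP_CHARS = "=XID"

_NEG = -1.0e18


@dataclass(frozen=True)
class AmpliconRef:
    """Amplicon reference with protospacer placement and editing window.

    ``window`` is 1-based inclusive in protospacer coordinates;
    ``protospacer_start`` is the 1-based amplicon position of protospacer
    base 1. ``pam_side`` records where the PAM sits relative to the
    protospacer (three_prime for Cas9-style targets).
    """

    sequence: str
    window: tuple[int, int]
    protospacer_start: int
    protospacer_len: int = 20
    pam_side: str = "three_prime"

    def __post_init__(self) -> None:
        ws, we = self.window
        if not 1 <= ws <= we <= self.protospacer_len:
            raise ValueError("editing window must lie within the protospacer")
        if not 1 <= self.protospacer_start <= len(self.sequence):
            raise ValueError("protospacer_start outside the amplicon")
        if self.protospacer_start + self.protospacer_len - 1 > len(self.sequence):
            raise ValueError("protospacer extends past the amplicon end")

    def window_amplicon(self) -> tuple[int, int]:
        """Editing window in 1-based amplicon coordinates."""
        off = self.protospacer_start - 1
        return (self.window[0] + off, self.window[1] + off)

    @property
    def protospacer(self) -> str:
        s = self.protospacer_start - 1
        return self.sequence[s : s + self.protospacer_len]


@dataclass
class Alignment:
    """A global read-vs-reference alignment as a CIGAR-like op list."""

    ops: list[tuple[str, int]]  # op in "=XID", run length
    score: float
    identity: float


@njit(cache=True)
def _gotoh(q, r, s_match, s_mismatch, go, ge, ops_out):  # pragma: no cover - numba
    m, n = q.shape[0], r.shape[0]
    H = np.empty((m + 1, n + 1))
    E = np.empty((m + 1, n + 1))  # gap in ref (insertion, consumes read)
    F = np.empty((m + 1, n + 1))  # gap in read (deletion, consumes ref)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 del, 2 ins
    ptrE = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 = extend
    ptrF = np.zeros((m + 1, n + 1), dtype=np.int8)
    H[0, 0] = 0.0
    E[0, 0] = _NEG
    F[0, 0] = _NEG
    for i in range(1, m + 1):
        E[i, 0] = go + (i - 1) * ge
        H[i, 0] = E[i, 0]
        F[i, 0] = _NEG
        ptrH[i, 0] = 2
        ptrE[i, 0] = 1 if i > 1 else 0
    for j in range(1, n + 1):
        F[0, j] = go + (j - 1) * ge
        H[0, j] = F[0, j]
        E[0, j] = _NEG
        ptrH[0, j] = 1
        ptrF[0, j] = 1 if j > 1 else 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            open_e = H[i - 1, j] + go
            ext_e = E[i - 1, j] + ge
            if ext_e > open_e:
                E[i, j] = ext_e
                ptrE[i, j] = 1
            else:
                E[i, j] = open_e
                ptrE[i, j] = 0
            open_f = H[i, j - 1] + go
            ext_f = F[i, j - 1] + ge
            if ext_f > open_f:
                F[i, j] = ext_f
                ptrF[i, j] = 1
            else:
                F[i, j] = open_f
                ptrF[i, j] = 0
            s = s_match if q[i - 1] == r[j - 1] and q[i - 1] < 4 else s_mismatch
            diag = H[i - 1, j - 1] + s
            # tie order: diagonal over gap, deletion over insertion
            if diag >= E[i, j] and diag >= F[i, j]:
                H[i, j] = diag
                ptrH[i, j] = 0
            elif F[i, j] >= E[i, j]:
                H[i, j] = F[i, j]
                ptrH[i, j] = 1
            else:
                H[i, j] = E[i, j]
                ptrH[i, j] = 2
    # traceback
    i, j = m, n
    k = 0
    state = 0  # 0 = H, 1 = F(del), 2 = E(ins)
    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                state = 1
                continue
            if j == 0:
                state = 2
                continue
            p = ptrH[i, j]
            if p == 0:
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    ops_out[k] = _OP_MATCH
                else:
                    ops_out[k] = _OP_MISMATCH
                k += 1
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:  # deletion run, consumes ref
            ops_out[k] = _OP_DEL
            k += 1
            ext = ptrF[i, j]
            j -= 1
            state = 1 if ext == 1 else 0
        else:  # insertion run, consumes read
            ops_out[k] = _OP_INS
            k += 1
            ext = ptrE[i, j]
            i -= 1
            state = 2 if ext == 1 else 0
    return H[m, n], k


def _run_length(ops: np.ndarray, k: int) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for idx in range(k - 1, -1, -1):  # kernel emits ops back-to-front
        c = _OP_CHARS[ops[idx]]
        if out and out[-1][0] == c:
            out[-1] = (c, out[-1][1] + 1)
        else:
            out.append((c, 1))
    return out


def align_read(
    read: SeqRecord,
    ref: AmpliconRef,
    scores: tuple[float, float, float, float] = DEFAULT_SCORES,
    min_identity: float = 0.6,
) -> Alignment | None:
    """Global affine-gap alignment of a read to the amplicon, or None if rejected.

    Identity is matches / alignment columns; reads under ``min_identity``
    (default 60%) are rejected as off-target amplicons or primer dimers.
    Tie-breaking is deterministic: at equal score a mismatch is preferred
    over a gap, and a deletion over an insertion.
    """
    q = _ENC[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
    r = _ENC[np.frombuffer(ref.sequence.encode(), dtype=np.uint8)]
    ops_buf = np.empty(len(q) + len(r), dtype=np.int8)
    score, k = _gotoh(q, r, scores[0], scores[1], scores[2], scores[3], ops_buf)
    ops = _run_length(ops_buf, k)
    columns = sum(length for _, length in ops)
    matches = sum(length for op, length in ops if op == "=")
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    return Alignment(ops=ops, score=float(score), identity=identity)


@dataclass
class EditMatrix:
    """Per-position substitution tallies plus window indel fraction.

    ``sub_counts[p, b]`` counts accepted reads carrying base ``b`` (A,C,G,T
    order) at 0-based reference position ``p`` where it differs from the
    reference base; ``coverage[p]`` counts reads with an aligned (non-gap)
    base there, so matches + substitutions = coverage at every position.
    """

    ref: AmpliconRef
    sub_counts: np.ndarray  # (ref_len, 4)
    coverage: np.ndarray  # (ref_len,)
    indel_reads: int
    n_reads_aligned: int
    n_reads_total: int

    @property
    def indel_fraction(self) -> float:
        return self.indel_reads / self.n_reads_aligned if self.n_reads_aligned else 0.0

    def edit_fraction(self, position: int, to_base: str) -> float:
        """Fraction of covering reads with ``to_base`` at 1-based amplicon ``position``."""
        p = position - 1
        cov = self.coverage[p]
        if cov == 0:
            return 0.0
        return float(self.sub_counts[p, "ACGT".index(to_base)] / cov)

    def to_dict(self) -> dict:
        return {
            "amplicon_length": len(self.ref.sequence),
            "window": list(self.ref.window),
            "protospacer_start": self.ref.protospacer_start,
            "n_reads_total": self.n_reads_total,
            "n_reads_aligned": self.n_reads_aligned,
            "indel_fraction": self.indel_fraction,
            "coverage": self.coverage.tolist(),
            "substitution_counts": self.sub_counts.tolist(),
        }


def quantify(
    reads: Iterable[SeqRecord],
    ref: AmpliconRef,
    scores: tuple[float, float, float, float] = DEFAULT_SCORES,
    min_identity: float = 0.6,
    whole_amplicon_indels: bool = False,
) -> EditMatrix:
    """Tabulate per-position substitutions and window indels over a read stream.

    Each accepted read counts once; substitutions are tallied marginally per
    position (no haplotype phasing). ``indel_fraction`` counts reads with at
    least one insertion or deletion overlapping the editing window (or
    anywhere on the amplicon with ``whole_amplicon_indels``). Raises if no
    read aligns, reporting the rejection tally.
    """
    L = len(ref.sequence)
    r_codes = _ENC[np.frombuffer(ref.sequence.encode(), dtype=np.uint8)]
    sub_counts = np.zeros((L, 4), dtype=np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    ws, we = ref.window_amplicon()
    indel_reads = 0
    n_total = 0
    n_aligned = 0
    for read in reads:
        n_total += 1
        aln = align_read(read, ref, scores=scores, min_identity=min_identity)
        if aln is None:
            continue
        n_aligned += 1
        qpos = 0  # 0-based in read
        rpos = 0  # 0-based in ref
        has_window_indel = False
        for op, length in aln.ops:
            if op in "=X":
                for t in range(length):
                    p = rpos + t
                    coverage[p] += 1
                    if op == "X":
                        b = _ENC[ord(read.sequence[qpos + t])]
                        if b < 4 and b != r_codes[p]:
                            sub_counts[p, b] += 1
                        elif b >= 4:
                            # N call: covered but not an edit toward any base
                            pass
                qpos += length
                rpos += length
            elif op == "D":
                span = (rpos + 1, rpos + length)  # 1-based deleted ref span
                if whole_amplicon_indels or (span[0] <= we and span[1] >= ws):
                    has_window_indel = True
                rpos += length
            else:  # insertion between ref positions rpos and rpos+1
                if whole_amplicon_indels or (ws - 1 <= rpos <= we):
                    has_window_indel = True
                qpos += length
        if has_window_indel:
            indel_reads += 1
    if n_aligned == 0:
        raise ValueError(
            f"zero accepted alignments out of {n_total} reads "
            f"(identity threshold {min_identity})"
        )
    return EditMatrix(
        ref=ref,
        sub_counts=sub_counts,
        coverage=coverage,
        indel_reads=indel_reads,
        n_reads_aligned=n_aligned,
        n_reads_total=n_total,
    )


def heatmap_table(
    matrix: EditMatrix,
    ref: AmpliconRef,
    conversion: tuple[str, str] = ("A", "G"),
) -> pd.DataFrame:
    """Percent of reads supporting a from->to conversion at each protospacer occurrence.

    One row per occurrence of ``from_base`` in the protospacer, positions
    numbered within the protospacer (the subscript convention of base-editing
    readouts), with the edit percentage on the 0-100 scale.
    """
    from_base, to_base = conversion
    rows = []
    proto = ref.protospacer
    off = ref.protospacer_start - 1
    for i, b in enumerate(proto):
        if b != from_base:
            continue
        amp_pos = off + i + 1
        rows.append(
            {
                "protospacer_position": i + 1,
                "amplicon_position": amp_pos,
                "from_base": from_base,
                "to_base": to_base,
                "percent": 100.0 * matrix.edit_fraction(amp_pos, to_base),
                "coverage": int(matrix.coverage[amp_pos - 1]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protospacer_position",
            "amplicon_position",
            "from_base",
            "to_base",
            "percent",
            "coverage",
        ],
    )
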