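"""sgRNA scaffold construction from a CRISPR repeat and tracrRNA.

The repeat's 3' region base-pairs with the tracrRNA's 5' anti-repeat. The
single-guide scaffold replaces the natural two-RNA junction with a GAAA
tetraloop: spacer + trimmed repeat + GAAA + trimmed anti-repeat + tracr tail.
The repeat:anti-repeat duplex is identified by a complementarity local
alignment (Watson-Crick +1, optional G:U wobble, mismatch -2, gap -3); an
externally computed dot-bracket structure can override it. Designs are
emitted as a cartesian series over helix trim levels, spacer lengths
(truncated from the 5', PAM-distal end) and tracr termination points.

Sequences are handled internally in the DNA alphabet and emitted as RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DuplexModel",
    "SgRnaDesign",
    "find_duplex",
    "duplex_from_dotbracket",
    "build_designs",
]

logger = logging.getLogger(__name__)

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in the RNA alphabet


def pairs_ok(a: str, b: str, allow_wobble: bool) -> bool:
    return (a, b) in _WC or (allow_wobble and (a, b) in _WOBBLE)


@dataclass
class DuplexModel:
    """Repeat:anti-repeat duplex: the paired index list and its score.

    ``pairing`` holds (repeat_index, tracr_index) 0-based pairs, repeat
    indices strictly increasing and tracr indices strictly decreasing
    (antiparallel helix, no pseudoknots); only Watson-Crick / wobble pairs
    are recorded, mismatched alignment columns are not part of the pairing.
    """

    repeat_seq: str
    tracr_seq: str
    pairing: list[tuple[int, int]]
    duplex_len: int
    score: float = 0.0

    def __post_init__(self) -> None:
        r_idx = [i for i, _ in self.pairing]
        t_idx = [j for _, j in self.pairing]
        if sorted(r_idx) != r_idx or sorted(t_idx, reverse=True) != t_idx:
            raise ValueError("pairing indices must be antiparallel and monotone")


def find_duplex(
    repeat: str,
    tracr: str,
    min_duplex: int = 6,
    allow_wobble: bool = True,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap: float = -3.0,
) -> DuplexModel:
    """Best local antiparallel pairing between repeat and tracr.

    Smith-Waterman of the repeat against the reversed tracr with
    complementarity scoring; at equal score the pairing closest to the
    repeat's 3' end wins. Raises if the best duplex has fewer than
    ``min_duplex`` complementary pairs.
    """
    if not repeat or not tracr:
        raise ValueError("repeat and tracr must be non-empty")
    rt = tracr[::-1]  # align repeat 5'->3' against tracr 3'->5'
    n, m = len(repeat), len(rt)
    H = np.zeros((n + 1, m + 1))
    best_score, best_cell = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if pairs_ok(repeat[i - 1], rt[j - 1], allow_wobble) else mismatch
            h = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
            H[i, j] = h
            # ties resolved toward the repeat's 3' end (largest i, then j)
            if h > best_score or (h == best_score and h > 0 and (i, j) >= best_cell):
                best_score, best_cell = h, (i, j)
    pairing: list[tuple[int, int]] = []
    i, j = best_cell
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if pairs_ok(repeat[i - 1], rt[j - 1], allow_wobble) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == match:
                pairing.append((i - 1, len(tracr) - j))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairing.reverse()
    if len(pairing) < min_duplex:
        raise ValueError(
            f"no repeat:anti-repeat duplex found: best duplex has {len(pairing)} "
            f"pairs (< min_duplex={min_duplex})"
        )
    return DuplexModel(
        repeat_seq=repeat,
        tracr_seq=tracr,
        pairing=pairing,
        duplex_len=len(pairing),
        score=best_score,
    )


def duplex_from_dotbracket(
    repeat: str, tracr: str, structure: str, min_duplex: int = 6
) -> DuplexModel:
    """Build a DuplexModel from an externally folded structure.

    ``structure`` is dot-bracket notation over ``repeat + tracr`` (e.g. from a
    thermodynamic folding tool); only brackets pairing a repeat position with
    a tracr position are kept.
    """
    concat_len = len(repeat) + len(tracr)
    if len(structure) != concat_len:
        raise ValueError("structure length must equal len(repeat) + len(tracr)")
    stack: list[int] = []
    pairing: list[tuple[int, int]] = []
    for idx, c in enumerate(structure):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            a = stack.pop()
            if a < len(repeat) <= idx:
                pairing.append((a, idx - len(repeat)))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    pairing.sort()
    if len(pairing) < min_duplex:
        raise ValueError("no repeat:anti-repeat duplex found in supplied structure")
    return DuplexModel(
        repeat_seq=repeat, tracr_seq=tracr, pairing=pairing, duplex_len=len(pairing)
    )


@dataclass
class SgRnaDesign:
    """One assembled single-guide scaffold variant."""

    design_id: str
    spacer: str
    trimmed_repeat: str
    trimmed_antirepeat: str
    tracr_tail: str
    trim_level: int
    spacer_len: int
    tail_end: int
    tetraloop: str = "GAAA"

    @property
    def full_sequence(self) -> str:
        return (
            self.spacer
            + self.trimmed_repeat
            + self.tetraloop
            + self.trimmed_antirepeat
            + self.tracr_tail
        )

    @property
    def rna(self) -> str:
        return self.full_sequence.replace("T", "U")


def build_designs(
    duplex: DuplexModel,
    spacer: str,
    trim_levels: Sequence[int],
    spacer_lens: Sequence[int],
    tail_ends: Sequence[int] | None = None,
    min_duplex: int = 6,
    tetraloop: str = "GAAA",
) -> list[SgRnaDesign]:
    """Cartesian (trim, spacer length, tail end) series of sgRNA designs.

    Trimming removes base pairs from the tetraloop-proximal end of the helix
    symmetrically on both strands. Spacers are truncated from their 5'
    (PAM-distal) end. ``tail_ends`` are 1-based tracr termination points;
    default is the full tracr. Combinations violating the geometry
    (helix below ``min_duplex`` pairs, spacer too short, tail ending inside
    the anti-repeat) are skipped with a warning.
    """
    repeat, tracr = duplex.repeat_seq, duplex.tracr_seq
    if tail_ends is None:
        tail_ends = [len(tracr)]
    pairing = duplex.pairing
    antirepeat_end = pairing[0][1]  # largest tracr index in the duplex
    designs: list[SgRnaDesign] = []
    for trim in trim_levels:
        if trim < 0 or duplex.duplex_len - trim < min_duplex:
            logger.warning(
                "skipping trim=%d: would leave %d < %d duplex pairs",
                trim, duplex.duplex_len - trim, min_duplex,
            )
            continue
        kept = pairing[: duplex.duplex_len - trim]
        r_last, t_first = kept[-1]  # tetraloop-proximal retained pair
        trimmed_repeat = repeat[: r_last + 1]
        trimmed_antirepeat = tracr[t_first : antirepeat_end + 1]
        for L in spacer_lens:
            if L <= 0 or L > len(spacer):
                logger.warning("skipping spacer_len=%d: source spacer is %d nt", L, len(spacer))
                continue
            sp = spacer[len(spacer) - L :]
            for tail_end in tail_ends:
                if tail_end < antirepeat_end + 1 or tail_end > len(tracr):
                    logger.warning("skipping tail_end=%d: outside the tracr tail", tail_end)
                    continue
                tail = tracr[antirepeat_end + 1 : tail_end]
                designs.append(
                    SgRnaDesign(
                        design_id=f"trim{trim}_sp{L}_tail{tail_end}",
                        spacer=sp,
                        trimmed_repeat=trimmed_repeat,
                        trimmed_antirepeat=trimmed_antirepeat,
                        tracr_tail=tail,
                        trim_level=trim,
                        spacer_len=L,
                        tail_end=tail_end,
                        tetraloop=tetraloop,
                    )
                )
    return designs
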