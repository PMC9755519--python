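"""PAM discovery from adapter-ligated cleavage products of a randomized (8N) library.

The enrichment-style assay sequences only cleaved molecules: each read carries
``adapter + protospacer-remnant + PAM + backbone anchor`` (or its reverse
complement). A fixed 14-24 bp backbone anchor adjacent to the randomized PAM
window locates the PAM; the distance between the ligated adapter and the
PAM-proximal edge is the cut distance. Observations are filtered to the modal
cut distance +/- 2, reduced to a position frequency matrix with information
content per position, and summarized as an IUPAC consensus and a logo-height
table. The retained non-target-strand cut distances, combined with an
externally measured target-strand cut site (run-off sequencing), give the
overhang geometry (blunt / 5' / 3' staggered).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import SET_TO_IUPAC, SeqRecord, reverse_complement

__all__ = [
    "AssayLayout",
    "PamObservation",
    "PamProfile",
    "OverhangCall",
    "locate_anchor",
    "extract_observation",
    "collect_observations",
    "build_profile",
    "call_consensus",
    "logo_matrix",
    "infer_overhang",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class AssayLayout:
    """Read architecture of the cleavage-product library.

    ``anchor`` is the fixed backbone sequence adjacent to the randomized PAM
    window (14-24 bp); ``adapter`` is the sequence ligated to the blunted cut
    end. ``pam_side`` states on which side of the anchor the PAM window lies
    in the forward read orientation.
    """

    adapter: str
    anchor: str
    pam_length: int = 8
    pam_side: str = "before_anchor"

    def __post_init__(self) -> None:
        if not 14 <= len(self.anchor) <= 24:
            raise ValueError(
                f"anchor length {len(self.anchor)} outside the supported 14-24 bp range"
            )
        if self.pam_length < 1:
            raise ValueError("pam_length must be >= 1")
        if self.pam_side not in ("before_anchor", "after_anchor"):
            raise ValueError(f"unknown pam_side {self.pam_side!r}")


@dataclass(frozen=True)
class PamObservation:
    """One read's extracted PAM, cut distance, and read orientation."""

    pam: str
    cut_distance: int
    orientation: str  # "forward" | "reverse"
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.cut_distance < 0:
            raise ValueError("cut_distance must be >= 0")


@dataclass
class PamProfile:
    """Filtered PAM observation set reduced to a PFM with consensus and cut histogram.

    ``cut_histogram`` covers retained observations only; ``pfm`` rows are
    frequencies over A,C,G,T summing to 1; ``information_bits[i]`` is
    ``2 + sum_b f_ib log2 f_ib`` in [0, 2].
    """

    n_raw: int
    n_retained: int
    modal_cut: int
    cut_histogram: dict[int, int]
    pfm: np.ndarray
    information_bits: np.ndarray
    consensus: str

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_retained": self.n_retained,
            "modal_cut": self.modal_cut,
            "cut_histogram": {str(k): v for k, v in sorted(self.cut_histogram.items())},
            "pfm": self.pfm.tolist(),
            "information_bits": self.information_bits.tolist(),
            "consensus": self.consensus,
        }


@dataclass(frozen=True)
class OverhangCall:
    """Cut geometry call from TS cut site plus retained NTS cut distances.

    ``overhang_lengths`` are magnitudes; the sign convention is carried by
    ``overhang_type`` (5' overhang when the NTS is cut PAM-distal of the TS).
    """

    ts_cut: int
    nts_positions: tuple[int, ...]
    overhang_type: str  # "blunt" | "five_prime" | "three_prime"
    overhang_lengths: tuple[int, ...]


def locate_anchor(
    read: SeqRecord, layout: AssayLayout, max_mismatch: int = 0
) -> tuple[int, str] | None:
    """Find the backbone anchor in the read, forward strand first.

    Returns the 0-based start of the leftmost match in the searched
    orientation, or ``None`` if the anchor is absent from both strands.
    Matching is exact by default (reads without an exact anchor match are
    excluded from the assay); ``max_mismatch`` relaxes it to a Hamming search.
    """
    anchor = layout.anchor
    for orientation, seq in (
        ("forward", read.sequence),
        ("reverse", reverse_complement(read.sequence)),
    ):
        if max_mismatch == 0:
            pos = seq.find(anchor)
            if pos >= 0:
                return pos, orientation
        else:
            for pos in range(len(seq) - len(anchor) + 1):
                window = seq[pos : pos + len(anchor)]
                if sum(a != b for a, b in zip(window, anchor)) <= max_mismatch:
                    return pos, orientation
    return None


def extract_observation(
    read: SeqRecord, hit: tuple[int, str], layout: AssayLayout
) -> tuple[PamObservation | None, str]:
    """Extract (PAM, cut distance) from an anchor hit.

    Returns ``(observation, "ok")`` or ``(None, reason)`` with reason
    ``"too_short"`` (read cannot contain the full PAM window) or
    ``"no_adapter"`` (adapter absent on the expected side in the same
    orientation -- a chimeric or undigested molecule).
    """
    pos, orientation = hit
    oriented = read.sequence if orientation == "forward" else reverse_complement(read.sequence)
    adapter, k = layout.adapter, layout.pam_length

    if layout.pam_side == "before_anchor":
        pam_start = pos - k
        if pam_start < 0:
            return None, "too_short"
        pam = oriented[pam_start:pos]
        a = oriented.find(adapter, 0, pam_start)
        if a < 0 or a + len(adapter) > pam_start:
            return None, "no_adapter"
        cut_distance = pam_start - (a + len(adapter))
    else:  # after_anchor: anchor + PAM + remnant + adapter
        pam_start = pos + len(layout.anchor)
        pam_end = pam_start + k
        if pam_end > len(oriented):
            return None, "too_short"
        pam = oriented[pam_start:pam_end]
        a = oriented.find(adapter, pam_end)
        if a < 0:
            return None, "no_adapter"
        cut_distance = a - pam_end

    return (
        PamObservation(pam=pam, cut_distance=cut_distance, orientation=orientation, read_id=read.id),
        "ok",
    )


def collect_observations(
    reads: Iterable[SeqRecord], layout: AssayLayout, max_anchor_mismatch: int = 0
) -> tuple[list[PamObservation], dict[str, int]]:
    """Run anchor location + extraction over a read stream.

    Returns the observation list and a discard tally accounting for every
    input read: keys ``ok``, ``no_anchor``, ``too_short``, ``no_adapter``.
    """
    tally = {"ok": 0, "no_anchor": 0, "too_short": 0, "no_adapter": 0}
    observations: list[PamObservation] = []
    for read in reads:
        hit = locate_anchor(read, layout, max_mismatch=max_anchor_mismatch)
        if hit is None:
            tally["no_anchor"] += 1
            continue
        obs, reason = extract_observation(read, hit, layout)
        if obs is None:
            tally[reason] += 1
        else:
            tally["ok"] += 1
            observations.append(obs)
    return observations, tally


def call_consensus(
    pfm: np.ndarray,
    include_threshold: float = 0.25,
    noise_floor_bits: float = 0.05,
) -> str:
    """Reduce a row-normalized PFM to an IUPAC consensus string.

    Per position, the IUPAC code of the set of bases with frequency >=
    ``include_threshold``; a position where all four or none qualify is 'N'.
    A position whose information content falls below ``noise_floor_bits`` is
    also 'N': at an uninformative position the empirical frequencies jitter
    around the uniform 0.25, so a raw threshold would otherwise emit an
    arbitrary partial code instead of 'N'.
    """
    if not 0.0 < include_threshold <= 1.0:
        raise ValueError(f"include_threshold must be in (0, 1], got {include_threshold}")
    pfm = np.asarray(pfm, dtype=float)
    codes = []
    for row in pfm:
        info = _information_bits(row)
        if info < noise_floor_bits:
            codes.append("N")
            continue
        qualifying = frozenset(b for b, f in zip(BASES, row) if f >= include_threshold)
        if len(qualifying) in (0, 4):
            codes.append("N")
        else:
            codes.append(SET_TO_IUPAC[qualifying])
    return "".join(codes)


def _information_bits(row: np.ndarray) -> float:
    nz = row[row > 0]
    return 2.0 + float(np.sum(nz * np.log2(nz)))


def build_profile(
    observations: Sequence[PamObservation],
    pseudocount: float = 0.5,
    include_threshold: float = 0.25,
    noise_floor_bits: float = 0.05,
) -> PamProfile:
    """Filter observations to the modal cut distance +/- 2 and build the PFM.

    The modal cut distance is the most frequent ``cut_distance`` (ties broken
    toward the smaller, PAM-proximal distance); only observations within +/- 2
    of it enter the PFM, matching the cut-site frequency filter of the assay.
    The PFM gets ``pseudocount`` per cell before row normalization. PAMs with
    non-ACGT bases (N calls) are excluded from the matrix but kept in the cut
    histogram.
    """
    if not observations:
        raise ValueError("no PAM observations")
    n_raw = len(observations)
    cut_counts = Counter(o.cut_distance for o in observations)
    max_count = max(cut_counts.values())
    modal_cut = min(d for d, c in cut_counts.items() if c == max_count)

    retained = [o for o in observations if abs(o.cut_distance - modal_cut) <= 2]
    pam_length = len(retained[0].pam)
    counts = np.zeros((pam_length, 4), dtype=float)
    n_ambiguous = 0
    for o in retained:
        if len(o.pam) != pam_length:
            raise ValueError("inconsistent PAM lengths among observations")
        idx = [_BASE_INDEX.get(b) for b in o.pam]
        if any(i is None for i in idx):
            n_ambiguous += 1
            continue
        counts[range(pam_length), idx] += 1
    if n_ambiguous:
        logger.info("excluded %d retained PAMs containing ambiguous bases", n_ambiguous)

    pfm = counts + pseudocount
    pfm /= pfm.sum(axis=1, keepdims=True)
    info = np.array([_information_bits(row) for row in pfm])
    consensus = call_consensus(pfm, include_threshold, noise_floor_bits)
    return PamProfile(
        n_raw=n_raw,
        n_retained=len(retained),
        modal_cut=modal_cut,
        cut_histogram=dict(Counter(o.cut_distance for o in retained)),
        pfm=pfm,
        information_bits=info,
        consensus=consensus,
    )


def logo_matrix(profile: PamProfile) -> pd.DataFrame:
    """Information-scaled letter heights: height(i, b) = f_ib * information_bits[i].

    Column sums equal the per-position information content; the table is
    directly consumable by standard sequence-logo plotters.
    """
    heights = profile.pfm * profile.information_bits[:, None]
    return pd.DataFrame(
        heights,
        index=pd.RangeIndex(1, profile.pfm.shape[0] + 1, name="position"),
        columns=list(BASES),
    )


def infer_overhang(ts_cut: int, profile: PamProfile) -> OverhangCall:
    """Combine an external target-strand cut site with the profile's NTS distances.

    The retained cut-distance support is interpreted as the set of non-target
    strand cleavage positions (distance from the PAM). All NTS positions
    PAM-distal of the TS cut give a 5' overhang, all PAM-proximal a 3'
    overhang, identity a blunt end; mixed signs are inconsistent geometry.
    """
    nts = tuple(sorted(profile.cut_histogram))
    deltas = [d - ts_cut for d in nts]
    if all(d == 0 for d in deltas):
        overhang_type = "blunt"
    elif all(d >= 0 for d in deltas):
        overhang_type = "five_prime"
    elif all(d <= 0 for d in deltas):
        overhang_type = "three_prime"
    else:
        raise ValueError("inconsistent cut geometry: NTS positions on both sides of the TS cut")
    return OverhangCall(
        ts_cut=ts_cut,
        nts_positions=nts,
        overhang_type=overhang_type,
        overhang_lengths=tuple(abs(d) for d in deltas),
    )
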