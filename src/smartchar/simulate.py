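"""Synthetic data with known ground truth for every assay module.

Each generator emulates one wet-lab readout so that parameter recovery is the
test surface: cleavage-product reads for PAM discovery (enrichment-style: only
cleaved molecules are sequenced), input/survivor count pairs for the mismatch
interference assay, edited amplicon reads for base-editing quantification, and
composition-skewed proteins with planted motifs for the feature screen.
Sequencing error is substitution-only; reads never contain indels beyond the
ones explicitly planted. All generators are bit-reproducible under a fixed
seed and return a machine-readable truth manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .edit_quant import AmpliconRef
from .mismatch_specificity import VariantLibrary
from .pam_discovery import AssayLayout
from .protein_screen import AMINO_ACIDS, ReferenceComposition
from .seqio import SeqRecord, iupac_match, reverse_complement

__all__ = [
    "PamTruth",
    "ToleranceTruth",
    "EditTruth",
    "simulate_pam_reads",
    "simulate_mismatch_counts",
    "reads_from_counts",
    "simulate_amplicon_reads",
    "simulate_protein",
    "DEFAULT_LAYOUT",
]

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: A concrete assay layout usable across examples and tests: a 10 nt adapter
#: and a 16 nt backbone anchor flanking the 8 nt randomized PAM window.
DEFAULT_LAYOUT = AssayLayout(
    adapter="ACACGACGCT",
    anchor="GTTCACTGCCGTATAG",
    pam_length=8,
    pam_side="before_anchor",
)


@dataclass(frozen=True)
class PamTruth:
    """Ground truth for the cleavage-product PAM assay.

    ``pam_iupac`` is the informative prefix (padded to the layout's PAM
    length with N); ``cut_dist`` the cut-distance distribution (distance from
    the PAM in nt on the sequenced strand); cleavage probabilities gate which
    library molecules emit a read; ``error_rate`` is per-base substitution
    error; ``orientation_mix`` the fraction of reverse-orientation reads.
    """

    pam_iupac: str = "NGG"
    cut_dist: Mapping[int, float] = field(default_factory=lambda: {5: 0.55, 6: 0.30, 7: 0.15})
    cleave_prob_match: float = 1.0
    cleave_prob_nonmatch: float = 0.0
    error_rate: float = 0.01
    orientation_mix: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.cut_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cut_dist probabilities sum to {total}, not 1")
        for p in (self.cleave_prob_match, self.cleave_prob_nonmatch,
                  self.error_rate, self.orientation_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ToleranceTruth:
    """Ground truth for the mismatch interference assay.

    ``tolerated`` positions are still cleaved when mismatched; the default
    profile mirrors a long-seed nuclease: intolerant along positions 1-13
    from the PAM except position 9, tolerated 14-24.
    """

    tolerated: frozenset[int] = frozenset({9} | set(range(14, 25)))
    cleave_tolerated: float = 0.99
    cleave_intolerant: float = 0.05
    depth_per_variant: int = 10_000

    @classmethod
    def seed13_except9(cls, spacer_len: int = 24, **kw) -> "ToleranceTruth":
        tolerated = frozenset({9} | set(range(14, spacer_len + 1)))
        return cls(tolerated=tolerated, **kw)


@dataclass(frozen=True)
class EditTruth:
    """Planted edits for amplicon-read simulation.

    ``edit_spec`` entries are (1-based amplicon position, from_base, to_base,
    fraction of reads edited); ``indel_spec`` optionally plants one indel:
    (1-based position, length, "ins"|"del", fraction).
    """

    edit_spec: Sequence[tuple[int, str, str, float]] = ()
    indel_spec: tuple[int, int, str, float] | None = None
    error_rate: float = 0.001


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_pam_reads(
    truth: PamTruth,
    layout: AssayLayout = DEFAULT_LAYOUT,
    n: int = 10_000,
    seed: int = 0,
    quality: int = 37,
) -> tuple[list[SeqRecord], dict]:
    """Emit ``n`` cleavage-product reads plus a truth manifest.

    Library molecules carry a uniformly random PAM; a molecule is cleaved
    with ``cleave_prob_match`` when its PAM matches the truth (informative
    prefix), else ``cleave_prob_nonmatch``, and only cleaved molecules emit a
    read: ``adapter + remnant(cut distance) + PAM + anchor``, reverse-
    complemented for the reverse-orientation fraction, with per-base
    substitution errors. Molecules are drawn until ``n`` reads exist.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    k = layout.pam_length
    if len(truth.pam_iupac) > k:
        raise ValueError("truth PAM longer than the layout's PAM window")
    pattern = truth.pam_iupac + "N" * (k - len(truth.pam_iupac))
    if truth.cleave_prob_match <= 0.0 and truth.cleave_prob_nonmatch <= 0.0:
        raise ValueError("no molecule can be cleaved: both cleavage probabilities are 0")
    rng = np.random.default_rng(seed)
    distances = sorted(truth.cut_dist)
    probs = np.array([truth.cut_dist[d] for d in distances])
    # per-position boolean masks of the padded truth pattern over A,C,G,T
    from .seqio import IUPAC_SETS

    allowed = np.array(
        [[b in IUPAC_SETS[p] for b in "ACGT"] for p in pattern], dtype=bool
    )
    reads: list[SeqRecord] = []
    n_molecules = 0
    n_cleaved_nonmatch = 0
    batch = 4096
    while len(reads) < n:
        pams = rng.integers(0, 4, size=(batch, k))
        matched = allowed[np.arange(k)[None, :], pams].all(axis=1)
        p_cleave = np.where(matched, truth.cleave_prob_match, truth.cleave_prob_nonmatch)
        cleaved = rng.random(batch) < p_cleave
        n_molecules += batch
        idx = np.nonzero(cleaved)[0]
        n_cleaved_nonmatch += int((~matched[idx]).sum())
        cuts = np.array(distances)[rng.choice(len(distances), size=idx.size, p=probs)]
        for row, cut in zip(idx, cuts):
            if len(reads) >= n:
                # unread tail of the batch still consumed the rng draws above,
                # keeping the stream reproducible regardless of n
                break
            pam = "".join(BASES[pams[row]])
            remnant = _random_bases(rng, int(cut))
            seq = layout.adapter + remnant + pam + layout.anchor
            seq = _apply_errors(rng, seq, truth.error_rate)
            orientation = "reverse" if rng.random() < truth.orientation_mix else "forward"
            if orientation == "reverse":
                seq = reverse_complement(seq)
            reads.append(
                SeqRecord(
                    id=f"sim{len(reads)}_{orientation}",
                    sequence=seq,
                    quality=[quality] * len(seq),
                )
            )
    manifest = {
        "generator": "simulate_pam_reads",
        "seed": seed,
        "n_reads": n,
        "n_molecules": n_molecules,
        "n_cleaved_nonmatch": n_cleaved_nonmatch,
        "pam_iupac": truth.pam_iupac,
        "pam_pattern_padded": pattern,
        "cut_dist": {str(d): truth.cut_dist[d] for d in distances},
        "error_rate": truth.error_rate,
        "orientation_mix": truth.orientation_mix,
        "layout": {
            "adapter": layout.adapter,
            "anchor": layout.anchor,
            "pam_length": layout.pam_length,
            "pam_side": layout.pam_side,
        },
    }
    return reads, manifest


def simulate_mismatch_counts(
    truth: ToleranceTruth,
    library: VariantLibrary,
    seed: int = 0,
) -> tuple[dict[str, int], dict[str, int], dict]:
    """Input and survivor counts for the mismatch interference assay.

    The input library is a uniform multinomial over the variants at total
    depth ``depth_per_variant * V``; each input molecule survives selection
    with probability 1 - cleave_p(variant), where the perfect match and
    tolerated-position variants are cleaved at ``cleave_tolerated`` and
    intolerant-position variants at ``cleave_intolerant``.
    """
    rng = np.random.default_rng(seed)
    ids = [v.variant_id for v in library.variants]
    V = len(ids)
    total = truth.depth_per_variant * V
    if total == 0:
        counts_in = {vid: 0 for vid in ids}
        return counts_in, dict(counts_in), {
            "generator": "simulate_mismatch_counts", "seed": seed, "depth_per_variant": 0,
        }
    draws = rng.multinomial(total, np.full(V, 1.0 / V))
    counts_in = {vid: int(c) for vid, c in zip(ids, draws)}
    counts_out: dict[str, int] = {}
    for v in library.variants:
        if v.position == 0 or v.position in truth.tolerated:
            p_cleave = truth.cleave_tolerated
        else:
            p_cleave = truth.cleave_intolerant
        counts_out[v.variant_id] = int(
            rng.binomial(counts_in[v.variant_id], 1.0 - p_cleave)
        )
    manifest = {
        "generator": "simulate_mismatch_counts",
        "seed": seed,
        "depth_per_variant": truth.depth_per_variant,
        "tolerated_positions": sorted(truth.tolerated),
        "cleave_tolerated": truth.cleave_tolerated,
        "cleave_intolerant": truth.cleave_intolerant,
        "spacer_len": len(library.spacer_ref),
    }
    return counts_in, counts_out, manifest


def reads_from_counts(
    counts: Mapping[str, int],
    library: VariantLibrary,
    flank5: str,
    flank3: str,
    quality: int = 37,
) -> list[SeqRecord]:
    """Expand a count table into error-free amplicon reads (flank5+protospacer+flank3)."""
    by_id = library.by_id()
    reads: list[SeqRecord] = []
    for vid in sorted(counts):
        proto = by_id[vid].protospacer
        seq = flank5 + proto + flank3
        for i in range(counts[vid]):
            reads.append(SeqRecord(id=f"{vid}_{i}", sequence=seq, quality=[quality] * len(seq)))
    return reads


def simulate_amplicon_reads(
    ref: AmpliconRef,
    truth: EditTruth,
    n: int = 10_000,
    seed: int = 0,
    quality: int = 37,
) -> tuple[list[SeqRecord], dict]:
    """Amplicon reads with planted substitutions/indels plus a truth manifest.

    Each read copies the reference, applies every planted edit independently
    with its fraction, applies the indel with its fraction, then per-base
    substitution errors. A substitution falling inside an applied deletion is
    skipped with a warning. Qualities are constant.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    L = len(ref.sequence)
    for pos, frm, to, frac in truth.edit_spec:
        if not 1 <= pos <= L:
            raise ValueError(f"edit position {pos} outside the amplicon")
        if ref.sequence[pos - 1] != frm:
            raise ValueError(f"edit at {pos}: reference base is {ref.sequence[pos-1]}, not {frm}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("edit fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    for i in range(n):
        seq = list(ref.sequence)
        deleted: set[int] = set()
        if truth.indel_spec is not None:
            pos, length, kind, frac = truth.indel_spec
            if rng.random() < frac:
                if kind == "del":
                    deleted = set(range(pos - 1, pos - 1 + length))
                elif kind == "ins":
                    seq[pos - 1] = _random_bases(rng, length) + seq[pos - 1]
                else:
                    raise ValueError(f"unknown indel type {kind!r}")
        for pos, frm, to, frac in truth.edit_spec:
            if rng.random() < frac:
                if pos - 1 in deleted:
                    logger.warning("substitution at %d overlaps deletion; skipped", pos)
                    continue
                seq[pos - 1] = to
        read_seq = "".join(b for j, b in enumerate(seq) if j not in deleted)
        read_seq = _apply_errors(rng, read_seq, truth.error_rate)
        reads.append(SeqRecord(id=f"amp{i}", sequence=read_seq, quality=[quality] * len(read_seq)))
    manifest = {
        "generator": "simulate_amplicon_reads",
        "seed": seed,
        "n_reads": n,
        "edit_spec": [list(e) for e in truth.edit_spec],
        "indel_spec": list(truth.indel_spec) if truth.indel_spec else None,
        "error_rate": truth.error_rate,
        "amplicon_length": L,
    }
    return reads, manifest


def simulate_protein(
    length: int,
    base_composition: ReferenceComposition | None = None,
    boosts: Mapping[str, float] | None = None,
    planted_motifs: Sequence[tuple[str, int]] = (),
    seed: int = 0,
) -> tuple[str, dict]:
    """An i.i.d. protein sequence from a boosted composition with planted motifs.

    ``boosts`` multiplies selected residues' background frequencies before
    renormalization (e.g. R,K x2.5 and M x0.3 emulates the arginine-rich
    compact-nuclease profile). ``planted_motifs`` are literal instances
    overwriting their windows at 1-based positions; overlaps are an error.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    if base_composition is None:
        base_composition = ReferenceComposition.default()
    boosts = dict(boosts or {})
    fracs = np.array([base_composition.fractions[a] * boosts.get(a, 1.0) for a in AMINO_ACIDS])
    fracs /= fracs.sum()
    rng = np.random.default_rng(seed)
    residues = np.array(list(AMINO_ACIDS))
    seq = list("".join(residues[rng.choice(20, size=length, p=fracs)]))
    occupied: set[int] = set()
    for instance, pos in planted_motifs:
        span = range(pos - 1, pos - 1 + len(instance))
        if pos < 1 or pos - 1 + len(instance) > length:
            raise ValueError(f"planted motif {instance!r} at {pos} does not fit")
        if occupied & set(span):
            raise ValueError("overlapping planted motifs")
        occupied.update(span)
        seq[pos - 1 : pos - 1 + len(instance)] = list(instance)
    manifest = {
        "generator": "simulate_protein",
        "seed": seed,
        "length": length,
        "boosts": boosts,
        "planted_motifs": [[m, p] for m, p in planted_motifs],
    }
    return "".join(seq), manifest
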