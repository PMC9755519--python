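"""Per-position mismatch-tolerance mapping from plasmid-interference sequencing.

A library of target plasmids carries the reference protospacer plus single-
substitution variants (one to a few alternate bases per position, positions
numbered 1..L from the PAM). The library is sequenced before (input) and
after (survivors) nuclease selection in cells. Variants the nuclease still
cleaves are depleted among survivors; variants carrying a mismatch the
nuclease cannot tolerate survive and are enriched. Comparing each position's
mean log2 enrichment against the perfect-match spacer (the fully-cleaved
anchor) yields per-position tolerated / intolerant / indeterminate calls --
the tolerance heatmap readout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seqio import SeqRecord

__all__ = [
    "Variant",
    "VariantLibrary",
    "ToleranceMap",
    "single_mismatch_library",
    "count_variants",
    "enrichment",
    "position_calls",
    "heatmap_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    """One library member. ``position`` is 1-based from the PAM; 0 for the perfect match."""

    variant_id: str
    position: int
    ref_base: str
    alt_base: str
    protospacer: str


@dataclass
class VariantLibrary:
    """The single-mismatch plasmid library: reference protospacer plus variants."""

    spacer_ref: str
    variants: list[Variant]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for v in self.variants:
            if v.protospacer in seen:
                raise ValueError(
                    f"variants {seen[v.protospacer]!r} and {v.variant_id!r} share a protospacer"
                )
            seen[v.protospacer] = v.variant_id
            diffs = [
                i + 1
                for i, (a, b) in enumerate(zip(self.spacer_ref, v.protospacer))
                if a != b
            ]
            if len(v.protospacer) != len(self.spacer_ref):
                raise ValueError(f"variant {v.variant_id!r}: protospacer length mismatch")
            if v.position == 0:
                if diffs:
                    raise ValueError(
                        f"perfect-match variant {v.variant_id!r} differs from the reference"
                    )
            else:
                if not 1 <= v.position <= len(self.spacer_ref):
                    raise ValueError(f"variant {v.variant_id!r}: position out of range")
                expected = self._spacer_index(v.position)
                if diffs != [expected + 1]:
                    raise ValueError(
                        f"variant {v.variant_id!r} does not differ from the reference at "
                        f"exactly its stated position"
                    )

    def _spacer_index(self, position: int) -> int:
        # positions count 1..L from the PAM; the PAM-proximal end is the 3' end
        # of the protospacer string, so position p maps to string index L - p.
        return len(self.spacer_ref) - position

    @property
    def perfect_id(self) -> str | None:
        for v in self.variants:
            if v.position == 0:
                return v.variant_id
        return None

    def by_id(self) -> dict[str, Variant]:
        return {v.variant_id: v for v in self.variants}

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "variant_id": v.variant_id,
                    "position": v.position,
                    "ref_base": v.ref_base,
                    "alt_base": v.alt_base,
                    "protospacer": v.protospacer,
                }
                for v in self.variants
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, spacer_ref: str | None = None) -> "VariantLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        variants = [
            Variant(
                variant_id=row.variant_id,
                position=int(row.position),
                ref_base=str(row.ref_base),
                alt_base=str(row.alt_base),
                protospacer=str(row.protospacer),
            )
            for row in df.itertuples()
        ]
        if spacer_ref is None:
            perfect = [v for v in variants if v.position == 0]
            if not perfect:
                raise ValueError("spacer_ref not given and no perfect-match entry in library")
            spacer_ref = perfect[0].protospacer
        return cls(spacer_ref=spacer_ref, variants=variants)


def single_mismatch_library(spacer_ref: str, alts_per_position: int = 1) -> VariantLibrary:
    """Build a canonical library: one perfect match plus single substitutions.

    ``alts_per_position`` alternate bases are chosen per position in fixed
    cyclic order (A->C->G->T->A, ...), so the library is deterministic. With
    a 24 nt spacer and one alternate per position this is the 25-member
    library layout used in the interference assay.
    """
    order = "ACGT"
    variants = [Variant("perfect", 0, "-", "-", spacer_ref)]
    L = len(spacer_ref)
    for pos in range(1, L + 1):
        idx = L - pos
        ref_base = spacer_ref[idx]
        alts = [b for b in order if b != ref_base][:alts_per_position]
        for alt in alts:
            proto = spacer_ref[:idx] + alt + spacer_ref[idx + 1 :]
            suffix = "" if alts_per_position == 1 else f"_{alt}"
            variants.append(Variant(f"p{pos:02d}{suffix}", pos, ref_base, alt, proto))
    return VariantLibrary(spacer_ref=spacer_ref, variants=variants)


def count_variants(
    reads: Iterable[SeqRecord],
    library: VariantLibrary,
    flank5: str,
    flank3: str,
) -> tuple[dict[str, int], int]:
    """Assign reads to library variants by exact protospacer match between flanks.

    Returns ``(counts, unassigned)``. A read is assigned iff the sequence
    between the first ``flank5`` occurrence and the following ``flank3``
    occurrence equals one variant's protospacer exactly; anything else
    (sequencing errors, chimeras, missing flanks) is unassigned, never
    force-assigned.
    """
    lookup = {v.protospacer: v.variant_id for v in library.variants}
    counts = {v.variant_id: 0 for v in library.variants}
    unassigned = 0
    for read in reads:
        seq = read.sequence
        i = seq.find(flank5)
        if i < 0:
            unassigned += 1
            continue
        start = i + len(flank5)
        j = seq.find(flank3, start)
        if j < 0:
            unassigned += 1
            continue
        vid = lookup.get(seq[start:j])
        if vid is None:
            unassigned += 1
        else:
            counts[vid] += 1
    return counts, unassigned


def enrichment(
    counts_out: Mapping[str, int],
    counts_in: Mapping[str, int],
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """Log2 relative-frequency enrichment of each variant in survivors vs input.

    e(v) = log2( ((out_v + pc) / (Out + pc*V)) / ((in_v + pc) / (In + pc*V)) )
    with V the number of variants. Relative frequencies make the statistic
    invariant to sequencing depth; survivors of uncleavable variants have
    e > 0, efficiently cleaved variants e < 0.
    """
    ids = sorted(set(counts_out) | set(counts_in))
    if not ids:
        raise ValueError("empty counts")
    V = len(ids)
    total_out = sum(counts_out.get(v, 0) for v in ids)
    total_in = sum(counts_in.get(v, 0) for v in ids)
    if total_out <= 0 or total_in <= 0:
        raise ValueError("both libraries must contain reads")
    denom_out = total_out + pseudocount * V
    denom_in = total_in + pseudocount * V
    return {
        v: math.log2(
            ((counts_out.get(v, 0) + pseudocount) / denom_out)
            / ((counts_in.get(v, 0) + pseudocount) / denom_in)
        )
        for v in ids
    }


@dataclass
class ToleranceMap:
    """Enrichment per variant plus per-position scores and tolerance calls."""

    counts_in: dict[str, int]
    counts_out: dict[str, int]
    enrichment: dict[str, float]
    position_score: dict[int, float]
    calls: dict[int, str]  # "tolerated" | "intolerant" | "indeterminate"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": sorted(self.calls),
                "score": [self.position_score[p] for p in sorted(self.calls)],
                "call": [self.calls[p] for p in sorted(self.calls)],
            }
        )


def position_calls(
    e: Mapping[str, float],
    library: VariantLibrary,
    perfect_id: str,
    margin: float = 1.0,
    counts_in: Mapping[str, int] | None = None,
    counts_out: Mapping[str, int] | None = None,
) -> ToleranceMap:
    """Per-position tolerance calls anchored on the perfect-match spacer.

    position_score(p) is the mean enrichment over that position's mismatch
    variants. A tolerated mismatch is still cleaved, so its survivors deplete
    like the perfect match: tolerated iff score <= e(perfect) + margin;
    intolerant iff score >= e(perfect) + 2*margin; otherwise indeterminate.
    """
    if perfect_id not in e:
        raise ValueError(f"perfect-match variant {perfect_id!r} absent from enrichment map")
    e_perfect = e[perfect_id]
    by_position: dict[int, list[float]] = {}
    for v in library.variants:
        if v.position == 0:
            continue
        if v.variant_id in e:
            by_position.setdefault(v.position, []).append(e[v.variant_id])
    positions = range(1, len(library.spacer_ref) + 1)
    scores: dict[int, float] = {}
    calls: dict[int, str] = {}
    for p in positions:
        vals = by_position.get(p)
        if not vals:
            logger.warning("position %d has no assayed variants; omitted from calls", p)
            continue
        score = sum(vals) / len(vals)
        scores[p] = score
        if score <= e_perfect + margin:
            calls[p] = "tolerated"
        elif score >= e_perfect + 2 * margin:
            calls[p] = "intolerant"
        else:
            calls[p] = "indeterminate"
    return ToleranceMap(
        counts_in=dict(counts_in or {}),
        counts_out=dict(counts_out or {}),
        enrichment=dict(e),
        position_score=scores,
        calls=calls,
    )


def heatmap_table(tol_map: ToleranceMap, library: VariantLibrary) -> pd.DataFrame:
    """Position x alternate-base table of enrichment values.

    Cells for unassayed (position, base) pairs are NaN (empty), not zero;
    one filled cell per mismatch variant with an enrichment value.
    """
    positions = range(1, len(library.spacer_ref) + 1)
    table = pd.DataFrame(
        float("nan"), index=pd.Index(positions, name="position"), columns=list("ACGT")
    )
    for v in library.variants:
        if v.position == 0 or v.variant_id not in tol_map.enrichment:
            continue
        table.loc[v.position, v.alt_base] = tol_map.enrichment[v.variant_id]
    return table
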