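# Methods

This note documents the models and procedures behind each pipeline, the
parameter defaults and why they were chosen, the design decisions made where
the assay descriptions left choices open, and the limitations of the
synthetic-data validation.

## PAM discovery (`pam_discovery`)

**Assay model.** An 8N-randomized PAM plasmid library is cleaved in vitro by
the nuclease:sgRNA complex; cleavage products are blunted and
adapter-ligated, so each sequenced molecule reads
`adapter + protospacer-remnant + PAM + backbone-anchor` (or its reverse
complement, depending on which end the sequencer enters). The fixed backbone
anchor (14–24 bp, supplied per assay in the layout config) locates the PAM
window; the number of bases between the adapter's end and the PAM-proximal
edge is the cut distance, i.e. the cleavage position measured from the PAM
on the sequenced strand. This is an enrichment-style design: uncleaved
molecules are never sequenced.

**Filters.** Reads with mean Phred quality ≤ 20 are dropped (the threshold
is strict `>`; whether the original filter was per-base, windowed, or
per-read mean is not documented anywhere we know of, so the per-read mean —
the simplest and most common choice — is the recorded default, exposed as
`--min-mean-q`). Anchor and adapter must match exactly; reads failing either
are tallied (`no_anchor`, `no_adapter`, `too_short`) rather than silently
dropped, so `n_raw` is fully accounted. A `--max-anchor-mismatch` escape
hatch exists but defaults to 0. Observations outside modal cut ± 2 are
excluded before building the matrix; the modal cut breaks ties toward the
smaller (PAM-proximal) distance. The modal cut is computed jointly over all
PAMs, not per-PAM.

**PFM and consensus.** The position frequency matrix adds a pseudocount of
0.5 per cell before row normalization (keeps logs finite; results at depth
≥ 10³ are insensitive to it). Information content per position is
`2 + Σ f log₂ f` bits; logo heights are frequency × information. The IUPAC
consensus includes every base with frequency ≥ 0.25 (a base must beat the
uniform expectation), with two guards: a position where all four or no bases
qualify is `N`, and a position whose information content is below a noise
floor (default 0.05 bits) is `N` outright. The floor exists because at a
truly uninformative position the empirical frequencies jitter around 0.25,
and a raw threshold would emit an arbitrary partial code roughly half the
time; 0.05 bits is ~100× the expected small-sample bias of the plug-in
entropy estimator at depth 5000 (≈ 3/(2·ln2·n) bits) and 8× below the
weakest real signal of interest (a two-base degenerate position carries
1 bit).

**Overhang geometry.** The target-strand cut site comes from an external
measurement (run-off sequencing) and is combined with the retained
non-target-strand cut-distance support. All NTS positions PAM-distal of the
TS cut ⇒ 5′ overhang; PAM-proximal ⇒ 3′ overhang; identical ⇒ blunt.
Overhang lengths are reported as magnitudes with the direction carried by
the type (so a TS cut at 5 with NTS at 4 is a 1-nt 3′ overhang). Zero-length
entries may coexist with one sign (e.g. NTS {3,5} with TS 3 is called 5′);
genuinely mixed signs raise an error rather than averaging incompatible
geometries.

## Mismatch specificity (`mismatch_specificity`)

**Assay model.** A library of target plasmids — one perfect-match
protospacer plus single-substitution variants at positions 1..L from the PAM
(L = 24 by default; 25 members with one alternate base per position) — is
transformed into cells expressing the nuclease and guide. Cleavable variants
kill their host; survivors are sequenced and compared with the untreated
input library.

**Statistic.** Log₂ ratio of relative frequencies with pseudocount 1 (keeps
zero-count variants finite; relative frequencies cancel library-size
differences). The original analysis reported enrichment only qualitatively,
so the per-position call is a recorded effect-size rule rather than a test:
the perfect-match spacer anchors the "fully cleaved" level, and a position is
*tolerated* if its mean variant enrichment is ≤ anchor + margin, *intolerant*
if ≥ anchor + 2·margin, otherwise *indeterminate*. The default margin of one
log₂ unit is far below the separation the assay produces (≈ 6 log₂ units
between classes at realistic cleavage rates) and far above counting noise at
depth ≥ 10³, so the calls are insensitive to it over more than an order of
magnitude; `--margin` exposes it. Multiple alternate bases per position are
averaged for the call; the per-substitution table is emitted alongside.
Reads are assigned to variants by exact protospacer match between the
flanks — single-substitution variants make Hamming-nearest assignment
ambiguous only for error-bearing reads, which are safer left unassigned. No
multiple-testing machinery is used, matching the qualitative readout.

## Protein screen (`protein_screen`)

**Composition deviation.** Observed residue fractions are regressed (OLS,
slope + intercept) against a packaged background table — the UniProtKB/
Swiss-Prot average composition, standing in for a database-wide background
and swappable via `--ref-comp`. Residuals are standardized by a robust scale
(1.4826 × median absolute deviation). A plain residual standard deviation
was rejected: two strongly enriched residues dominate the sum of squares and
cap their own z-scores near √(n/2) ≈ 3 while masking a depleted methionine
entirely, and an exact fit degenerates to 0/0. With the MAD scale the
17-residue bulk defines the noise level and outliers are measured against
it. Flags: `arg_lys_enriched` iff R and K are both > +2σ (default,
`--sigma`); `met_depleted` iff M < −2σ.

**Motif grammar.** Patterns combine fixed residues, `X` (any), `X(m,n)` /
`X(m-n)` bounded gaps (the two notations are treated as identical), and
`[AB]` / `[A/B]` alternation. All match start positions are reported
(overlaps allowed); at each start only the shortest match (minimal end over
gap choices) is kept so nested gap alternatives are never double counted.
The default set: `RRXRR`; zinc ribbons `CX(2,4)C`, `CX(2,4)H`, `HX(2,4)C`;
Zn-finger `CX(2,4)CX(27,31)CX(2,4)[C/H]`. The finder is validated against an
independent regex oracle on random sequences.

**Charge and pI.** Henderson–Hasselbalch per ionizable group (D, E, C, Y, H,
K, R, both termini) with the EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5,
D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); alternative sets can be passed
programmatically. Net charge is strictly decreasing in pH, so the pI is the
unique root, found by 60 bisections on [0, 14] — enough to hold the charge
residual at the root below 0.01 elementary charges even for very long
sequences with steep titration curves.

**Verdict.** `SMART-like` = length within 400–1050 aa ∧ `arg_lys_enriched` ∧
(≥ 1 RRXRR ∨ ≥ 2 zinc ribbons). Counts are reported raw; a cross-family
significance test against reference nuclease panels is out of scope (it
needs the reference panel).

## Guide design (`guide_design`)

The repeat:anti-repeat duplex is identified by a Smith–Waterman local
alignment of the repeat against the reversed tracrRNA with complementarity
scoring (Watson–Crick +1, G:U wobble +1 when enabled, mismatch −2, gap −3;
ties resolved toward the repeat's 3′ end). This replaces thermodynamic
folding deliberately: the artifact's job is deterministic scaffold
construction, not ΔG prediction, and the duplex of interest is near-perfect,
making the result insensitive to the exact scores (asserted by an
oracle-equivalence test). An externally folded dot-bracket structure can
override the alignment via `duplex_from_dotbracket` / `--dotbracket`.

Designs are the cartesian product of helix trim levels × spacer lengths ×
tracr termination points: `spacer + trimmed-repeat + GAAA + trimmed-
anti-repeat + tracr-tail`. Trimming removes base pairs from the
tetraloop-proximal helix end symmetrically on both strands (whether the
original trimming was symmetric is not documented; symmetric is the recorded
choice). Spacers truncate from the 5′ (PAM-distal) end, the standard
guide-truncation convention. Combinations that would leave fewer than
`min_duplex` pairs (default 6), exceed the source spacer, or terminate
inside the anti-repeat are skipped with a warning. Sequences are handled in
the DNA alphabet and emitted as RNA. Note that G:U wobble pairing is not
strand-symmetric (G:T maps to C:A under reverse complement), so the
mirror-image symmetry of duplex calls holds only for pure Watson–Crick
pairing.

## Edit quantification (`edit_quant`)

Global affine-gap (Gotoh) alignment of each read to the amplicon, defaults
match 2, mismatch −3, gap open −8 (cost of the first gap base), extend −1.
Tie-breaking is fixed: at equal score a substitution beats a gap, and a
deletion beats an insertion — making op lists deterministic and planted-
indel recovery exact. Alignments under 60 % identity are rejected (off-target
amplicon / primer-dimer guard, `--min-identity`). These numerical choices are
recorded defaults of this implementation; the readouts they feed are
per-position marginal edit fractions (no haplotype phasing) and the fraction
of reads with an indel overlapping the editing window (`--whole-amplicon`
widens to the full amplicon). Base quality does not mask calls by default
(an optional threshold exists). The kernel is numba-compiled and verified
against an exhaustive-path DP oracle on small instances.

## Synthetic data (`simulate`)

The generators define the study conditions used throughout the tests and the
acceptance script:

- **PAM assay**: uniform random 8-mer PAMs; cleavage probability 1.0 for
  truth-matching PAMs and 0.0 otherwise (the idealized enrichment assay —
  only cleaved molecules are sequenced); cut distances {5: 0.55, 6: 0.30,
  7: 0.15} (the 5–7 nt regime of a 5′-overhang-producing nuclease); per-base
  substitution error 1 %; both read orientations at 50 %; constant Q37.
  `n` counts emitted reads; molecules are drawn (vectorized, in batches)
  until `n` cleaved reads exist, and the batch's random draws are consumed
  in full so the stream is reproducible regardless of `n`.
- **Mismatch assay**: uniform multinomial input at depth 10,000 per variant;
  Bernoulli survival at 1 − cleavage probability, with cleavage 0.99 for
  tolerated and 0.05 for intolerant variants; default truth profile
  "intolerant at 1–13 except 9, tolerated 14–24" (the long-seed pattern) on
  a 24-nt spacer with the canonical 25-member library.
- **Amplicon assay**: planted substitutions applied independently per read
  at their fractions, one optional planted indel, substitution-only
  sequencing error 0.1 %. A substitution falling inside an applied deletion
  is skipped with a warning.
- **Proteins**: i.i.d. residues from the background composition with
  multiplicative boosts (the SMART-like fixture boosts R and K ×2.5 and M
  ×0.3 on 600 aa) and literal motif instances overwriting their windows.

All generators are bit-reproducible under a fixed seed and emit a JSON truth
manifest consumed directly by the tests.

**What recovery on synthetic data does not show.** Reads have no quality
gradients, PCR duplicates, chimeras beyond the adapter-failure class, or
read-level indel errors (substitution-only error keeps the alignment oracle
exact — a documented simplification); protein fixtures are i.i.d. with
planted motifs, not homology-structured. Passing tests therefore demonstrate
correctness of the statistics and the filters under the modeled error
processes, not robustness to every real-library artifact. Problem sizes in
the test suite and acceptance script (10,000 reads per PAM class, depth
10,000 per variant, 10,000 amplicon reads, 100-protein calibration panels)
were chosen as the package's standard verification conditions; they complete
in seconds on a single core.

## Degenerate inputs and numerical conventions

- Empty observation lists, empty count maps, zero-depth libraries, and
  zero accepted alignments raise descriptive `ValueError`s that the CLI maps
  to exit code 1 (usage errors exit 2).
- FASTQ is Phred+33 only; input that decodes above Q45 is rejected as
  probable Phred+64 with a clear message.
- PAMs containing ambiguous bases are excluded from the frequency matrix but
  retained in the cut histogram.
- Enrichment is exactly antisymmetric under in/out swap; scale invariance is
  exact at pseudocount 0 and holds to O(pc/total) at the default.
- CLI manifests key input checksums by basename so identical runs in
  different directories produce identical output trees.
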