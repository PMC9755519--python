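import numpy as np
import pytest

from smartchar import simulate
from smartchar.pam_discovery import (
    AssayLayout,
    PamObservation,
    build_profile,
    call_consensus,
    collect_observations,
    extract_observation,
    infer_overhang,
    locate_anchor,
    logo_matrix,
)
from smartchar.seqio import SeqRecord, iupac_match, reverse_complement

ADAPTER = "ACACGACGCT"
ANCHOR = "GTTCACTGCCGTATAG"
LAYOUT = AssayLayout(adapter=ADAPTER, anchor=ANCHOR)


def _read(remnant: str, pam: str = "TGGATCAA") -> SeqRecord:
    return SeqRecord("r", ADAPTER + remnant + pam + ANCHOR)


class TestAnchorAndExtraction:
    def test_forward_hit_by_construction(self):
        read = _read("ACGTA")
        assert locate_anchor(read, LAYOUT) == (10 + 5 + 8, "forward")

    def test_reverse_hit_mirrors_forward(self):
        read = _read("ACGTA")
        rc = SeqRecord("r", reverse_complement(read.sequence))
        pos, orient = locate_anchor(rc, LAYOUT)
        assert orient == "reverse"
        obs, reason = extract_observation(rc, (pos, orient), LAYOUT)
        assert reason == "ok"
        assert obs.pam == "TGGATCAA"
        assert obs.cut_distance == 5

    def test_anchor_absent_returns_none(self, rng):
        bases = np.array(list("ACGT"))
        hits = 0
        for _ in range(10_000):
            read = SeqRecord("r", "".join(bases[rng.integers(0, 4, 100)]))
            if locate_anchor(read, LAYOUT) is not None:
                hits += 1
        # chance of a 16-mer in 100 random bases ~ 2 * 85 * 4^-16 per read
        assert hits == 0

    def test_anchor_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="14-24"):
            AssayLayout(adapter=ADAPTER, anchor="ACGTACGTACGT")  # 12 nt

    @pytest.mark.parametrize("remnant,expected_cut", [("ACGTA", 5), ("", 0)])
    def test_cut_distance_by_construction(self, remnant, expected_cut):
        read = _read(remnant)
        hit = locate_anchor(read, LAYOUT)
        obs, reason = extract_observation(read, hit, LAYOUT)
        assert reason == "ok"
        assert obs.pam == "TGGATCAA"
        assert obs.cut_distance == expected_cut

    def test_missing_adapter_tallied_not_dropped_silently(self):
        no_adapter = SeqRecord("r", "TTTTT" + "TGGATCAA" + ANCHOR)
        obs, tally = collect_observations([no_adapter, _read("AC")], LAYOUT)
        assert tally == {"ok": 1, "no_anchor": 0, "too_short": 0, "no_adapter": 1}
        assert len(obs) == 1

    def test_cut_distance_distribution_recovered(self):
        truth = simulate.PamTruth(pam_iupac="NGG", error_rate=0.0, orientation_mix=0.0)
        reads, _ = simulate.simulate_pam_reads(truth, LAYOUT, n=10_000, seed=11)
        obs, _ = collect_observations(reads, LAYOUT)
        dists = np.array([o.cut_distance for o in obs])
        n = len(dists)
        for d, p in truth.cut_dist.items():
            count = int((dists == d).sum())
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) <= 3 * sigma


class TestProfile:
    def test_degenerate_single_pam(self):
        obs = [PamObservation("AGGTTTTT", 5, "forward") for _ in range(50)]
        prof = build_profile(obs)
        assert prof.modal_cut == 5
        assert prof.consensus.startswith("AGG")
        assert prof.pfm[0, 0] > 0.95  # A dominates position 1
        np.testing.assert_allclose(prof.pfm.sum(axis=1), 1.0, atol=1e-9)

    def test_ngg_recovery_with_sequencing_error(self):
        truth = simulate.PamTruth(pam_iupac="NGG", error_rate=0.01)
        reads, _ = simulate.simulate_pam_reads(truth, LAYOUT, n=10_000, seed=7)
        obs, _ = collect_observations(reads, LAYOUT)
        prof = build_profile(obs)
        assert prof.consensus == "NGGNNNNN"
        assert prof.modal_cut == 5

    def test_religation_artifacts_excluded(self, rng):
        good = [
            PamObservation("ACGTACGT", int(rng.choice([5, 6, 7], p=[0.55, 0.3, 0.15])), "forward")
            for _ in range(800)
        ]
        artifacts = [PamObservation("ACGTACGT", 15, "forward") for _ in range(200)]
        prof = build_profile(good + artifacts)
        assert prof.n_raw == 1000
        assert prof.n_retained == 800
        assert all(abs(d - prof.modal_cut) <= 2 for d in prof.cut_histogram)

    def test_modal_cut_tie_breaks_to_smaller_distance(self):
        obs = [PamObservation("AAAAAAAA", d, "forward") for d in [3, 3, 7, 7]]
        assert build_profile(obs).modal_cut == 3

    def test_empty_observations_error(self):
        with pytest.raises(ValueError, match="no PAM observations"):
            build_profile([])

    def test_orientation_invariance(self):
        truth = simulate.PamTruth(pam_iupac="NRC", error_rate=0.0)
        reads, _ = simulate.simulate_pam_reads(truth, LAYOUT, n=2000, seed=13)
        flipped = [
            SeqRecord(r.id, reverse_complement(r.sequence), r.quality) for r in reads
        ]
        p1 = build_profile(collect_observations(reads, LAYOUT)[0])
        p2 = build_profile(collect_observations(flipped, LAYOUT)[0])
        np.testing.assert_allclose(p1.pfm, p2.pfm)
        assert p1.consensus == p2.consensus
        assert p1.cut_histogram == p2.cut_histogram

    def test_information_decreases_with_error_rate(self):
        profiles = {}
        for err in (0.0, 0.01, 0.05):
            truth = simulate.PamTruth(pam_iupac="NGG", error_rate=err)
            reads, _ = simulate.simulate_pam_reads(truth, LAYOUT, n=4000, seed=21)
            profiles[err] = build_profile(collect_observations(reads, LAYOUT)[0])
        for pos in range(8):
            i0 = profiles[0.0].information_bits[pos]
            i1 = profiles[0.01].information_bits[pos]
            i2 = profiles[0.05].information_bits[pos]
            # strict ordering at informative positions; sampling jitter at
            # uninformative ones stays within a small tolerance
            assert i1 <= i0 + 0.02
            assert i2 <= i1 + 0.02

    def test_recovery_of_random_iupac_truths(self):
        """Error-free reads at depth 5000 recover any <=4-informative-position truth."""
        rng = np.random.default_rng(99)
        codes = list("ACGTRYSWKMBDHV")
        for trial in range(20):
            n_info = int(rng.integers(1, 5))
            truth_str = "".join(rng.choice(codes, size=n_info))
            truth = simulate.PamTruth(
                pam_iupac=truth_str, error_rate=0.0,
                cut_dist={5: 1.0},
            )
            reads, _ = simulate.simulate_pam_reads(
                truth, LAYOUT, n=5000, seed=1000 + trial
            )
            prof = build_profile(collect_observations(reads, LAYOUT)[0])
            expected = truth_str + "N" * (8 - n_info)
            assert prof.consensus == expected, f"truth {truth_str}: got {prof.consensus}"


class TestConsensus:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.05, 0.05, 0.85, 0.05), "G"),
            ((0.45, 0.02, 0.51, 0.02), "R"),
            ((0.25, 0.25, 0.25, 0.25), "N"),
            ((0.30, 0.30, 0.30, 0.10), "V"),
        ],
    )
    def test_single_rows(self, row, expected):
        assert call_consensus(np.array([row])) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            call_consensus(np.array([[0.25, 0.25, 0.25, 0.25]]), include_threshold=0.0)
        with pytest.raises(ValueError):
            call_consensus(np.array([[0.25, 0.25, 0.25, 0.25]]), include_threshold=1.5)

    def test_near_uniform_position_is_n(self):
        # sampling jitter around uniform must not produce a partial code
        row = np.array([[0.2505, 0.2497, 0.2501, 0.2497]])
        assert call_consensus(row) == "N"


class TestLogoMatrix:
    def test_uniform_column_has_zero_height(self):
        obs = [PamObservation(b * 8, 5, "forward") for b in "ACGT" for _ in range(25)]
        prof = build_profile(obs)
        table = logo_matrix(prof)
        assert table.to_numpy().max() < 0.01

    def test_pure_column_two_bits_without_pseudocount(self):
        obs = [PamObservation("GGGGGGGG", 5, "forward") for _ in range(100)]
        prof = build_profile(obs, pseudocount=0.0)
        table = logo_matrix(prof)
        np.testing.assert_allclose(table["G"].to_numpy(), 2.0)
        np.testing.assert_allclose(
            table.sum(axis=1).to_numpy(), prof.information_bits
        )

    def test_informative_positions_dominate(self):
        truth = simulate.PamTruth(pam_iupac="NGG", error_rate=0.01)
        reads, _ = simulate.simulate_pam_reads(truth, LAYOUT, n=5000, seed=3)
        prof = build_profile(collect_observations(reads, LAYOUT)[0])
        table = logo_matrix(prof)
        col_info = table.sum(axis=1)
        assert col_info.loc[2] + col_info.loc[3] > 0.8 * col_info.sum()


class TestOverhang:
    def test_five_prime_staggered_geometry(self):
        obs = [
            PamObservation("AAAAAAAA", d, "forward")
            for d, k in ((5, 55), (6, 30), (7, 15))
            for _ in range(k)
        ]
        prof = build_profile(obs)
        call = infer_overhang(3, prof)
        assert call.overhang_type == "five_prime"
        assert call.nts_positions == (5, 6, 7)
        assert call.overhang_lengths == (2, 3, 4)

    def test_blunt_when_nts_equals_ts(self):
        obs = [PamObservation("AAAAAAAA", 3, "forward") for _ in range(10)]
        call = infer_overhang(3, build_profile(obs))
        assert call.overhang_type == "blunt"
        assert call.overhang_lengths == (0,)

    def test_three_prime_reports_magnitude(self):
        obs = [PamObservation("AAAAAAAA", 4, "forward") for _ in range(10)]
        call = infer_overhang(5, build_profile(obs))
        assert call.overhang_type == "three_prime"
        assert call.overhang_lengths == (1,)

    def test_mixed_signs_rejected(self):
        obs = [PamObservation("AAAAAAAA", d, "forward") for d in (4, 4, 6, 6)]
        with pytest.raises(ValueError, match="inconsistent cut geometry"):
            infer_overhang(5, build_profile(obs))
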