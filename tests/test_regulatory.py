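"""Divergence profiles, shadowing HMM, motif scanning and locus matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from candevo.regulatory import (
    MBE_PATTERN,
    CalibrationError,
    RunPattern,
    ShadowHMM,
    calibrate_hmm,
    column_divergence,
    divergence_profile,
    motif_matrix,
    scan_mbe,
    scan_pattern,
    segment_islands,
    variant_indicator,
)
from candevo.seqdata import UTRAlignment
from candevo.synthetic import SimConfig, simulate_orf, simulate_tree, simulate_utr
from conftest import brute_force_mbe, jaccard


class TestDivergenceProfile:
    def test_identical_sequences_give_zero(self):
        utr = UTRAlignment(("a", "b", "c"), ("ACGTACGT",) * 3)
        prof = divergence_profile(utr, window=4, step=2)
        assert np.all(prof.values == 0.0)

    def test_window_equal_to_length_reduces_to_global_mean(self):
        utr = UTRAlignment(("a", "b"), ("AAAA", "AAAT"))
        prof = divergence_profile(utr, window=4)
        assert len(prof.values) == 1
        assert prof.values[0] == pytest.approx(np.nanmean(column_divergence(utr)))

    def test_planted_divergent_block_elevated(self):
        cfg = SimConfig(seed=31)
        utr, truth = simulate_utr(cfg)
        prof = divergence_profile(utr, window=20, step=5)
        island = truth.island_coords[0]
        inside = [v for s, v in zip(prof.starts, prof.values)
                  if island[0] <= s and s + 20 <= island[1]]
        outside = [v for s, v in zip(prof.starts, prof.values)
                   if s + 20 <= island[0] - 50]
        assert np.mean(inside) < np.mean(outside)

    def test_window_larger_than_alignment_rejected(self):
        utr = UTRAlignment(("a",), ("ACGT",))
        with pytest.raises(ValueError, match="window"):
            divergence_profile(utr, window=5)


class TestCalibration:
    def test_closed_form_initialization(self):
        orf = np.zeros(100, dtype=int)  # fully invariant ORF
        rng = np.random.default_rng(0)
        utr = (rng.random(400) < 0.5).astype(int)
        hmm = calibrate_hmm(orf, utr, max_iter=0)
        assert hmm.theta_c == pytest.approx(1 / 102)
        assert hmm.theta_n == pytest.approx((utr.sum() + 1) / 402, abs=1e-9)

    def test_uninformative_calibration_rejected(self):
        orf = np.ones(50, dtype=int)
        utr = np.zeros(50, dtype=int)
        with pytest.raises(CalibrationError):
            calibrate_hmm(orf, utr)

    def test_em_loglik_monotone_nondecreasing(self):
        cfg = SimConfig(seed=33)
        tree = simulate_tree(cfg)
        orf, _, _ = simulate_orf(cfg, tree)
        utr, _ = simulate_utr(cfg, tree)
        hmm = calibrate_hmm(variant_indicator(orf), variant_indicator(utr))
        trace = hmm.loglik_trace
        assert len(trace) >= 2
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_parameter_recovery(self):
        """Fitted emission rates land near the generating variant fractions."""
        errs = []
        for seed in range(5):
            cfg = SimConfig(seed=seed)
            tree = simulate_tree(cfg)
            orf, _, _ = simulate_orf(cfg, tree)
            utr, truth = simulate_utr(cfg, tree)
            x = variant_indicator(utr)
            island_mask = np.zeros(cfg.utr_length, bool)
            for a, b in truth.island_coords:
                island_mask[a:b] = True
            hmm = calibrate_hmm(variant_indicator(orf), x)
            errs.append(abs(hmm.theta_n - x[~island_mask].mean()))
        assert max(errs) < 0.1


class TestSegmentation:
    def test_all_invariant_utr_is_one_island(self):
        utr = UTRAlignment(("a", "b"), ("A" * 200, "A" * 200))
        hmm = ShadowHMM(0.01, 0.5, np.array([[0.99, 0.01], [0.01, 0.99]]), lmin=50)
        islands = segment_islands(utr, hmm)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (0, 200)

    def test_lmin_larger_than_runs_gives_empty_list(self):
        utr = UTRAlignment(("a", "b"), ("A" * 30, "A" * 30))
        hmm = ShadowHMM(0.01, 0.5, np.array([[0.99, 0.01], [0.01, 0.99]]), lmin=50)
        assert segment_islands(utr, hmm) == []

    def test_planted_islands_recovered(self):
        """Reported islands overlap planted ones with Jaccard >= 0.8."""
        for seed in (41, 42, 43):
            cfg = SimConfig(seed=seed)
            tree = simulate_tree(cfg)
            orf, _, _ = simulate_orf(cfg, tree)
            utr, truth = simulate_utr(cfg, tree)
            hmm = calibrate_hmm(variant_indicator(orf), variant_indicator(utr))
            found = [(i.start, i.end) for i in segment_islands(utr, hmm)]
            for t in truth.island_coords:
                assert max((jaccard(t, f) for f in found), default=0.0) >= 0.8

    def test_islands_disjoint_sorted_and_long_enough(self):
        cfg = SimConfig(seed=44)
        tree = simulate_tree(cfg)
        orf, _, _ = simulate_orf(cfg, tree)
        utr, _ = simulate_utr(cfg, tree)
        hmm = calibrate_hmm(variant_indicator(orf), variant_indicator(utr))
        islands = segment_islands(utr, hmm)
        for a, b in zip(islands, islands[1:]):
            assert a.end <= b.start
        assert all(i.length >= hmm.lmin for i in islands)


class TestScanner:
    @pytest.mark.parametrize(
        "seq,expect",
        [
            ("GTAGT", [(0, 5, 1)]),
            ("ATTTAGT", [(0, 7, 3)]),
            ("CTAGT", []),
            ("GTAGTAGT", [(0, 5, 1), (3, 8, 1)]),
        ],
    )
    def test_hand_scanned_cases(self, seq, expect):
        hits = scan_mbe(seq, allow_overlap=True)
        assert [(h.start, h.end, h.run_length) for h in hits] == expect

    def test_no_overlap_mode_skips_contained_starts(self):
        hits = scan_mbe("GTAGTAGT", allow_overlap=False)
        assert [(h.start, h.end) for h in hits] == [(0, 5)]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_matches_bruteforce_on_random_sequences(self, seq):
        got = {(h.start, h.end) for h in scan_mbe(seq, allow_overlap=True)}
        assert got == brute_force_mbe(seq)

    def test_pluggable_pattern(self):
        pat = RunPattern("Y", "A", 2, 3, "CC", name="toy")
        hits = scan_pattern("TAAACC", pat)
        assert [(h.start, h.end, h.run_length) for h in hits] == [(0, 6, 3)]


class TestMotifMatrix:
    def test_single_taxon_matrix(self):
        utr = UTRAlignment(("only",), ("AAGTAGTAA",))
        mat = motif_matrix(utr)
        assert list(mat.presence.index) == ["only"]
        assert set(mat.frequencies) <= {0.0, 1.0}

    def test_disjoint_hits_make_two_loci(self):
        utr = UTRAlignment(("x", "y"), ("GTAGTCCCCCCCCCC", "CCCCCCCCCCGTAGT"))
        mat = motif_matrix(utr)
        assert len(mat.loci) == 2
        assert np.allclose(mat.frequencies, [0.5, 0.5])

    def test_frequencies_invariant_to_taxon_order(self):
        cfg = SimConfig(seed=51)
        utr, _ = simulate_utr(cfg)
        rev = UTRAlignment(tuple(reversed(utr.taxa)), tuple(reversed(utr.sequences)))
        m1, m2 = motif_matrix(utr), motif_matrix(rev)
        assert m1.loci == m2.loci
        assert np.allclose(np.sort(m1.frequencies), np.sort(m2.frequencies))

    def test_locus_frequency_equals_simulated_truth(self):
        """Scanner-recovered presence at planted loci matches ground truth."""
        for seed in (52, 53):
            cfg = SimConfig(seed=seed)
            utr, truth = simulate_utr(cfg)
            mat = motif_matrix(utr)
            for k, m in enumerate(truth.motif_loci):
                span = (m["position"], m["position"] + len(m["instance"]))
                li = [i for i, (a, b) in enumerate(mat.loci) if a < span[1] and b > span[0]]
                want = np.mean([truth.motif_presence[t][k] for t in utr.taxa])
                got = mat.frequencies[li[0]] if li else 0.0
                assert got == pytest.approx(want)

    def test_external_hits_for_unknown_taxon_rejected(self):
        utr = UTRAlignment(("x",), ("GTAGT",))
        from candevo.regulatory import MotifHit

        with pytest.raises(ValueError, match="absent"):
            motif_matrix(utr, hits_by_taxon={"z": [MotifHit("z", 0, 5, 1)]})
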