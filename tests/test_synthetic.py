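"""Simulator contracts: determinism, rate expectations, truth consistency."""

import numpy as np
import pytest

from candevo.regulatory import scan_mbe
from candevo.seqdata import GENETIC_CODE, STOP_CODONS
from candevo.synthetic import (
    SimConfig,
    simulate_orf,
    simulate_reporter,
    simulate_tree,
    simulate_utr,
)

ZERO_TREE = "((A:0,B:0):0,(C:0,D:0):0);"


class TestSimulateOrf:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=11, n_taxa=6, n_codons=50)
        a1, t1, tr1 = simulate_orf(cfg)
        a2, t2, tr2 = simulate_orf(cfg)
        assert a1.sequences == a2.sequences
        assert t1.to_newick() == t2.to_newick()
        assert tr1.ancestral == tr2.ancestral

    def test_zero_branch_lengths_give_identical_tips(self):
        cfg = SimConfig(seed=1, tree_newick=ZERO_TREE, n_codons=30)
        aln, tree, truth = simulate_orf(cfg)
        root = truth.ancestral["node0"]
        assert all(s == root for s in aln.sequences)

    def test_no_stop_codons_ever(self):
        cfg = SimConfig(seed=2, n_taxa=8, n_codons=60, omega_background=1.0)
        aln, _, truth = simulate_orf(cfg)
        for seq in list(aln.sequences) + list(truth.ancestral.values()):
            for j in range(0, len(seq), 3):
                assert seq[j : j + 3] not in STOP_CODONS

    def test_omega_zero_means_no_nonsynonymous_changes(self):
        cfg = SimConfig(seed=3, n_taxa=8, n_codons=80, hotspot_fraction=0.0,
                        omega_background=0.0, background_rate=0.01)
        aln, _, truth = simulate_orf(cfg)
        assert sum(s["nonsyn"] for s in truth.site_changes) == 0
        assert sum(s["syn"] for s in truth.site_changes) > 0

    def test_neutral_event_count_matches_poisson_expectation(self):
        """At omega=1 realized substitutions are Poisson(sum branch*rate*3*n)."""
        newick = "((A:2,B:2):2,(C:2,D:2):2);"
        rate, n_codons, reps = 0.01, 50, 100
        total_time = 12.0
        lam = total_time * rate * 3 * n_codons
        totals = []
        for seed in range(reps):
            cfg = SimConfig(seed=seed, tree_newick=newick, n_codons=n_codons,
                            background_rate=rate, hotspot_fraction=0.0,
                            omega_background=1.0)
            _, _, truth = simulate_orf(cfg)
            totals.append(sum(s["total"] for s in truth.site_changes))
        mean = np.mean(totals)
        se = np.sqrt(lam / reps)
        assert abs(mean - lam) < 3 * se

    def test_hotspots_accumulate_more_changes(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_taxa=8, n_codons=200,
                            hotspot_fraction=0.05, hotspot_rate_multiplier=10.0,
                            omega_background=1.0, omega_hotspot=1.0)
            _, _, truth = simulate_orf(cfg)
            per_site = np.array([s["total"] for s in truth.site_changes])
            hot = np.zeros(len(per_site), bool)
            hot[truth.hotspot_sites] = True
            if per_site[hot].mean() > per_site[~hot].mean():
                hits += 1
        assert hits >= 19

    def test_truth_counts_consistent_with_parent_child_differences(self):
        """Event counts equal summed parent-child differences on single-hit sites."""
        cfg = SimConfig(seed=4, n_taxa=8, n_codons=100)
        aln, tree, truth = simulate_orf(cfg)
        n = cfg.n_codons
        diff_counts = np.zeros(n, dtype=int)
        for node in tree.preorder_nodes:
            if node.parent_node is None:
                continue
            child = node.taxon.label if node.is_leaf() else node.label
            parent_node = node.parent_node
            parent = (parent_node.taxon.label if parent_node.is_leaf()
                      else parent_node.label)
            ps, cs = truth.ancestral[parent], truth.ancestral[child]
            for j in range(n):
                if ps[3 * j : 3 * j + 3] != cs[3 * j : 3 * j + 3]:
                    diff_counts[j] += sum(
                        a != b for a, b in zip(ps[3 * j : 3 * j + 3], cs[3 * j : 3 * j + 3])
                    )
        event_counts = np.array([s["total"] for s in truth.site_changes])
        multi_hit = set()
        for branch_events in truth.branch_site_events.values():
            for site, c in branch_events.items():
                if c > 1:
                    multi_hit.add(site)
        for j in range(n):
            if j in multi_hit:
                assert diff_counts[j] <= event_counts[j]
            else:
                assert diff_counts[j] == event_counts[j]


class TestSimulateUtr:
    def test_island_rate_zero_keeps_island_columns_invariant(self):
        cfg = SimConfig(seed=5, island_rate=0.0)
        aln, truth = simulate_utr(cfg)
        for a, b in truth.island_coords:
            for j in range(a, b):
                col = {s[j] for s in aln.sequences}
                assert len(col) == 1

    def test_motif_always_present_when_p_is_one(self):
        cfg = SimConfig(seed=6, motif_presence=(1.0, 1.0, 1.0, 1.0))
        aln, truth = simulate_utr(cfg)
        for t in aln.taxa:
            seq = aln.sequence(t)
            for m in truth.motif_loci:
                pos = m["position"]
                hits = scan_mbe(seq[max(0, pos - 1) : pos + len(m["instance"]) + 1])
                assert hits, f"motif at {pos} missing in {t}"

    def test_absent_taxa_have_no_hit_at_locus(self):
        cfg = SimConfig(seed=7)
        aln, truth = simulate_utr(cfg)
        for k, m in enumerate(truth.motif_loci):
            span = (m["position"], m["position"] + len(m["instance"]))
            for t in aln.taxa:
                hits = scan_mbe(aln.sequence(t))
                overlapping = [h for h in hits if h.start < span[1] and h.end > span[0]]
                assert bool(overlapping) == truth.motif_presence[t][k]

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=8)
        a1, _ = simulate_utr(cfg)
        a2, _ = simulate_utr(cfg)
        assert a1.sequences == a2.sequences


class TestSimulateReporter:
    def test_zero_noise_ratios_equal_group_means(self):
        cfg = SimConfig(seed=9, reporter_noise_sd=0.0)
        df = simulate_reporter(cfg)
        for line, mean in cfg.reporter_group_means.items():
            sub = df[df["line"] == line]
            np.testing.assert_allclose(sub["green"] / sub["orange"], mean)

    def test_shape(self):
        cfg = SimConfig(seed=10, reporter_replicates=4)
        df = simulate_reporter(cfg)
        assert len(df) == 4 * len(cfg.reporter_group_means)
        assert set(df.columns) == {"line", "replicate", "green", "orange"}

    def test_nonpositive_mean_rejected(self):
        cfg = SimConfig(seed=1, reporter_group_means={"a": 1.0, "b": -2.0})
        with pytest.raises(ValueError, match="positive"):
            simulate_reporter(cfg)
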