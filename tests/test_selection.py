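"""Codon counting, neutrality Z-test, per-site tests, distances, NJ."""

from itertools import permutations, product

import numpy as np
import pytest
from skbio import DistanceMatrix

from candevo._codons import ALL_CODONS
from candevo.seqdata import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    TimedTree,
    translate,
)
from candevo.selection import (
    bootstrap_support,
    codon_sites,
    neighbor_joining,
    neutrality_test,
    pairwise_counts,
    pairwise_differences,
    per_site_selection,
    saturation_fit,
    tree_splits,
)
from candevo.synthetic import SimConfig, simulate_orf, simulate_tree


def enumerate_sites(codon: str) -> float:
    """Oracle: synonymous site count by explicit neighbor enumeration."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            tot += 1
            syn += GENETIC_CODE[nb] == GENETIC_CODE[codon]
        if tot:
            s += syn / tot
    return s


class TestCodonSites:
    def test_phenylalanine_third_position(self):
        s, n = codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(3 - 1 / 3)

    def test_methionine_has_no_synonymous_sites(self):
        assert codon_sites("ATG")[0] == 0.0

    def test_fourfold_third_position_contributes_one(self):
        assert codon_sites("GGG")[0] == pytest.approx(1.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")

    def test_sites_sum_to_three_and_match_enumeration(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert s == pytest.approx(enumerate_sites(codon))


def pathway_oracle(c1: str, c2: str):
    """Oracle: average (syn, nonsyn) steps over stop-free pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (np.mean([r[0] for r in results]), np.mean([r[1] for r in results]))


class TestPairwiseCounts:
    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [("TTT", "TTC", 1.0, 0.0), ("TTT", "CTC", 1.0, 1.0), ("ATG", "ATG", 0.0, 0.0)],
    )
    def test_hand_enumerated_cases(self, a, b, sd, nd):
        pc = pairwise_counts(a, b)
        assert pc.Sd == pytest.approx(sd)
        assert pc.Nd == pytest.approx(nd)

    def test_symmetric_and_total_steps_preserved(self):
        rng = np.random.default_rng(3)
        codons = rng.choice(SENSE_CODONS, size=60)
        for a, b in zip(codons[:30], codons[30:]):
            f, r = pairwise_counts(a, b), pairwise_counts(b, a)
            assert f.Sd == pytest.approx(r.Sd) and f.Nd == pytest.approx(r.Nd)
            want = pathway_oracle(a, b)
            if want is not None:
                assert f.Sd == pytest.approx(want[0])
                assert f.Nd == pytest.approx(want[1])

    def test_ambiguous_codons_skipped_pairwise(self):
        pc = pairwise_counts("TTTNNNATG", "TTCAAAATG")
        assert pc.n_codons == 2
        assert pc.Sd == pytest.approx(1.0)

    def test_no_comparable_codons_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_counts("NNN", "AAA")


class TestNeutralityTest:
    def test_identical_sequences_degenerate(self):
        aln = CodonAlignment(("a", "b"), ("ATGGCT", "ATGGCT"))
        res = neutrality_test(aln, B=100, seed=0)
        assert res.degenerate

    def test_seed_reproducible_and_taxon_order_invariant(self):
        cfg = SimConfig(seed=21, n_taxa=6, n_codons=80)
        aln, _, _ = simulate_orf(cfg)
        r1 = neutrality_test(aln, B=150, seed=5)
        r2 = neutrality_test(aln, B=150, seed=5)
        assert r1.z == r2.z
        rev = CodonAlignment(tuple(reversed(aln.taxa)), tuple(reversed(aln.sequences)))
        r3 = neutrality_test(rev, B=150, seed=5)
        assert r3.mean_dN == pytest.approx(r1.mean_dN)
        assert r3.mean_dS == pytest.approx(r1.mean_dS)

    def test_purifying_selection_gives_negative_z(self):
        neg = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_taxa=8, n_codons=200,
                            hotspot_fraction=0.0, omega_background=0.05)
            aln, _, _ = simulate_orf(cfg)
            neg += neutrality_test(aln, B=150, seed=seed).z < 0
        assert neg >= 19


class TestPerSiteSelection:
    def test_invariant_site(self, quartet_tree):
        aln = CodonAlignment(tuple("ABCD"), ("ATG",) * 4)
        (res,) = per_site_selection(aln, quartet_tree)
        assert res.cs == res.cn == 0
        assert res.p_positive == 1.0 and res.p_negative == 1.0

    def test_forced_synonymous_change(self, quartet_tree):
        aln = CodonAlignment(tuple("ABCD"), ("TTT", "TTT", "TTT", "TTC"))
        (res,) = per_site_selection(aln, quartet_tree)
        assert res.cs == pytest.approx(1.0)
        assert res.cn == pytest.approx(0.0)

    def test_binomial_tail_value(self):
        from candevo.selection import _binom_upper_tail

        assert _binom_upper_tail(3, 3, 0.75) == pytest.approx(0.75**3)
        assert _binom_upper_tail(0, 5, 0.3) == 1.0

    def test_unresolved_site_skipped(self, quartet_tree):
        aln = CodonAlignment(tuple("ABCD"), ("NNN", "NNN", "NNN", "TTC"))
        (res,) = per_site_selection(aln, quartet_tree)
        assert res.skipped

    def test_total_changes_at_least_protein_census(self):
        from candevo.ancestry import census

        cfg = SimConfig(seed=17, n_taxa=8, n_codons=120, omega_background=0.3)
        aln, tree, _ = simulate_orf(cfg)
        sites = per_site_selection(aln, tree)
        total_nonsyn = sum(s.cn for s in sites)
        cen = census(translate(aln), tree)
        assert total_nonsyn >= cen.T - 1e-9


class TestDistances:
    def test_identical_and_single_difference(self):
        aln = CodonAlignment(("a", "b"), ("ATG", "ATA"))
        dm = pairwise_differences(aln, "nt")
        assert dm["a", "b"] == 1.0

    def test_matches_bruteforce_counts(self):
        cfg = SimConfig(seed=23, n_taxa=6, n_codons=50)
        aln, _, _ = simulate_orf(cfg)
        dm = pairwise_differences(aln, "nt")
        for i, a in enumerate(aln.taxa):
            for b in aln.taxa[i + 1 :]:
                sa, sb = aln.sequence(a), aln.sequence(b)
                want = sum(x != y for x, y in zip(sa, sb))
                assert dm[a, b] == want


class TestSaturation:
    def test_collinear_points_give_r2_one(self):
        tree = TimedTree.from_newick("((A:1,B:1):1,(C:2,(D:1,E:1):1):0);")
        ids = list("ABCDE")
        d = np.zeros((5, 5))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    t = tree.t_mrca(a, b)
                    d[i, j] = d[j, i] = 2.0 * t
        fit = saturation_fit(DistanceMatrix(d, ids=ids), tree)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_too_few_pairs_rejected(self):
        tree = TimedTree.from_newick("((A:1,B:1):1,C:2);")
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float), ids=list("ABC"))
        with pytest.raises(ValueError, match="3 pairs"):
            saturation_fit(d, tree, [("A", "B"), ("A", "C")])


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovers_topology(self):
        # additive distances on ((A,B),(C,D)); check against all 3 topologies
        d = np.array(
            [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 3], [8, 7, 3, 0]], float
        )
        t = neighbor_joining(DistanceMatrix(d, ids=list("ABCD")))
        splits = tree_splits(t, set("ABCD"))
        assert splits == {frozenset("AB")}
        assert frozenset("AC") not in splits and frozenset("AD") not in splits

    def test_three_taxa_closed_form_branch_lengths(self):
        d = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("XYZ"))
        t = neighbor_joining(d)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["X"] == pytest.approx(1.0)
        assert lengths["Y"] == pytest.approx(1.0)
        assert lengths["Z"] == pytest.approx(3.0)

    def test_focal_split_support_on_long_branches(self):
        cfg = SimConfig(seed=29, n_codons=120, omega_background=0.5,
                        tree_newick="((A:5,B:5):30,(C:5,D:5):30);")
        aln, _, _ = simulate_orf(cfg)
        _, support = bootstrap_support(aln, B=100, seed=3)
        key = frozenset("AB") if frozenset("AB") in support else frozenset("CD")
        assert support[key] >= 95.0
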