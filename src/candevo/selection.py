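"""Codon-based selection statistics, distances, saturation fits, NJ trees.

The counting approach follows the classical synonymous/nonsynonymous
bookkeeping: every sense codon contributes s synonymous and 3 - s
nonsynonymous sites (fractions of viable single-step neighbors), and codon
pairs are compared by averaging synonymous/nonsynonymous steps over all
orderings of the minimal mutational pathway, excluding pathways through stop
codons.  From these, pairwise dN and dS, a bootstrap Z-test of strict
neutrality (dN = dS), and a per-codon exact binomial test of selection using
parsimony-reconstructed ancestral codons.

Distances here are deliberately uncorrected difference counts: the point of
the saturation regressions is to expose multiple hits as a loss of linearity
between raw differences and divergence time, which a correction would mask.
Neighbor-joining and bootstrap support operate on those same raw distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from ._codons import (
    CODON_INDEX,
    IS_SENSE,
    N_SITES,
    ND_TABLE,
    S_SITES,
    SD_TABLE,
    encode_codons,
    synonymous_sites,
)
from .seqdata import CodonAlignment, ProteinAlignment, TimedTree, STOP_CODONS

__all__ = [
    "PairwiseCodonCounts",
    "NeutralityResult",
    "SiteSelection",
    "SaturationFit",
    "codon_sites",
    "pairwise_counts",
    "neutrality_test",
    "per_site_selection",
    "pairwise_differences",
    "saturation_fit",
    "neighbor_joining",
    "bootstrap_support",
]


def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of a sense codon.

    s sums, over the three positions, the fraction of viable (non-stop)
    single-nucleotide neighbors encoding the same amino acid; n = 3 - s.
    """
    s = synonymous_sites(codon.upper())
    return s, 3.0 - s


@dataclass(frozen=True)
class PairwiseCodonCounts:
    """Nei-Gojobori-style counts for one sequence pair."""

    S: float  # synonymous sites, averaged over the pair
    N: float  # nonsynonymous sites
    Sd: float  # pathway-averaged synonymous differences
    Nd: float  # pathway-averaged nonsynonymous differences
    n_codons: int  # codons compared (both resolved sense codons)

    @property
    def dS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def dN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0


def _comparable(idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    ok_a = (idx_a >= 0) & IS_SENSE[np.clip(idx_a, 0, None)]
    ok_b = (idx_b >= 0) & IS_SENSE[np.clip(idx_b, 0, None)]
    return ok_a & ok_b


def pairwise_counts(seq_a: str, seq_b: str) -> PairwiseCodonCounts:
    """Codon-counting comparison of two equal-length in-frame sequences.

    Codons containing gaps, Ns, or stops in either sequence are skipped
    pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = encode_codons(seq_a.upper()), encode_codons(seq_b.upper())
    comp = _comparable(a, b)
    if not np.any(comp):
        raise ValueError("no comparable codons between the two sequences")
    ai, bi = a[comp], b[comp]
    S = float(np.sum((S_SITES[ai] + S_SITES[bi]) / 2.0))
    N = float(np.sum((N_SITES[ai] + N_SITES[bi]) / 2.0))
    Sd = float(np.sum(SD_TABLE[ai, bi]))
    Nd = float(np.sum(ND_TABLE[ai, bi]))
    return PairwiseCodonCounts(S, N, Sd, Nd, int(np.sum(comp)))


# ---------------------------------------------------------------------------
# Bootstrap Z-test of strict neutrality


@dataclass
class NeutralityResult:
    """Codon-based test of strict neutrality (dN = dS) over all pairs.

    The statistic is Z = (mean dN - mean dS) / SE, with the SE estimated by
    bootstrap over codon columns; P-values come from the standard normal.
    """

    mean_dN: float
    mean_dS: float
    z: float
    se: float
    p_two_tailed: float
    p_one_tailed: float
    B: int
    seed: int | None
    degenerate: bool = False


def _pair_arrays(aln: CodonAlignment):
    """Per-pair, per-codon component arrays for vectorized resampling."""
    enc = [encode_codons(s) for s in aln.sequences]
    pairs = list(combinations(range(len(aln.taxa)), 2))
    n_c = aln.length_codons
    sd = np.zeros((len(pairs), n_c))
    nd = np.zeros((len(pairs), n_c))
    ss = np.zeros((len(pairs), n_c))
    nn = np.zeros((len(pairs), n_c))
    for p, (i, j) in enumerate(pairs):
        a, b = enc[i], enc[j]
        comp = _comparable(a, b)
        ai, bi = a[comp], b[comp]
        sd[p, comp] = SD_TABLE[ai, bi]
        nd[p, comp] = ND_TABLE[ai, bi]
        ss[p, comp] = (S_SITES[ai] + S_SITES[bi]) / 2.0
        nn[p, comp] = (N_SITES[ai] + N_SITES[bi]) / 2.0
    return sd, nd, ss, nn


def _mean_dn_ds(sd, nd, ss, nn, cols) -> tuple[float, float]:
    S = ss[:, cols].sum(axis=1)
    N = nn[:, cols].sum(axis=1)
    Sd = sd[:, cols].sum(axis=1)
    Nd = nd[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dS = np.where(S > 0, Sd / S, np.nan)
        dN = np.where(N > 0, Nd / N, np.nan)
    return float(np.nanmean(dN)), float(np.nanmean(dS))


def neutrality_test(
    aln: CodonAlignment, B: int = 1000, seed: int | None = None
) -> NeutralityResult:
    """Bootstrap Z-test of dN = dS averaged over all sequence pairs.

    Codon columns are resampled with replacement B times to estimate the
    standard error of (mean dN - mean dS).  An alignment with no
    synonymous or nonsynonymous differences at all returns a degenerate
    flagged result with no Z.
    """
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 sequences")
    if B < 100:
        raise ValueError("B must be at least 100")
    sd, nd, ss, nn = _pair_arrays(aln)
    n_c = aln.length_codons
    all_cols = np.arange(n_c)
    mean_dN, mean_dS = _mean_dn_ds(sd, nd, ss, nn, all_cols)
    if sd.sum() == 0 and nd.sum() == 0:
        return NeutralityResult(mean_dN, mean_dS, float("nan"), 0.0, 1.0, 1.0, B, seed, True)
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        cols = rng.integers(n_c, size=n_c)
        dn, ds = _mean_dn_ds(sd, nd, ss, nn, cols)
        reps[b] = dn - ds
    se = float(np.std(reps, ddof=1))
    diff = mean_dN - mean_dS
    if se == 0:
        return NeutralityResult(mean_dN, mean_dS, float("nan"), 0.0, 1.0, 1.0, B, seed, True)
    z = diff / se
    p_two = float(2.0 * stats.norm.sf(abs(z)))
    p_one = float(stats.norm.sf(abs(z)))
    return NeutralityResult(mean_dN, mean_dS, z, se, p_two, p_one, B, seed)


# ---------------------------------------------------------------------------
# Per-site (codon-by-codon) selection test


@dataclass(frozen=True)
class SiteSelection:
    """Counting-based selection test at one codon site.

    cs / cn are synonymous / nonsynonymous changes inferred over the tree
    from parsimony ancestral codons (fractional where pathways are averaged);
    p_s the expected synonymous proportion from the site's codon composition.
    """

    site: int
    cs: float
    cn: float
    p_s: float
    p_positive: float  # excess nonsynonymous
    p_negative: float  # excess synonymous
    skipped: bool = False


def _binom_upper_tail(k: float, n: float, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), extended to real k via betainc."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(special.betainc(k, n - k + 1.0, p))


def per_site_selection(aln: CodonAlignment, tree: TimedTree) -> list[SiteSelection]:
    """Per-codon synonymous/nonsynonymous change counts and binomial tests.

    Ancestral codons are reconstructed by Fitch parsimony over codon states
    (ties broken lexicographically, parent state preferred); each branch's
    codon pair contributes pathway-averaged syn/nonsyn steps.  For each site
    the exact binomial upper-tail probabilities of the observed or more
    biased nonsynonymous (p_positive) and synonymous (p_negative) counts are
    reported, with the expected synonymous proportion p_s taken from the mean
    synonymous site fraction of the codons observed at the site.
    """
    missing = set(aln.taxa) - set(tree.leaf_labels)
    if missing:
        raise ValueError(f"alignment taxa absent from tree: {sorted(missing)}")
    postorder = tree.postorder_nodes
    preorder = tree.preorder_nodes
    taxon_of = {t: i for i, t in enumerate(aln.taxa)}
    results: list[SiteSelection] = []
    for site in range(aln.length_codons):
        column = aln.codon_column(site)
        leaf_codon: dict = {}
        resolved = []
        for node in postorder:
            if not node.is_leaf():
                continue
            i = taxon_of.get(node.taxon.label)
            if i is None:
                continue
            codon = column[i]
            if codon in CODON_INDEX and codon not in STOP_CODONS:
                leaf_codon[node] = codon
                resolved.append(codon)
        if len(resolved) < 2:
            results.append(SiteSelection(site, 0.0, 0.0, float("nan"), 1.0, 1.0, skipped=True))
            continue
        # bottom-up Fitch over codon states
        sets: dict = {}
        for node in postorder:
            if node.is_leaf():
                c = leaf_codon.get(node)
                sets[node] = None if c is None else frozenset((c,))
                continue
            child_sets = [sets[c] for c in node.child_nodes() if sets[c] is not None]
            if not child_sets:
                sets[node] = None
                continue
            acc = child_sets[0]
            for cs_ in child_sets[1:]:
                inter = acc & cs_
                acc = inter if inter else acc | cs_
            sets[node] = acc
        # top-down assignment
        assigned: dict = {}
        for node in preorder:
            if sets.get(node) is None:
                assigned[node] = None
                continue
            parent = node.parent_node
            pstate = assigned.get(parent) if parent is not None else None
            if pstate is not None and pstate in sets[node]:
                assigned[node] = pstate
            else:
                assigned[node] = min(sets[node])
        cs = cn = 0.0
        for node in preorder:
            parent = node.parent_node
            if parent is None:
                continue
            a, b = assigned.get(parent), assigned.get(node)
            if a is None or b is None or a == b:
                continue
            i, j = CODON_INDEX[a], CODON_INDEX[b]
            cs += float(SD_TABLE[i, j])
            cn += float(ND_TABLE[i, j])
        p_s = float(np.mean([S_SITES[CODON_INDEX[c]] / 3.0 for c in resolved]))
        n_tot = cs + cn
        p_pos = _binom_upper_tail(cn, n_tot, 1.0 - p_s)
        p_neg = _binom_upper_tail(cs, n_tot, p_s)
        results.append(SiteSelection(site, cs, cn, p_s, p_pos, p_neg))
    return results


# ---------------------------------------------------------------------------
# Raw pairwise differences, saturation regression


def _resolved_mask(seqs: list[str], level: str) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    if level == "nt":
        return np.isin(arr, list("ACGT")), arr
    return ~np.isin(arr, list("X-?")), arr


def pairwise_differences(aln, level: str = "nt") -> DistanceMatrix:
    """Raw counts of differing resolved positions per pair (no correction).

    *aln* is a :class:`CodonAlignment`/:class:`UTRAlignment` for ``level="nt"``
    or a :class:`ProteinAlignment` for ``level="aa"``.  Positions where either
    sequence is unresolved are skipped for that pair.
    """
    if level not in ("nt", "aa"):
        raise ValueError("level must be 'nt' or 'aa'")
    ok, arr = _resolved_mask(list(aln.sequences), level)
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = ok[i] & ok[j]
        d[i, j] = d[j, i] = float(np.sum((arr[i] != arr[j]) & both))
    return DistanceMatrix(d, ids=list(aln.taxa))


@dataclass
class SaturationFit:
    """OLS fit of pairwise difference counts on t_mrca."""

    pairs: list[tuple[str, str]]
    t_mrca: np.ndarray
    differences: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def saturation_fit(
    dm: DistanceMatrix,
    tree: TimedTree,
    pair_filter: Callable[[str, str], bool] | Sequence[tuple[str, str]] | None = None,
) -> SaturationFit:
    """Regress pairwise difference counts against divergence time.

    ``pair_filter`` restricts the pairs used, either a predicate on the two
    taxon labels or an explicit pair list (e.g. only between-clade pairs).
    A weak fit (low R²) at deep times is the signature of substitutional
    saturation: repeated hits at the same positions erode the linearity of
    raw differences in time.
    """
    ids = list(dm.ids)
    if pair_filter is None:
        pairs = list(combinations(ids, 2))
    elif callable(pair_filter):
        pairs = [(a, b) for a, b in combinations(ids, 2) if pair_filter(a, b)]
    else:
        pairs = [tuple(p) for p in pair_filter]
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a saturation fit")
    t = np.array([tree.t_mrca(a, b) for a, b in pairs])
    d = np.array([dm[a, b] for a, b in pairs])
    if np.all(t == t[0]):
        raise ValueError("all selected pairs share one t_mrca; regression undefined")
    fit = stats.linregress(t, d)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    return SaturationFit(pairs, t, d, float(fit.slope), float(fit.intercept), r2)


# ---------------------------------------------------------------------------
# Neighbor-joining with bootstrap support


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining tree from a symmetric distance matrix."""
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 taxa")
    return nj(dm)


def tree_splits(tree: TreeNode, taxa: set[str]) -> set[frozenset]:
    """Non-trivial bipartitions of *taxa* induced by the tree's internal edges.

    Each split is canonicalized as the lexicographically smaller of the two
    sides among those of minimal size, so rooted and unrooted renderings of
    the same topology yield identical split sets.
    """
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = frozenset(taxa - side)
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (len(side) == len(other) and sorted(side) < sorted(other)):
            splits.add(side)
        else:
            splits.add(other)
    return splits


def bootstrap_support(
    aln, B: int = 1000, seed: int | None = None, level: str = "nt"
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree from raw differences plus per-split bootstrap support (%).

    Alignment columns are resampled with replacement B times; support for
    each split of the full-data tree is the percentage of replicate trees
    containing it.  Internal nodes of the returned tree are labeled with
    their support.
    """
    taxa = set(aln.taxa)
    base = neighbor_joining(pairwise_differences(aln, level=level))
    base_splits = tree_splits(base, taxa)
    counts = {s: 0 for s in base_splits}
    rng = np.random.default_rng(seed)
    ok, arr = _resolved_mask(list(aln.sequences), level)
    n = len(aln.taxa)
    L = arr.shape[1]
    for _ in range(B):
        cols = rng.integers(L, size=L)
        a_s, ok_s = arr[:, cols], ok[:, cols]
        d = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            both = ok_s[i] & ok_s[j]
            d[i, j] = d[j, i] = float(np.sum((a_s[i] != a_s[j]) & both))
        rep = nj(DistanceMatrix(d, ids=list(aln.taxa)))
        rep_splits = tree_splits(rep, taxa)
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / B for s, c in counts.items()}
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = frozenset(taxa - side)
        key = side if side in support else other
        if key in support:
            node.name = f"{support[key]:.0f}"
    return base, support
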