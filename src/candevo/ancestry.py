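"""Parsimony ancestral reconstruction and the substitution census.

For each residue column of a protein alignment, the Fitch parsimony length —
the minimum number of state changes needed to explain the leaf states on the
given rooted tree — estimates how many substitutions occurred at that site.
Summing over sites yields the substitution census: V variable sites, M
recurrent sites (two or more inferred changes, the homoplasy signal), T total
inferred changes, and the mean number of changes per variable site.

Missing states ('X', '-', '?') are excluded from Fitch state sets rather than
treated as an extra character, so incomplete sequencing cannot inflate the
census.  Per-exon enrichment asks whether the replacements concentrate in one
exon more than expected from its length, via an upper-tail cumulative
binomial probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .seqdata import ExonMap, ProteinAlignment, TimedTree

__all__ = [
    "MISSING_STATES",
    "SubstitutionCensus",
    "ExonEnrichment",
    "ConvergentSite",
    "fitch_site_count",
    "census",
    "exon_binomial",
    "convergence_report",
]

MISSING_STATES = frozenset({"X", "-", "?"})


def _fitch(states: Mapping[str, str], tree: TimedTree) -> tuple[int, int]:
    """(parsimony length, number of non-missing leaves) for one column."""
    n_resolved = 0
    changes = 0
    sets: dict = {}
    for node in tree.postorder_nodes:
        if node.is_leaf():
            s = states.get(node.taxon.label)
            if s is None or s in MISSING_STATES:
                sets[node] = None
            else:
                sets[node] = frozenset((s,))
                n_resolved += 1
            continue
        child_sets = [sets[c] for c in node.child_nodes() if sets[c] is not None]
        if not child_sets:
            sets[node] = None
            continue
        acc = child_sets[0]
        for cs in child_sets[1:]:  # pairwise fold; exact Fitch on binary trees
            inter = acc & cs
            if inter:
                acc = inter
            else:
                acc = acc | cs
                changes += 1
        sets[node] = acc
    return changes, n_resolved


def fitch_site_count(states: Mapping[str, str], tree: TimedTree) -> int:
    """Fitch parsimony length of one character column on a rooted tree.

    *states* maps leaf labels to single-character states; missing markers
    ('X', '-', '?') and absent leaves contribute nothing.  With fewer than
    two resolved leaves the count is 0 (a warning is issued).
    """
    changes, n_resolved = _fitch(states, tree)
    if n_resolved < 2:
        warnings.warn("fewer than 2 non-missing leaves; parsimony length is 0")
        return 0
    return changes


@dataclass
class SubstitutionCensus:
    """Per-site inferred change counts and their summary.

    T = sum of per-site counts, V = number of variable sites (count >= 1),
    M = number of recurrent sites (count >= 2), mean_per_variable = T/V.
    """

    site_counts: np.ndarray
    degenerate: bool = False

    @property
    def T(self) -> int:
        return int(np.sum(self.site_counts))

    @property
    def V(self) -> int:
        return int(np.sum(self.site_counts >= 1))

    @property
    def M(self) -> int:
        return int(np.sum(self.site_counts >= 2))

    @property
    def mean_per_variable(self) -> float:
        if self.V == 0:
            return 0.0
        return self.T / self.V

    @property
    def variable_sites(self) -> np.ndarray:
        return np.nonzero(self.site_counts >= 1)[0]

    @property
    def recurrent_sites(self) -> np.ndarray:
        return np.nonzero(self.site_counts >= 2)[0]

    @classmethod
    def from_site_counts(cls, counts: Sequence[int]) -> "SubstitutionCensus":
        counts = np.asarray(counts, dtype=np.int64)
        return cls(counts, degenerate=bool(np.all(counts == 0)))


def census(protein_aln: ProteinAlignment, tree: TimedTree) -> SubstitutionCensus:
    """Fitch parsimony substitution census over all residue columns."""
    missing = set(protein_aln.taxa) - set(tree.leaf_labels)
    if missing:
        raise ValueError(f"alignment taxa absent from tree: {sorted(missing)}")
    counts = np.zeros(protein_aln.length_aa, dtype=np.int64)
    taxa = protein_aln.taxa
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(protein_aln.length_aa):
            states = {t: s[j] for t, s in zip(taxa, protein_aln.sequences)}
            counts[j], _ = _fitch(states, tree)
    return SubstitutionCensus(counts, degenerate=bool(np.all(counts == 0)))


# ---------------------------------------------------------------------------
# Per-exon binomial enrichment


@dataclass(frozen=True)
class ExonEnrichment:
    """Upper-tail binomial probability of an exon's replacement count.

    p = L_e / L where L is the total residue length covered by the exon map;
    P_cum = P(X >= r_e) for X ~ Binomial(R, p).
    """

    exon: str
    length: int
    observed: int
    total: int
    p: float
    p_cum: float
    degenerate: bool = False


def exon_binomial(site_counts: Sequence[int], exon_map: ExonMap) -> list[ExonEnrichment]:
    """Cumulative binomial enrichment of replacements per exon.

    *site_counts* gives the inferred replacement count per residue (e.g.
    ``SubstitutionCensus.site_counts``).  Residues not covered by any exon
    are excluded from both the total R and the length L.
    """
    counts = np.asarray(site_counts, dtype=np.int64)
    if exon_map.exons and exon_map.exons[-1].end > len(counts):
        raise ValueError("exon map extends beyond the protein")
    L = exon_map.covered_length
    per_exon = [int(np.sum(counts[e.start : e.end])) for e in exon_map.exons]
    R = int(sum(per_exon))
    out = []
    for e, r_e in zip(exon_map.exons, per_exon):
        p = e.length / L
        if R == 0:
            out.append(ExonEnrichment(e.name, e.length, 0, 0, p, 1.0, degenerate=True))
            continue
        # upper tail P(X >= r_e); survival function at r_e - 1
        p_cum = float(stats.binom.sf(r_e - 1, R, p)) if r_e > 0 else 1.0
        out.append(ExonEnrichment(e.name, e.length, r_e, R, p, p_cum))
    return out


# ---------------------------------------------------------------------------
# Convergence report


@dataclass(frozen=True)
class ConvergentSite:
    """A recurrent site where carriers of a shared state are not a clade."""

    site: int
    state: str
    carriers: tuple[str, ...]


def _is_clade(tree: TimedTree, carriers: set[str], resolved: set[str]) -> bool:
    """True when *carriers* are monophyletic among leaves with resolved data."""
    taxa = [tree._leaf_by_label[t].taxon for t in carriers]
    mrca = tree.tree.mrca(taxa=taxa)
    below = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return (below & resolved) == carriers


def convergence_report(
    protein_aln: ProteinAlignment, tree: TimedTree, site_census: SubstitutionCensus | None = None
) -> list[ConvergentSite]:
    """Flag shared derived states whose carriers are not monophyletic.

    For each recurrent site (>= 2 inferred changes), leaves are grouped by
    residue state; a state carried by two or more leaves that do not form a
    clade (among leaves with resolved data at the site) implies independent
    acquisition — convergence or reversal.  A state unambiguously assigned to
    the root by Fitch is ancestral and not reported.
    """
    if site_census is None:
        site_census = census(protein_aln, tree)
    out: list[ConvergentSite] = []
    for j in site_census.recurrent_sites:
        states = {t: s[j] for t, s in zip(protein_aln.taxa, protein_aln.sequences)}
        resolved = {t for t, s in states.items() if s not in MISSING_STATES}
        by_state: dict[str, set[str]] = {}
        for t in resolved:
            by_state.setdefault(states[t], set()).add(t)
        root_set = _fitch_root_set(states, tree)
        for state, carriers in sorted(by_state.items()):
            if len(carriers) < 2 or carriers == resolved:
                continue
            if root_set is not None and len(root_set) == 1 and state in root_set:
                continue  # unambiguously ancestral
            if not _is_clade(tree, carriers, resolved):
                out.append(ConvergentSite(int(j), state, tuple(sorted(carriers))))
    return out


def _fitch_root_set(states: Mapping[str, str], tree: TimedTree):
    sets: dict = {}
    for node in tree.postorder_nodes:
        if node.is_leaf():
            s = states.get(node.taxon.label)
            sets[node] = None if s is None or s in MISSING_STATES else frozenset((s,))
            continue
        child_sets = [sets[c] for c in node.child_nodes() if sets[c] is not None]
        if not child_sets:
            sets[node] = None
            continue
        acc = child_sets[0]
        for cs in child_sets[1:]:
            inter = acc & cs
            acc = inter if inter else acc | cs
        sets[node] = acc
    return sets[tree.tree.seed_node]
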