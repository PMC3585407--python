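import numpy as np
import pytest

from candevo.seqdata import CodonAlignment, TimedTree
from candevo.synthetic import SimConfig, simulate_orf, simulate_tree, simulate_utr


@pytest.fixture
def quartet_tree() -> TimedTree:
    return TimedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_codon_aln() -> CodonAlignment:
    return CodonAlignment(
        ("A", "B", "C", "D"),
        ("ATGGCTTTT", "ATGGCTTTC", "ATGTCTTTT", "ATGTCTTTC"),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed 0)."""
    cfg = SimConfig(seed=0)
    tree = simulate_tree(cfg)
    orf, _, orf_truth = simulate_orf(cfg, tree)
    utr, utr_truth = simulate_utr(cfg, tree)
    return cfg, tree, orf, orf_truth, utr, utr_truth


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# Independent oracles shared across test modules


def sankoff_length(node, states) -> int:
    """Unit-cost minimal change count by dynamic programming (oracle).

    *node* is a nested tuple of leaf names; leaves with missing states get a
    free cost vector, which is equivalent to pruning them.
    """
    import math

    alphabet = sorted({s for s in states.values() if s not in "X-?"})
    if not alphabet:
        return 0

    def costs(n):
        if isinstance(n, str):
            s = states.get(n)
            if s is None or s in "X-?":
                return {a: 0 for a in alphabet}
            return {a: (0 if a == s else math.inf) for a in alphabet}
        left, right = costs(n[0]), costs(n[1])
        return {
            a: min(left[b] + (a != b) for b in alphabet)
            + min(right[b] + (a != b) for b in alphabet)
            for a in alphabet
        }

    return int(min(costs(node).values()))


def tuple_to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return f"({tuple_to_newick(node[0])},{tuple_to_newick(node[1])})"


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if not isinstance(tree, str):
        left, right = tree
        for nl in _insert_everywhere(left, leaf):
            yield (nl, right)
        for nr in _insert_everywhere(right, leaf):
            yield (left, nr)


def all_rooted_topologies(leaves: list[str]):
    """Every rooted binary topology on the given leaves ((2n-3)!! shapes)."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for prev in trees for t in _insert_everywhere(prev, leaf)]
    return trees


def brute_force_mbe(seq: str) -> set[tuple[int, int]]:
    """Oracle: every substring of length 5-7 matching purine T{n} AGT."""
    out = set()
    for n in (1, 2, 3):
        w = n + 4
        for i in range(len(seq) - w + 1):
            sub = seq[i : i + w]
            if sub[0] in "AG" and sub[1 : 1 + n] == "T" * n and sub[1 + n :] == "AGT":
                out.add((i, i + w))
    return out
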