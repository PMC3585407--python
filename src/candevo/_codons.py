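"""Precomputed codon tables for counting-method selection statistics.

Built once at import: per-codon synonymous/nonsynonymous site fractions and
pathway-averaged per-pair synonymous/nonsynonymous difference counts, with
mutational pathways passing through stop codons excluded (renormalized).
Single-nucleotide neighbors that are stop codons are excluded from the viable
mutation set everywhere, so s + n = 3 exactly for every sense codon.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .seqdata import GENETIC_CODE, SENSE_CODONS, STOP_CODONS

BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}
IS_SENSE = np.array([c not in STOP_CODONS for c in ALL_CODONS])


def neighbors(codon: str, position: int) -> list[str]:
    """The three single-nucleotide mutants of *codon* at *position*."""
    return [
        codon[:position] + b + codon[position + 1 :]
        for b in BASES
        if b != codon[position]
    ]


def viable_neighbors(codon: str, position: int) -> list[str]:
    """Single-nucleotide mutants at *position* that are not stop codons."""
    return [m for m in neighbors(codon, position) if m not in STOP_CODONS]


def synonymous_sites(codon: str) -> float:
    """Synonymous site count s for a sense codon.

    Per position, the fraction of viable (non-stop) single-step neighbors that
    encode the same amino acid; summed over the three positions.  The
    nonsynonymous site count is 3 - s by construction.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in CODON_INDEX:
        raise ValueError(f"ambiguous codon {codon}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        viable = viable_neighbors(codon, pos)
        if viable:
            s += sum(GENETIC_CODE[m] == aa for m in viable) / len(viable)
    return s


def _path_steps(c1: str, c2: str):
    """Pathway-averaged (syn, nonsyn) step counts between two sense codons.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are dropped and the remainder renormalized.  If every
    pathway passes through a stop (does not occur between sense codons in the
    standard code, but guarded), all pathways are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:  # pragma: no cover - unreachable with standard code
        for order in permutations(diff):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def _build_tables():
    n = len(ALL_CODONS)
    s_sites = np.full(n, np.nan)
    for c in SENSE_CODONS:
        s_sites[CODON_INDEX[c]] = synonymous_sites(c)
    sd = np.full((n, n), np.nan)
    nd = np.full((n, n), np.nan)
    for c1 in SENSE_CODONS:
        i = CODON_INDEX[c1]
        for c2 in SENSE_CODONS:
            j = CODON_INDEX[c2]
            if j < i:
                continue
            a, b = _path_steps(c1, c2)
            sd[i, j] = sd[j, i] = a
            nd[i, j] = nd[j, i] = b
    return s_sites, sd, nd


#: per-codon synonymous site fractions (NaN for stops), and pathway-averaged
#: per-pair synonymous / nonsynonymous step counts (NaN where either is a stop)
S_SITES, SD_TABLE, ND_TABLE = _build_tables()
N_SITES = np.where(np.isnan(S_SITES), np.nan, 3.0 - S_SITES)


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an in-frame sequence; -1 for unresolved codons."""
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        codon = seq[3 * j : 3 * j + 3]
        idx = CODON_INDEX.get(codon)
        if idx is not None:
            out[j] = idx
    return out
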