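"""UTR conservation profiling, conserved-island segmentation, motif scanning.

Phylogenetic shadowing: across a multi-species alignment of non-coding
sequence, regulatory elements show up as runs of columns with markedly
reduced divergence ("conserved islands") against a fast-evolving background.
Segmentation uses a two-state hidden Markov model over per-column binary
variant indicators.  The conserved-state emission probability theta_c (the
chance a conserved column is variant) is calibrated on open-reading-frame
columns — the most conserved sequence class available — and held fixed while
Baum-Welch refines the nonconserved emission theta_n and the transition
matrix on the UTR columns themselves.

Motif scanning covers degenerate patterns of the form prefix + run + suffix
over IUPAC codes; the built-in pattern is the Musashi binding element
R T{1-3} A G T (R = purine).  Scanning is sense-strand only: these are mRNA
elements.  Per-taxon hits are clustered into alignment-anchored loci by
span overlap, giving a presence/absence matrix and per-locus frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import UTRAlignment

__all__ = [
    "DivergenceProfile",
    "ConservedIsland",
    "ShadowHMM",
    "RunPattern",
    "MBE_PATTERN",
    "MotifHit",
    "MotifLocusMatrix",
    "column_divergence",
    "variant_indicator",
    "divergence_profile",
    "calibrate_hmm",
    "segment_islands",
    "scan_pattern",
    "scan_mbe",
    "motif_matrix",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# Column statistics


def column_divergence(aln: UTRAlignment) -> np.ndarray:
    """Per-column divergence: 1 - modal-base frequency among resolved bases.

    Columns with no resolved base (gap/N only) are NaN.
    """
    L = aln.length_nt
    out = np.full(L, np.nan)
    seqs = aln.sequences
    for j in range(L):
        counts: dict[str, int] = {}
        for s in seqs:
            b = s[j]
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        if total:
            out[j] = 1.0 - max(counts.values()) / total
    return out


def variant_indicator(aln) -> np.ndarray:
    """Binary per-column indicator: >1 distinct resolved base among taxa.

    Gaps and Ns are ignored; columns with fewer than two resolved bases are 0.
    Accepts any alignment-like object with ``sequences``.
    """
    L = len(aln.sequences[0])
    out = np.zeros(L, dtype=np.int8)
    for j in range(L):
        seen = set()
        for s in aln.sequences:
            b = s[j]
            if b in "ACGT":
                seen.add(b)
                if len(seen) > 1:
                    out[j] = 1
                    break
    return out


@dataclass(frozen=True)
class DivergenceProfile:
    """Sliding-window mean column divergence (percent-variation plot)."""

    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray


def divergence_profile(utr: UTRAlignment, window: int, step: int = 1) -> DivergenceProfile:
    """Mean column divergence in sliding windows; gap-only columns excluded."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = utr.length_nt
    if window > L:
        raise ValueError(f"window {window} exceeds alignment length {L}")
    div = column_divergence(utr)
    starts = np.arange(0, L - window + 1, step)
    values = np.array([np.nanmean(div[s : s + window]) if np.any(~np.isnan(div[s : s + window])) else np.nan
                       for s in starts])
    return DivergenceProfile(window, step, starts, values)


# ---------------------------------------------------------------------------
# Two-state Bernoulli shadowing HMM

STATE_CONSERVED, STATE_NONCONSERVED = 0, 1


class CalibrationError(ValueError):
    """ORF calibration not informative (theta_c >= theta_n)."""


@dataclass
class ShadowHMM:
    """Two-state HMM over binary column variant indicators.

    ``theta_c`` / ``theta_n`` are the probabilities that a conserved /
    nonconserved column is variant; ``trans[i, j]`` the probability of moving
    from state i to state j between adjacent columns; ``lmin`` the minimum
    reported island length in nt.
    """

    theta_c: float
    theta_n: float
    trans: np.ndarray
    lmin: int = 50
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.theta_c < self.theta_n:
            raise CalibrationError(
                f"theta_c={self.theta_c:.4g} must be < theta_n={self.theta_n:.4g}"
            )
        if not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    def _log_emissions(self, x: np.ndarray) -> np.ndarray:
        th = np.array([self.theta_c, self.theta_n])
        return np.where(x[:, None] == 1, np.log(th), np.log1p(-th))

    def loglik(self, x: np.ndarray) -> float:
        """Forward-algorithm log-likelihood of a 0/1 column sequence."""
        loge = self._log_emissions(np.asarray(x))
        logt = np.log(self.trans)
        alpha = np.log(0.5) + loge[0]
        for t in range(1, len(loge)):
            alpha = loge[t] + _logsumexp2(alpha[:, None] + logt)
        return float(_logsumexp(alpha))

    def viterbi(self, x: np.ndarray) -> np.ndarray:
        """Most probable state path for a 0/1 column sequence."""
        x = np.asarray(x)
        loge = self._log_emissions(x)
        logt = np.log(self.trans)
        T = len(x)
        delta = np.log(0.5) + loge[0]
        back = np.zeros((T, 2), dtype=np.int8)
        for t in range(1, T):
            cand = delta[:, None] + logt
            back[t] = np.argmax(cand, axis=0)
            delta = loge[t] + np.max(cand, axis=0)
        path = np.zeros(T, dtype=np.int8)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = np.max(a)
    return m + np.log(np.sum(np.exp(a - m)))


def _logsumexp2(a: np.ndarray) -> np.ndarray:
    # column-wise logsumexp of a 2x2 array
    m = np.max(a, axis=0)
    return m + np.log(np.sum(np.exp(a - m[None, :]), axis=0))


def _pseudo_fraction(x: np.ndarray) -> float:
    x = np.asarray(x)
    return (float(np.sum(x)) + 1.0) / (len(x) + 2.0)


def calibrate_hmm(
    orf_columns: np.ndarray,
    utr_columns: np.ndarray,
    lmin: int = 50,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ShadowHMM:
    """Calibrate the shadowing HMM on ORF columns and refine on UTR columns.

    theta_c is the variant-column fraction of the open reading frame (with a
    1/(n+2) pseudocount) and stays fixed: coding sequence defines what
    "conserved" means for this alignment.  theta_n is initialized from the
    overall UTR variant fraction and refined together with the transition
    matrix by Baum-Welch (EM) on the UTR columns.  Raises
    :class:`CalibrationError` when the initialization gives theta_c >=
    theta_n, i.e. the UTR is no more variable than coding sequence.
    """
    orf_columns = np.asarray(orf_columns)
    utr_columns = np.asarray(utr_columns)
    if orf_columns.size == 0 or utr_columns.size == 0:
        raise ValueError("calibration requires non-empty ORF and UTR column sets")
    theta_c = _pseudo_fraction(orf_columns)
    theta_n = _pseudo_fraction(utr_columns)
    stay = 1.0 - 1.0 / max(2 * lmin, 2)
    hmm = ShadowHMM(theta_c, theta_n, np.array([[stay, 1 - stay], [1 - stay, stay]]), lmin)

    x = utr_columns
    T = len(x)
    prev_ll = -np.inf
    for _ in range(max_iter):
        loge = hmm._log_emissions(x)
        logt = np.log(hmm.trans)
        # forward
        alpha = np.zeros((T, 2))
        alpha[0] = np.log(0.5) + loge[0]
        for t in range(1, T):
            alpha[t] = loge[t] + _logsumexp2(alpha[t - 1][:, None] + logt)
        ll = float(_logsumexp(alpha[-1]))
        hmm.loglik_trace.append(ll)
        # backward
        beta = np.zeros((T, 2))
        for t in range(T - 2, -1, -1):
            beta[t] = _logsumexp2((logt + (loge[t + 1] + beta[t + 1])[None, :]).T)
        gamma = alpha + beta
        gamma -= _np_logsumexp_rows(gamma)[:, None]
        g = np.exp(gamma)
        # transition expectations
        xi = np.zeros((2, 2))
        for t in range(T - 1):
            m = alpha[t][:, None] + logt + (loge[t + 1] + beta[t + 1])[None, :] - ll
            xi += np.exp(m)
        denom = g[:-1].sum(axis=0)
        trans = xi / denom[:, None]
        trans = trans / trans.sum(axis=1, keepdims=True)
        # theta_n update only; theta_c held fixed by design
        w = g[:, STATE_NONCONSERVED]
        theta_n_new = (float(np.sum(w * x)) + 1.0) / (float(np.sum(w)) + 2.0)
        theta_n_new = max(theta_n_new, hmm.theta_c + 1e-6)
        hmm = ShadowHMM(hmm.theta_c, theta_n_new, trans, lmin, hmm.loglik_trace)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return hmm


def _np_logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = np.max(a, axis=1)
    return m + np.log(np.sum(np.exp(a - m[:, None]), axis=1))


@dataclass(frozen=True)
class ConservedIsland:
    """Maximal conserved-state run (0-based half-open alignment columns)."""

    start: int
    end: int
    mean_divergence: float
    offset_from_start_codon: int | None = None
    offset_from_stop_codon: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_islands(utr: UTRAlignment, hmm: ShadowHMM) -> list[ConservedIsland]:
    """Viterbi-decode the UTR and report conserved runs of length >= lmin.

    Island anchors are reported relative to the alignment's start/stop codon
    offsets when those are set: distance from the start-codon column to the
    island, and from the stop-codon column to the island, in alignment nt.
    """
    x = variant_indicator(utr)
    path = hmm.viterbi(x)
    div = column_divergence(utr)
    islands = []
    j = 0
    L = len(path)
    while j < L:
        if path[j] == STATE_CONSERVED:
            k = j
            while k < L and path[k] == STATE_CONSERVED:
                k += 1
            if k - j >= hmm.lmin:
                seg = div[j:k]
                mean_div = float(np.nanmean(seg)) if np.any(~np.isnan(seg)) else float("nan")
                off_start = None if utr.start_codon_offset is None else j - utr.start_codon_offset
                off_stop = None if utr.stop_codon_offset is None else j - utr.stop_codon_offset
                islands.append(ConservedIsland(j, k, mean_div, off_start, off_stop))
            j = k
        else:
            j += 1
    return islands


# ---------------------------------------------------------------------------
# Degenerate run-pattern motif scanning


@dataclass(frozen=True)
class RunPattern:
    """Degenerate motif of the form prefix + run_base{run_min..run_max} + suffix.

    Prefix and suffix are IUPAC strings.  At a shared start position the
    longest admissible run is preferred.
    """

    prefix: str
    run_base: str
    run_min: int
    run_max: int
    suffix: str
    name: str = "pattern"

    @property
    def min_length(self) -> int:
        return len(self.prefix) + self.run_min + len(self.suffix)

    @property
    def max_length(self) -> int:
        return len(self.prefix) + self.run_max + len(self.suffix)


#: Musashi binding element: purine, 1-3 T's, then AGT (DNA representation)
MBE_PATTERN = RunPattern("R", "T", 1, 3, "AGT", name="MBE")


@dataclass(frozen=True)
class MotifHit:
    taxon: str | None
    start: int
    end: int
    run_length: int


def _iupac_match(seq: str, i: int, pattern: str) -> bool:
    for k, p in enumerate(pattern):
        if seq[i + k] not in IUPAC[p]:
            return False
    return True


def scan_pattern(seq: str, pattern: RunPattern, allow_overlap: bool = True,
                 taxon: str | None = None) -> list[MotifHit]:
    """All occurrences of a run pattern on the sense strand.

    At each start the longest admissible run length is taken; with
    ``allow_overlap`` every start is examined, otherwise scanning resumes
    after each hit's end.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    L = len(seq)
    i = 0
    npre, nsuf = len(pattern.prefix), len(pattern.suffix)
    while i <= L - pattern.min_length:
        found = None
        for n in range(pattern.run_max, pattern.run_min - 1, -1):
            end = i + npre + n + nsuf
            if end > L:
                continue
            if not _iupac_match(seq, i, pattern.prefix):
                break
            run = seq[i + npre : i + npre + n]
            if run != pattern.run_base * n:
                continue
            if _iupac_match(seq, i + npre + n, pattern.suffix):
                found = MotifHit(taxon, i, end, n)
                break
        if found:
            hits.append(found)
            i = i + 1 if allow_overlap else found.end
        else:
            i += 1
    return hits


def scan_mbe(seq: str, allow_overlap: bool = True, taxon: str | None = None) -> list[MotifHit]:
    """Scan for Musashi binding elements (R T{1-3} A G T), sense strand."""
    return scan_pattern(seq, MBE_PATTERN, allow_overlap=allow_overlap, taxon=taxon)


# ---------------------------------------------------------------------------
# Cross-taxon motif locus matrix


@dataclass
class MotifLocusMatrix:
    """Alignment-anchored motif loci x taxa presence matrix.

    ``loci`` are merged alignment-column spans (0-based half-open);
    ``presence`` is a boolean DataFrame indexed by taxon with one column per
    locus; ``frequencies`` the per-locus fraction of taxa carrying a hit.
    """

    loci: list[tuple[int, int]]
    presence: pd.DataFrame

    @property
    def frequencies(self) -> np.ndarray:
        if self.presence.empty:
            return np.zeros(0)
        return self.presence.to_numpy().mean(axis=0)

    def per_taxon_counts(self) -> pd.Series:
        return self.presence.sum(axis=1)


def motif_matrix(
    utr: UTRAlignment,
    pattern: RunPattern = MBE_PATTERN,
    allow_overlap: bool = True,
    hits_by_taxon: dict[str, list[MotifHit]] | None = None,
) -> MotifLocusMatrix:
    """Scan every taxon, map hits to alignment columns, cluster into loci.

    Hits are computed on each taxon's ungapped sequence and mapped back to
    alignment columns; hit spans that overlap across taxa are merged into a
    single locus (single-linkage interval merging).  Pass ``hits_by_taxon``
    to supply hits computed elsewhere (e.g. including an ORF 3' tail); their
    coordinates must already be alignment columns.
    """
    spans_by_taxon: dict[str, list[tuple[int, int]]] = {}
    if hits_by_taxon is None:
        for t in utr.taxa:
            seq, cols = utr.ungapped(t)
            spans = []
            for h in scan_pattern(seq, pattern, allow_overlap=allow_overlap, taxon=t):
                spans.append((cols[h.start], cols[h.end - 1] + 1))
            spans_by_taxon[t] = spans
    else:
        unknown = set(hits_by_taxon) - set(utr.taxa)
        if unknown:
            raise ValueError(f"hits for taxa absent from alignment: {sorted(unknown)}")
        for t in utr.taxa:
            spans_by_taxon[t] = [(h.start, h.end) for h in hits_by_taxon.get(t, [])]

    all_spans = sorted(sp for spans in spans_by_taxon.values() for sp in spans)
    loci: list[tuple[int, int]] = []
    for a, b in all_spans:
        if loci and a < loci[-1][1]:
            loci[-1] = (loci[-1][0], max(loci[-1][1], b))
        else:
            loci.append((a, b))

    data = np.zeros((len(utr.taxa), len(loci)), dtype=bool)
    for ti, t in enumerate(utr.taxa):
        for a, b in spans_by_taxon[t]:
            for li, (la, lb) in enumerate(loci):
                if a < lb and b > la:
                    data[ti, li] = True
                    break
    presence = pd.DataFrame(
        data, index=list(utr.taxa), columns=[f"locus_{a}_{b}" for a, b in loci]
    )
    return MotifLocusMatrix(loci, presence)
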