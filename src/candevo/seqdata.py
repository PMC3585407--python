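"""Data model and I/O for alignments, timed trees, and exon annotations.

The package operates on three in-memory containers:

* :class:`CodonAlignment` — in-frame aligned coding sequences, the substrate
  for every open-reading-frame statistic (substitution census, selection
  tests, saturation regressions).
* :class:`UTRAlignment` — aligned non-coding sequence, optionally anchored to
  the position of the start/stop codon, the substrate for conservation
  profiling and motif scanning.
* :class:`TimedTree` — a rooted topology with node ages in millions of years,
  supplying time-to-most-recent-common-ancestor (t_mrca) lookups and the
  structure over which parsimony changes are counted.

All coordinates are 0-based, half-open: codon units for exon maps, alignment
nucleotide columns for UTR features.  FASTA is read/written through
biopython, Newick through dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "STOP_CODONS",
    "GENETIC_CODE",
    "CodonAlignment",
    "ProteinAlignment",
    "UTRAlignment",
    "TimedTree",
    "ExonRecord",
    "ExonMap",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_newick_timed",
    "read_exon_map",
    "write_exon_map",
    "translate",
]

ALPHABET = set("ACGTN-")

_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, stop codons map to '*'
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
GENETIC_CODE.update({c: "*" for c in _table.stop_codons})
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))


class AlignmentError(ValueError):
    """Raised when sequences violate an alignment invariant."""


def _check_equal_lengths(taxa: Sequence[str], seqs: Sequence[str]) -> int:
    if not taxa:
        raise AlignmentError("empty alignment")
    if len(taxa) != len(set(taxa)):
        raise AlignmentError("duplicate taxon labels")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    return lengths.pop()


def _check_alphabet(taxa: Sequence[str], seqs: Sequence[str]) -> None:
    for t, s in zip(taxa, seqs):
        bad = set(s) - ALPHABET
        if bad:
            raise AlignmentError(f"{t}: illegal characters {sorted(bad)}")


def codon_is_resolved(codon: str) -> bool:
    """True when all three positions are plain bases (no N, no gap)."""
    return all(b in "ACGT" for b in codon)


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame aligned coding sequences keyed by taxon.

    Invariants: equal sequence lengths divisible by 3; alphabet A/C/G/T/N/-;
    no internal stop codon in any fully resolved codon.  A terminal stop is
    permitted and flagged via :attr:`has_terminal_stop`.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        length = _check_equal_lengths(self.taxa, self.sequences)
        if length % 3 != 0:
            raise AlignmentError(f"length {length} not divisible by 3")
        _check_alphabet(self.taxa, self.sequences)
        n_codons = length // 3
        for t, s in zip(self.taxa, self.sequences):
            for j in range(n_codons - 1):  # last codon may be a stop
                codon = s[3 * j : 3 * j + 3]
                if codon_is_resolved(codon) and codon in STOP_CODONS:
                    raise AlignmentError(f"{t}: internal stop codon {codon} at codon {j}")

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    @property
    def length_codons(self) -> int:
        return self.length_nt // 3

    @property
    def has_terminal_stop(self) -> bool:
        j = self.length_codons - 1
        return any(
            codon_is_resolved(s[3 * j : 3 * j + 3]) and s[3 * j : 3 * j + 3] in STOP_CODONS
            for s in self.sequences
        )

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def codon(self, taxon_index: int, site: int) -> str:
        return self.sequences[taxon_index][3 * site : 3 * site + 3]

    def codon_column(self, site: int) -> list[str]:
        return [s[3 * site : 3 * site + 3] for s in self.sequences]

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.taxa, self.sequences))


@dataclass(frozen=True)
class ProteinAlignment:
    """Aligned residue strings, one residue per complete codon ('X' = missing)."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_equal_lengths(self.taxa, self.sequences)

    @property
    def length_aa(self) -> int:
        return len(self.sequences[0])

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def column(self, site: int) -> list[str]:
        return [s[site] for s in self.sequences]

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.taxa, self.sequences))


@dataclass(frozen=True)
class UTRAlignment:
    """Aligned non-coding nucleotide sequence.

    ``start_codon_offset`` / ``stop_codon_offset`` anchor the alignment to the
    coding sequence: the alignment column (0-based) at which the start codon
    begins, respectively the column just past the stop codon.  Either anchor
    may be ``None`` when the corresponding end is not represented.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    start_codon_offset: int | None = None
    stop_codon_offset: int | None = None

    def __post_init__(self) -> None:
        _check_equal_lengths(self.taxa, self.sequences)
        _check_alphabet(self.taxa, self.sequences)

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def ungapped(self, taxon: str) -> tuple[str, list[int]]:
        """Ungapped sequence for *taxon* plus a map position -> alignment column."""
        seq = self.sequence(taxon)
        chars, cols = [], []
        for i, c in enumerate(seq):
            if c != "-":
                chars.append(c)
                cols.append(i)
        return "".join(chars), cols

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.taxa, self.sequences))


def translate(aln: CodonAlignment) -> ProteinAlignment:
    """Translate an in-frame codon alignment with the standard genetic code.

    Codons containing N or a gap translate to 'X'.  A terminal stop codon is
    dropped from the protein (the nucleotide record keeps it); a resolved
    internal stop raises :class:`AlignmentError`.
    """
    n = aln.length_codons
    drop_last = aln.has_terminal_stop
    n_out = n - 1 if drop_last else n
    out = []
    for s in aln.sequences:
        residues = []
        for j in range(n_out):
            codon = s[3 * j : 3 * j + 3]
            if not codon_is_resolved(codon):
                residues.append("X")
                continue
            aa = GENETIC_CODE[codon]
            if aa == "*":
                raise AlignmentError(f"internal stop codon {codon} at codon {j}")
            residues.append(aa)
        out.append("".join(residues))
    return ProteinAlignment(aln.taxa, tuple(out))


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta_alignment(path: str | Path, expect_codon: bool = False):
    """Read an aligned multi-FASTA into a codon or UTR alignment.

    ``expect_codon=True`` returns a validated :class:`CodonAlignment`
    (length divisible by 3 enforced); otherwise a :class:`UTRAlignment`.
    Taxon order is preserved from the file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    if expect_codon:
        return CodonAlignment(taxa, seqs)
    return UTRAlignment(taxa, seqs)


def write_fasta_alignment(aln, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Timed trees


class TreeError(ValueError):
    """Raised for malformed trees (unlabeled leaves, negative branch lengths)."""


@dataclass
class TimedTree:
    """Rooted topology with node ages in millions of years.

    The age of a node is its maximum path length (in branch-length units,
    taken to be My) to any descendant leaf; leaves have age 0.  Ultrametricity
    is not required, so on a non-clock tree the age of an internal node is a
    lower bound on its true calibration.
    """

    tree: dendropy.Tree
    _ages: dict = field(default_factory=dict, repr=False)
    _leaf_by_label: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True  # topology is taken as rooted throughout
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("unlabeled leaf in tree")
            self._leaf_by_label[leaf.taxon.label] = leaf
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
        self._postorder = list(self.tree.postorder_node_iter())
        self._preorder = list(self.tree.preorder_node_iter())
        for node in self._postorder:
            if node.is_leaf():
                self._ages[node] = 0.0
            else:
                self._ages[node] = max(
                    self._ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
                )

    @classmethod
    def from_newick(cls, newick: str) -> "TimedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "TimedTree":
        return cls.from_newick(Path(path).read_text())

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(self._leaf_by_label)

    @property
    def postorder_nodes(self) -> list:
        return self._postorder

    @property
    def preorder_nodes(self) -> list:
        return self._preorder

    def age(self, node) -> float:
        return self._ages[node]

    def mrca(self, a: str, b: str):
        for t in (a, b):
            if t not in self._leaf_by_label:
                raise TreeError(f"unknown taxon {t!r}")
        if a == b:
            return self._leaf_by_label[a]
        node = self.tree.mrca(taxa=[self._leaf_by_label[a].taxon, self._leaf_by_label[b].taxon])
        return node

    def t_mrca(self, a: str, b: str) -> float:
        """Age (My) of the most recent common ancestor of taxa *a* and *b*."""
        return self._ages[self.mrca(a, b)]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_newick_timed(path: str | Path) -> TimedTree:
    """Read a Newick file with branch lengths into a :class:`TimedTree`."""
    return TimedTree.from_file(path)


# ---------------------------------------------------------------------------
# Exon maps (BED-like, codon units)


@dataclass(frozen=True)
class ExonRecord:
    name: str
    start: int  # codon units, 0-based
    end: int  # half-open

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad exon interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonMap:
    """Sorted, non-overlapping exon intervals in codon coordinates."""

    exons: tuple[ExonRecord, ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValueError("exon intervals overlap or are unsorted")
            prev_end = e.end

    @property
    def covered_length(self) -> int:
        return sum(e.length for e in self.exons)

    def validate_against(self, length_aa: int) -> None:
        if self.exons and self.exons[-1].end > length_aa:
            raise ValueError(
                f"exon map extends to {self.exons[-1].end} beyond protein length {length_aa}"
            )


def read_exon_map(path: str | Path) -> ExonMap:
    """Read a BED-like TSV: name, start, end (codon units, 0-based half-open)."""
    exons = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, start, end = line.split("\t")[:3]
        exons.append(ExonRecord(name, int(start), int(end)))
    exons.sort(key=lambda e: e.start)
    return ExonMap(tuple(exons))


def write_exon_map(exon_map: ExonMap, path: str | Path) -> None:
    lines = [f"{e.name}\t{e.start}\t{e.end}" for e in exon_map.exons]
    Path(path).write_text("\n".join(lines) + "\n")
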