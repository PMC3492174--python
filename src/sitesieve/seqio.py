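"""Alignment and tree input/output, plus the standard data transforms.

Alignments are rectangular character matrices over the IUPAC nucleotide or
amino-acid alphabet, with an attached partition map assigning contiguous
1-based site ranges to named genes.  Transforms provided here mirror the
preprocessing steps routinely applied to protein-coding phylogenomic
matrices: gene concatenation, removal of third codon positions (N12),
degeneracy recoding that masks synonymous variation (DEGEN1), and
translation to amino acids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "Alignment",
    "GenePartitionSet",
    "read_alignment",
    "write_alignment",
    "concatenate_genes",
    "drop_third_positions",
    "degen1_recode",
    "translate_aa",
    "read_trees",
    "write_trees",
    "write_partition_map",
    "read_partition_map",
]

NT_MISSING = frozenset("-?N")
AA_MISSING = frozenset("-?X")

# IUPAC nucleotide ambiguity codes as state sets
IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_NT.items() if k not in "-?N"}
_SET_TO_IUPAC[frozenset("ACGT")] = "N"

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
VALID_NT = frozenset(IUPAC_NT) | {"U"}
VALID_AA = frozenset(AA_ALPHABET) | {"X", "-", "?", "*", "B", "Z", "J"}


class AlignmentFormatError(ValueError):
    """Raised for unparseable or internally inconsistent alignment files."""


@dataclass
class Alignment:
    """Taxa-by-sites character matrix with a gene partition map.

    Parameters
    ----------
    taxa : list of str
        Ordered, unique sequence labels.
    matrix : ndarray of shape (n_taxa, n_sites), dtype '<U1'
        Uppercase characters.
    partitions : dict
        Gene name -> (start, end), 1-based inclusive site ranges, disjoint
        and jointly covering all sites, in site order.
    alphabet : {'nt', 'aa'}
    """

    taxa: list[str]
    matrix: np.ndarray
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("matrix must be 2-D")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentFormatError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise AlignmentFormatError(f"duplicate taxon labels: {sorted(dupes)}")
        if not self.partitions:
            self.partitions = {"all": (1, self.n_sites)} if self.n_sites else {}
        self._check_partitions()
        valid = VALID_NT if self.alphabet == "nt" else VALID_AA
        bad = set(self.matrix.ravel()) - valid
        if bad:
            raise AlignmentFormatError(f"invalid characters for {self.alphabet}: {sorted(bad)}")

    def _check_partitions(self) -> None:
        covered = 0
        prev_end = 0
        for gene, (lo, hi) in self.partitions.items():
            if lo != prev_end + 1 or hi < lo - 1:
                raise AlignmentFormatError(
                    f"partition {gene!r} range ({lo},{hi}) not contiguous from {prev_end}"
                )
            covered += hi - lo + 1
            prev_end = hi
        if covered != self.n_sites:
            raise AlignmentFormatError("partitions do not cover all sites")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def missing_chars(self) -> frozenset[str]:
        return NT_MISSING if self.alphabet == "nt" else AA_MISSING

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def occupancy(self) -> float:
        """Fraction of cells that are not missing ('-', '?', 'N'/'X')."""
        miss = np.isin(self.matrix, list(self.missing_chars))
        return 1.0 - miss.mean() if self.matrix.size else 1.0

    def gene_slice(self, gene: str) -> "Alignment":
        lo, hi = self.partitions[gene]
        return Alignment(
            list(self.taxa), self.matrix[:, lo - 1 : hi],
            {gene: (1, hi - lo + 1)}, self.alphabet,
        )

    def take_sites(self, idx: np.ndarray, partition_name: str = "filtered") -> "Alignment":
        """Subset to the given 0-based site indices (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return Alignment(
            list(self.taxa), self.matrix[:, idx],
            {partition_name: (1, len(idx))} if len(idx) else {}, self.alphabet,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
            and self.partitions == other.partitions
        )


@dataclass
class GenePartitionSet:
    """Per-gene alignments sharing a master taxon list."""

    genes: dict[str, Alignment]
    master_taxa: list[str]

    def __post_init__(self) -> None:
        for name, aln in self.genes.items():
            extra = set(aln.taxa) - set(self.master_taxa)
            if extra:
                raise AlignmentFormatError(
                    f"gene {name!r} has taxa outside the master list: {sorted(extra)}"
                )


def read_alignment(path, fmt: str = "fasta", alphabet: str = "nt") -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Characters are uppercased; 'U' is mapped to 'T'.  Ragged rows and
    duplicate labels raise :class:`AlignmentFormatError`.
    """
    biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
    try:
        if fmt == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), biofmt))
    except ValueError as exc:
        raise AlignmentFormatError(str(exc)) from exc
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"ragged sequence lengths in {path}: {sorted(lengths)}")
    taxa = [r.id for r in records]
    mat = np.array([list(str(r.seq).upper().replace("U", "T")) for r in records], dtype="<U1")
    return Alignment(taxa, mat, alphabet=alphabet)


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=t, description="")
        for t, row in zip(aln.taxa, aln.matrix)
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    else:
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-relaxed")


def concatenate_genes(genes: GenePartitionSet, master_taxa: list[str] | None = None) -> Alignment:
    """Concatenate per-gene alignments gene-by-gene into a supermatrix.

    Taxa absent from a gene are filled with '?' over that gene's sites; the
    partition map records the gene boundaries in concatenation order.
    """
    if master_taxa is None:
        master_taxa = genes.master_taxa
    alphabet = next(iter(genes.genes.values())).alphabet if genes.genes else "nt"
    blocks, partitions = [], {}
    pos = 0
    for name, g in genes.genes.items():
        block = np.full((len(master_taxa), g.n_sites), "?", dtype="<U1")
        for i, t in enumerate(master_taxa):
            if t in g.taxa:
                block[i] = g.matrix[g.taxa.index(t)]
        blocks.append(block)
        partitions[name] = (pos + 1, pos + g.n_sites)
        pos += g.n_sites
    mat = np.concatenate(blocks, axis=1) if blocks else np.empty((len(master_taxa), 0), dtype="<U1")
    return Alignment(list(master_taxa), mat, partitions, alphabet)


def _codon_starts(aln: Alignment, op: str) -> np.ndarray:
    starts = []
    for gene, (lo, hi) in aln.partitions.items():
        n = hi - lo + 1
        if n % 3:
            raise AlignmentFormatError(
                f"{op}: gene {gene!r} has length {n}, not divisible by 3"
            )
        starts.extend(range(lo - 1, hi, 3))
    return np.asarray(starts, dtype=int)


def drop_third_positions(aln: Alignment) -> Alignment:
    """Remove every third codon position (the N12 transform)."""
    _codon_starts(aln, "drop_third_positions")
    keep, partitions = [], {}
    pos = 0
    for gene, (lo, hi) in aln.partitions.items():
        n = hi - lo + 1
        for s in range(lo - 1, hi, 3):
            keep.extend((s, s + 1))
        partitions[gene] = (pos + 1, pos + 2 * n // 3)
        pos += 2 * n // 3
    out = aln.matrix[:, keep] if keep else np.empty((aln.n_taxa, 0), dtype="<U1")
    return Alignment(list(aln.taxa), out, partitions, aln.alphabet)


def _degen_tables() -> tuple[dict[str, str], dict[str, str]]:
    """Degeneracy recodings derived from the standard genetic code.

    For each amino acid (and for the stop 'codon family'), the recoded codon
    carries, at each position, the IUPAC code covering every nucleotide seen
    among that amino acid's codons.
    """
    table = standard_dna_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    stop = {c: "*" for c in table.stop_codons}
    by_aa["*"] = list(stop)
    codon_map: dict[str, str] = {}
    aa_degen: dict[str, str] = {}
    for aa, codons in by_aa.items():
        degen = "".join(
            _SET_TO_IUPAC[frozenset(c[i] for c in codons)] for i in range(3)
        )
        aa_degen[aa] = degen
        for c in codons:
            codon_map[c] = degen
    return codon_map, aa_degen


_DEGEN_CODON_MAP, _DEGEN_AA_MAP = _degen_tables()


def _expand_codon(codon: str) -> list[str]:
    """All unambiguous codons compatible with an IUPAC-ambiguous codon."""
    out = [""]
    for ch in codon:
        out = [p + n for p in out for n in IUPAC_NT[ch]]
    return out


def degen1_recode(aln: Alignment) -> Alignment:
    """Mask synonymous variation by recoding codons with ambiguity codes.

    Each codon is replaced by the degeneracy codon of its amino acid: at each
    position the IUPAC code covering all nucleotides among the synonymous
    codons.  Ambiguous codons are recoded over the union of the amino acids
    they may encode; codons containing missing characters ('-', '?', 'N')
    pass through unchanged.  Stop codons are recoded over the stop family
    with a warning.
    """
    if aln.alphabet != "nt":
        raise AlignmentFormatError("degen1_recode requires a nucleotide alignment")
    starts = _codon_starts(aln, "degen1_recode")
    out = aln.matrix.copy()
    stop_seen = False
    for i in range(aln.n_taxa):
        row = aln.matrix[i]
        for s in starts:
            codon = "".join(row[s : s + 3])
            if set(codon) & NT_MISSING:
                continue
            if codon in _DEGEN_CODON_MAP:
                degen = _DEGEN_CODON_MAP[codon]
                stop_seen = stop_seen or codon in standard_dna_table.stop_codons
            else:
                aas = {
                    standard_dna_table.forward_table.get(c, "*")
                    for c in _expand_codon(codon)
                }
                stop_seen = stop_seen or "*" in aas
                sets = [
                    frozenset().union(*(IUPAC_NT[_DEGEN_AA_MAP[a][p]] for a in aas))
                    for p in range(3)
                ]
                degen = "".join(_SET_TO_IUPAC[s] for s in sets)
            out[i, s : s + 3] = list(degen)
    if stop_seen:
        warnings.warn("stop codon(s) encountered during degeneracy recoding")
    return Alignment(list(aln.taxa), out, dict(aln.partitions), "nt")


def translate_aa(aln: Alignment) -> Alignment:
    """Translate an in-frame nucleotide alignment to amino acids.

    Codons with any missing character become 'X', except all-gap codons
    which stay '-'.  Internal stops translate to '*' with a warning.
    """
    if aln.alphabet != "nt":
        raise AlignmentFormatError("translate_aa requires a nucleotide alignment")
    starts = _codon_starts(aln, "translate_aa")
    out = np.empty((aln.n_taxa, len(starts)), dtype="<U1")
    stop_seen = False
    for i in range(aln.n_taxa):
        row = aln.matrix[i]
        for j, s in enumerate(starts):
            codon = "".join(row[s : s + 3])
            if codon == "---":
                out[i, j] = "-"
            elif set(codon) & NT_MISSING:
                out[i, j] = "X"
            else:
                aas = {
                    standard_dna_table.forward_table.get(c, "*")
                    for c in _expand_codon(codon)
                }
                if len(aas) == 1:
                    out[i, j] = aas.pop()
                    stop_seen = stop_seen or out[i, j] == "*"
                else:
                    out[i, j] = "X"
    if stop_seen:
        warnings.warn("internal stop codon(s) translated to '*'")
    partitions, pos = {}, 0
    for gene, (lo, hi) in aln.partitions.items():
        n = (hi - lo + 1) // 3
        partitions[gene] = (pos + 1, pos + n)
        pos += n
    return Alignment(list(aln.taxa), out, partitions, "aa")


def read_trees(path_or_string: str) -> list:
    """Read one or more newick trees, returning :class:`sitesieve.trees.Tree`."""
    from .trees import Tree

    try:
        text = open(path_or_string).read()
    except (OSError, ValueError):
        text = str(path_or_string)
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    return [Tree.from_newick(c + ";") for c in chunks]


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


def write_partition_map(aln: Alignment, path, datatype: str = "DNA") -> None:
    """Serialize the partition map as RAxML-style 'DNA, gene = lo-hi' lines."""
    with open(path, "w") as fh:
        for gene, (lo, hi) in aln.partitions.items():
            fh.write(f"{datatype}, {gene} = {lo}-{hi}\n")


def read_partition_map(path) -> dict[str, tuple[int, int]]:
    partitions = {}
    for line in open(path):
        line = line.strip()
        if not line:
            continue
        _, rest = line.split(",", 1)
        name, rng = rest.split("=")
        lo, hi = rng.strip().split("-")
        partitions[name.strip()] = (int(lo), int(hi))
    return partitions
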