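"""Paired protein/CDS database, Lys-C digestion, and peptide-to-codon lookup.

Per-codon mistranslation analysis needs to know which codon encoded each
residue of each identified peptide.  This module pairs a protein FASTA with
its coding-sequence FASTA (one CDS per protein record, validated by exact
translation), digests proteins in silico with Lys-C, locates peptides back
in the database, and maps residue indices to codons.

Coordinates are 0-based half-open throughout; 1-based coordinates appear
only in rendered reports.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "DatabaseError",
    "CodingGene",
    "PeptideLocation",
    "SequenceDatabase",
    "read_paired_fasta",
    "digest_lysC",
    "locate_peptide",
    "codon_at",
    "translate_codon",
    "codons_for_residue",
]

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_FORWARD = dict(standard_dna_table.forward_table)  # codon -> amino acid


class DatabaseError(ValueError):
    """A protein/CDS pair violates the database contract."""


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) encoded by a DNA codon; '*' for stop."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    try:
        return _FORWARD[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


def codons_for_residue(aa: str) -> list[str]:
    """Sorted DNA codons encoding a given amino acid."""
    codons = sorted(c for c, r in _FORWARD.items() if r == aa)
    if not codons:
        raise ValueError(f"no codons encode residue {aa!r}")
    return codons


@dataclass(frozen=True)
class CodingGene:
    """A protein sequence paired with the coding DNA sequence behind it.

    ``cds`` covers exactly the protein (3 nt per residue) plus, when
    ``has_stop`` is set, one trailing stop codon.  The stop codon is kept
    in ``cds`` but never indexed by :meth:`codon`.
    """

    gene_id: str
    protein: str
    cds: str
    has_stop: bool = False

    @classmethod
    def from_sequences(cls, gene_id: str, protein: str, cds: str) -> "CodingGene":
        """Validate and build; raises :class:`DatabaseError` on any mismatch."""
        protein = protein.upper()
        cds = cds.upper()
        if not protein:
            raise DatabaseError(f"{gene_id}: empty protein sequence")
        bad = set(cds) - set("ACGT")
        if bad:
            raise DatabaseError(
                f"{gene_id}: CDS contains non-ACGT characters {sorted(bad)}"
            )
        if len(cds) % 3 != 0:
            raise DatabaseError(f"{gene_id}: CDS length {len(cds)} is not a multiple of 3")
        n_codons = len(cds) // 3
        if n_codons == len(protein) + 1:
            has_stop = True
        elif n_codons == len(protein):
            has_stop = False
        else:
            raise DatabaseError(
                f"{gene_id}: CDS has {n_codons} codons for a protein of "
                f"{len(protein)} residues"
            )
        translated = str(Seq(cds).translate())
        if has_stop:
            if not translated.endswith("*"):
                raise DatabaseError(f"{gene_id}: CDS does not end in a stop codon")
            translated = translated[:-1]
        internal = translated.find("*")
        if internal != -1:
            raise DatabaseError(
                f"{gene_id}: internal stop codon at residue index {internal}"
            )
        if translated != protein:
            for i, (a, b) in enumerate(zip(translated, protein)):
                if a != b:
                    raise DatabaseError(
                        f"{gene_id}: translation mismatch at residue index {i} "
                        f"(CDS encodes {a!r}, protein has {b!r})"
                    )
            raise DatabaseError(f"{gene_id}: translation mismatch")  # pragma: no cover
        return cls(gene_id, protein, cds, has_stop)

    def codon(self, residue_index: int) -> str:
        """Codon encoding ``protein[residue_index]``."""
        if not 0 <= residue_index < len(self.protein):
            raise IndexError(
                f"residue index {residue_index} outside protein of length "
                f"{len(self.protein)} ({self.gene_id})"
            )
        return self.cds[3 * residue_index : 3 * residue_index + 3]


@dataclass(frozen=True)
class PeptideLocation:
    """Exact occurrence of a peptide within a protein (0-based offset)."""

    gene_id: str
    start: int
    length: int


@dataclass
class SequenceDatabase:
    """An ordered collection of :class:`CodingGene` records.

    Genes are kept sorted by ``gene_id`` so every downstream traversal is
    deterministic.  A concatenated protein corpus is built lazily for fast
    exact-substring peptide location.
    """

    genes: dict[str, CodingGene] = field(default_factory=dict)
    _corpus: str | None = field(default=None, repr=False, compare=False)
    _offsets: list[int] = field(default_factory=list, repr=False, compare=False)
    _order: list[str] = field(default_factory=list, repr=False, compare=False)

    @classmethod
    def from_genes(cls, genes: list[CodingGene]) -> "SequenceDatabase":
        db = cls()
        for gene in sorted(genes, key=lambda g: g.gene_id):
            if gene.gene_id in db.genes:
                raise DatabaseError(f"duplicate gene ID {gene.gene_id!r}")
            db.genes[gene.gene_id] = gene
        return db

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> CodingGene:
        return self.genes[gene_id]

    def _build_corpus(self) -> None:
        # Proteins joined with '#' (never a residue code) so one C-level
        # substring scan covers the whole database.
        parts, offsets, order = [], [], []
        pos = 0
        for gid, gene in self.genes.items():
            order.append(gid)
            offsets.append(pos)
            parts.append(gene.protein)
            pos += len(gene.protein) + 1
        self._corpus = "#".join(parts)
        self._offsets = offsets
        self._order = order

    def locate(self, base_sequence: str) -> list[PeptideLocation]:
        """All exact occurrences of a peptide, in (gene_id, start) order."""
        if not base_sequence:
            return []
        if self._corpus is None:
            self._build_corpus()
        corpus = self._corpus
        hits: list[PeptideLocation] = []
        i = corpus.find(base_sequence)
        while i != -1:
            gi = bisect_right(self._offsets, i) - 1
            gid = self._order[gi]
            start = i - self._offsets[gi]
            # a hit spanning the '#' separator cannot occur because '#' is
            # not a residue character
            hits.append(PeptideLocation(gid, start, len(base_sequence)))
            i = corpus.find(base_sequence, i + 1)
        hits.sort(key=lambda loc: (loc.gene_id, loc.start))
        return hits


def _read_fasta(path: str) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise DatabaseError(f"duplicate FASTA ID {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise DatabaseError(f"no FASTA records in {path}")
    return records


def read_paired_fasta(protein_path: str, cds_path: str) -> SequenceDatabase:
    """Load and cross-validate a protein FASTA and its CDS FASTA.

    Record IDs must match one-to-one and each CDS must translate exactly
    (standard genetic code) to its protein, with an optional trailing stop.
    """
    proteins = _read_fasta(protein_path)
    cdss = _read_fasta(cds_path)
    only_prot = sorted(set(proteins) - set(cdss))
    only_cds = sorted(set(cdss) - set(proteins))
    if only_prot or only_cds:
        raise DatabaseError(
            f"ID mismatch between FASTA files: protein-only {only_prot[:5]}, "
            f"CDS-only {only_cds[:5]}"
        )
    genes = [
        CodingGene.from_sequences(gid, proteins[gid], cdss[gid])
        for gid in sorted(proteins)
    ]
    return SequenceDatabase.from_genes(genes)


def digest_lysC(protein: str, max_missed: int = 0) -> list[tuple[str, int]]:
    """In-silico Lys-C digest: cleave C-terminal to every K, including K|P.

    Returns (peptide, start offset) pairs.  With ``max_missed`` > 0 all
    concatenations of up to ``max_missed + 1`` adjacent fragments are also
    returned, in (start, length) order.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # fully cleaved fragments tile the protein
    fragments: list[tuple[str, int]] = []
    start = 0
    for i, aa in enumerate(protein):
        if aa == "K":
            fragments.append((protein[start : i + 1], start))
            start = i + 1
    if start < len(protein):
        fragments.append((protein[start:], start))
    peptides: list[tuple[str, int]] = []
    for i in range(len(fragments)):
        seq = ""
        for j in range(i, min(i + max_missed + 1, len(fragments))):
            seq += fragments[j][0]
            peptides.append((seq, fragments[i][1]))
    peptides.sort(key=lambda p: (p[1], len(p[0])))
    return peptides


def locate_peptide(base_sequence: str, db: SequenceDatabase) -> list[PeptideLocation]:
    """All exact occurrences of a wild-type peptide across the database."""
    return db.locate(base_sequence)


def codon_at(gene: CodingGene, residue_index: int) -> str:
    """Codon encoding residue ``residue_index`` of ``gene`` (0-based)."""
    return gene.codon(residue_index)
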