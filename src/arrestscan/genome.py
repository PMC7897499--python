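"""Genome data model and I/O.

In-memory containers for annotated bacterial genomes, upstream candidate
ORFs and result tables, together with readers/writers for the plain-text
formats the pipeline consumes and emits (nucleotide FASTA, GFF3 with
``product=`` attributes, TSV result tables).

Coordinate conventions
----------------------
* internal nucleotide coordinates are 0-based, half-open;
* GFF3 I/O converts to/from the format's 1-based inclusive coordinates;
* protein residues are numbered 1-based, which matches the residue
  numbering used for arrest peptides in the literature (e.g. Arg98).

Translation uses the bacterial/archaeal genetic code (NCBI table 11) with
the alternative initiators ATG/GTG/TTG all read as Met.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "Genome",
    "GeneRecord",
    "CandidateORF",
    "GenomeFormatError",
    "TranslationError",
    "translate",
    "reverse_complement",
    "read_genome",
    "write_genome",
    "write_gff3",
    "write_fasta",
    "write_protein_fasta",
]

_VALID_DNA = re.compile(r"^[ACGT]+$")
_TOKEN_SPLIT = re.compile(r"[^A-Za-z0-9]+")

CODE_TABLE_ID = 11
START_CODONS = ("ATG", "GTG", "TTG")
_TABLE = CodonTable.unambiguous_dna_by_id[CODE_TABLE_ID]
STOP_CODONS = tuple(_TABLE.stop_codons)


class GenomeFormatError(ValueError):
    """Malformed FASTA/GFF3 input (bad coordinates, unknown seqid, non-ACGT)."""


class TranslationError(ValueError):
    """CDS cannot be translated (internal stop, length not divisible by 3)."""


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate(cds_dna: str, strand: str = "+") -> str:
    """Translate a CDS to its amino-acid sequence (stop excluded).

    The terminal stop codon, if present, is removed.  An internal stop or a
    length not divisible by 3 raises :class:`TranslationError`.  The first
    codon is read as Met when it is one of the initiators ATG/GTG/TTG.
    """
    if strand == "-":
        cds_dna = reverse_complement(cds_dna)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(cds_dna) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds_dna)} not divisible by 3")
    if not _VALID_DNA.match(cds_dna):
        raise GenomeFormatError("CDS contains non-ACGT characters")
    aa = str(Seq(cds_dna).translate(table=CODE_TABLE_ID))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        pos = aa.index("*") + 1
        raise TranslationError(f"internal stop codon at codon {pos}")
    if aa and cds_dna[:3] in START_CODONS:
        aa = "M" + aa[1:]
    return aa


def translate_frame(dna: str) -> str:
    """Translate a nucleotide string codon-by-codon, keeping '*' for stops.

    Low-level helper without start/stop conventions, used by the construct
    designers to inspect reading frames.
    """
    if len(dna) % 3 != 0:
        raise TranslationError(f"length {len(dna)} not divisible by 3")
    return str(Seq(dna).translate(table=CODE_TABLE_ID))


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene interval on a genome (0-based, half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str
    name: str = ""
    product_keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        if self.end - self.start < 3:
            raise ValueError(f"gene {self.gene_id}: interval shorter than one codon")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A nucleotide sequence with strand-aware annotated gene intervals."""

    genome_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")
        if not _VALID_DNA.match(self.sequence):
            raise GenomeFormatError(
                f"genome {self.genome_id}: sequence contains non-ACGT characters "
                "(IUPAC ambiguity codes are not supported)"
            )
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} interval [{g.start},{g.end}) outside genome "
                    f"of length {len(self.sequence)}"
                )
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateORF:
    """An upstream ORF tied to a sec/yidC-class target gene.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    genome and *include* the stop codon; ``protein`` excludes the stop.
    ``distance_nt`` is the strand-aware gap between the ORF's stop-codon end
    and the target gene's start (>= 0).
    """

    candidate_id: str
    genome_id: str
    target_gene_id: str
    start: int
    end: int
    strand: str
    protein: str
    distance_nt: int
    edge_truncated: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        expect = (self.end - self.start) // 3 - 1
        if len(self.protein) != expect:
            raise ValueError(
                f"protein length {len(self.protein)} != (end-start)/3 - 1 = {expect}"
            )
        if "*" in self.protein:
            raise ValueError("protein contains an internal stop")
        if self.distance_nt < 0:
            raise ValueError("distance_nt must be >= 0")

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def _tokens(text: str) -> tuple[str, ...]:
    return tuple(t.lower() for t in _TOKEN_SPLIT.split(text) if t)


def read_genome(fasta_path, gff3_path) -> Genome:
    """Read one genome from a nucleotide FASTA and its GFF3 annotation.

    The FASTA must contain exactly one record; GFF3 rows must reference its
    id.  Only features of type ``gene`` or ``CDS`` become
    :class:`GeneRecord` entries (others, e.g. exported ``ORF`` rows, are
    ignored).  The ``gene``/``Name`` attribute becomes the gene name; both
    it and the ``product`` attribute are tokenized (lower-cased) into
    ``product_keywords``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise GenomeFormatError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    sequence = str(rec.seq).upper()

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        if feat.seqid != rec.id:
            raise GenomeFormatError(
                f"{gff3_path}: feature references unknown sequence id {feat.seqid!r} "
                f"(FASTA record is {rec.id!r})"
            )
        start = feat.start - 1  # GFF3 1-based inclusive -> 0-based half-open
        end = feat.end
        if start < 0 or end <= start:
            raise GenomeFormatError(f"{gff3_path}: malformed coordinates for {feat.id}")
        name = (feat.attributes.get("gene") or feat.attributes.get("Name") or [""])[0]
        product = (feat.attributes.get("product") or [""])[0]
        keywords = _tokens(name) + _tokens(product)
        gene_id = feat.id or f"{rec.id}:{start}-{end}"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                name=name,
                product_keywords=keywords,
            )
        )
    return Genome(genome_id=rec.id, sequence=sequence, genes=genes)


def write_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_gff3(genome: Genome, path, extra_features=()) -> None:
    """Write gene annotation as GFF3 (1-based inclusive coordinates).

    ``extra_features`` is an iterable of (type, start, end, strand, attrs)
    tuples in internal coordinates, e.g. exported candidate ORFs.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.name:
                attrs.append(f"gene={g.name}")
            if g.product_keywords:
                attrs.append("product=" + " ".join(g.product_keywords))
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "arrestscan",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
        for ftype, start, end, strand, attrs in extra_features:
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "arrestscan",
                        ftype,
                        str(start + 1),
                        str(end),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_genome(genome: Genome, fasta_path, gff3_path) -> None:
    write_fasta(genome, fasta_path)
    write_gff3(genome, gff3_path)


def write_protein_fasta(candidates, path) -> None:
    """Write candidate proteins as FASTA with ``candidate_id|genome_id`` headers."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.candidate_id}|{c.genome_id}\n{c.protein}\n")
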