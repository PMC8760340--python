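"""Sequence and annotation I/O plus basic protein physicochemistry.

Conventions used throughout the package:

* protein residue positions are 1-based on the sequence *as provided*
  (precursor numbering, so a signal peptide occupies residues 1..n);
* genome coordinates are 1-based inclusive, GFF3 dialect;
* the protein alphabet is the 20 standard residues plus ``X`` (unknown).
  ``X`` is tolerated by scanning and alignment (where it scores zero) but
  rejected by physicochemical calculations, which need real masses.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

# Average residue (i.e. amino acid minus water) masses in Daltons, and the
# mass of one water molecule added back per chain.  Values are the standard
# average masses rounded to 0.01 Da and are pinned here: every physchem
# number this package reports derives from this table.
RESIDUE_MASS_DA = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}
WATER_MASS_DA = 18.02

# Bjellqvist-style pKa set used for the net-charge curve.  pI depends on the
# table chosen; this one is fixed so results are reproducible.
PKA_POSITIVE = {"Nterm": 7.50, "K": 10.00, "R": 12.00, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}


class SeqIOError(ValueError):
    """Raised on malformed FASTA/GFF3 input or alphabet violations."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record requires a non-empty id")
        if not self.seq:
            raise SeqIOError(f"{self.id}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise SeqIOError(
                f"{self.id}: invalid residue(s) {sorted(bad)}; allowed "
                f"alphabet is the 20 standard residues plus X"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.seq):
            raise IndexError(f"{self.id}: position {pos} outside 1..{len(self.seq)}")
        return self.seq[pos - 1]


@dataclass(frozen=True)
class AlignedRecord:
    """A gapped sequence from a multiple alignment (gaps allowed)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - PROTEIN_ALPHABET - {GAP}
        if not self.seq or bad:
            raise SeqIOError(f"{self.id}: invalid aligned sequence")


@dataclass(frozen=True)
class GeneModel:
    """A CDS feature linked to its translated protein product."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SeqIOError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise SeqIOError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class PhyschemSummary:
    mw_da: float
    pi: float


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[ProteinRecord] | list[AlignedRecord]:
    """Read a protein FASTA file, preserving record order.

    Duplicate ids are an error (no silent overwrite).  With
    ``allow_gaps=True`` returns :class:`AlignedRecord` objects so aligned
    FASTA (``-`` gap characters) can be loaded for phylogenetics.
    """
    path = Path(path)
    records: list = []
    seen: set[str] = set()
    with open(path) as fh:
        text = fh.read()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0]
        raise SeqIOError(f"{path}: malformed FASTA, expected '>' header, got {first[:40]!r}")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip()
        if allow_gaps:
            records.append(AlignedRecord(id=rec.id, seq=seq))
        else:
            records.append(ProteinRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord | AlignedRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, 60-column wrapped."""
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i:i + 60] + "\n")


def read_dna_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into ``{contig_id: sequence}``."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SeqIOError(f"{path}: duplicate contig id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        # allow empty file -> empty genome
        pass
    return out


def write_dna_fasta(contigs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _translate_cds(dna: str, gene_id: str) -> str:
    if len(dna) % 3 != 0:
        raise SeqIOError(f"{gene_id}: CDS length {len(dna)} not divisible by 3")
    aa = str(Seq(dna).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise SeqIOError(f"{gene_id}: internal stop codon in CDS translation")
    if not aa:
        raise SeqIOError(f"{gene_id}: CDS translates to empty protein")
    return aa


def read_gff3(path: str | Path, fasta_path: str | Path) -> tuple[list[GeneModel], list[ProteinRecord]]:
    """Read CDS features from GFF3 and translate them against the genome.

    Returns gene models sorted by (contig, start) and the corresponding
    translated proteins (stop codon removed).  Minus-strand CDS are
    translated from the reverse complement.
    """
    import gffutils

    contigs = read_dna_fasta(fasta_path)
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("##gff-version"):
        raise SeqIOError(f"{path}: missing ##gff-version pragma")
    db = gffutils.create_db(text, ":memory:", from_string=True, force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    feats = sorted(db.features_of_type("CDS"), key=lambda f: (f.seqid, f.start))
    for f in feats:
        ids = f.attributes.get("ID")
        if not ids:
            raise SeqIOError(f"{path}: CDS at {f.seqid}:{f.start}-{f.end} missing ID attribute")
        gene_id = ids[0]
        if f.seqid not in contigs:
            raise SeqIOError(f"{gene_id}: contig {f.seqid!r} not present in genome FASTA")
        contig_seq = contigs[f.seqid]
        if f.start < 1 or f.end > len(contig_seq):
            raise SeqIOError(
                f"{gene_id}: CDS {f.start}-{f.end} outside contig bounds 1-{len(contig_seq)}"
            )
        dna = contig_seq[f.start - 1:f.end]
        if f.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        aa = _translate_cds(dna, gene_id)
        product_id = f"{gene_id}_prot"
        genes.append(GeneModel(gene_id=gene_id, contig=f.seqid, start=f.start,
                               end=f.end, strand=f.strand, product_id=product_id))
        proteins.append(ProteinRecord(id=product_id, seq=aa, description=f"product of {gene_id}"))
    return genes, proteins


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               contig_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for cid, ln in contig_lengths.items():
                fh.write(f"##sequence-region {cid} 1 {ln}\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tcdmine\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# physicochemistry
# ---------------------------------------------------------------------------

def _net_charge(seq: str, ph: float) -> float:
    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = pos(PKA_POSITIVE["Nterm"]) - neg(PKA_NEGATIVE["Cterm"])
    for aa in seq:
        if aa in ("K", "R", "H"):
            charge += pos(PKA_POSITIVE[aa])
        elif aa in ("D", "E", "C", "Y"):
            charge -= neg(PKA_NEGATIVE[aa])
    return charge


def compute_physchem(record: ProteinRecord) -> PhyschemSummary:
    """Average molecular mass and theoretical pI of a protein.

    Mass is the sum of average residue masses plus one water; pI is found by
    bisection on the Henderson-Hasselbalch net-charge curve using the pinned
    pKa table.  ``X`` residues are rejected: they have no mass.
    """
    if "X" in record.seq:
        raise SeqIOError(f"{record.id}: physchem undefined for sequences containing X")
    mw = sum(RESIDUE_MASS_DA[aa] for aa in record.seq) + WATER_MASS_DA
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if _net_charge(record.seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2.0
    return PhyschemSummary(mw_da=round(mw, 2), pi=round(pi, 2))
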