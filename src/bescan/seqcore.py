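"""Sequence primitives, coordinate conventions and file readers/writers.

Conventions used throughout the package:

* Genomic positions are 1-based inclusive (VCF convention).  Internal
  Python string offsets are 0-based half-open; every conversion between
  the two happens inside this module.
* Sequences are upper-cased on ingestion and restricted to the IUPAC
  DNA alphabet (ACGT, N and the degenerate two/three-base codes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    ContractError,
    CoordinateError,
    FormatError,
)

log = logging.getLogger(__name__)

# IUPAC degeneracy: code -> set of primary bases it stands for.
IUPAC_EXPANSION = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)

CANONICAL_CHROMS = {
    "human": {str(i) for i in range(1, 23)} | {"X", "Y", "M"},
    "mouse": {str(i) for i in range(1, 20)} | {"X", "Y", "M"},
}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix and map MT -> M."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "M" if c.upper() == "MT" else c


def validate_iupac(bases: str, name: str = "") -> str:
    """Upper-case *bases* and raise :class:`AlphabetError` on the first
    character outside the IUPAC DNA alphabet."""
    up = bases.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_EXPANSION:
            raise AlphabetError(ch, i, name)
    return up


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the IUPAC alphabet."""

    name: str
    bases: str

    def __post_init__(self):
        object.__setattr__(self, "bases", validate_iupac(self.bases, self.name))

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC DNA string.

    Degenerate codes are complemented by their standard pairing
    (R<->Y, K<->M, S/W self, B<->V, D<->H, N self).
    """
    seq = validate_iupac(seq)
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_match(pattern: str, text: str) -> bool:
    """True iff every *text* base is within the degeneracy set of the
    corresponding *pattern* base.

    A text N (or any degenerate text code) only matches pattern
    positions at least as degenerate: ambiguous reference bases are
    never reported as matching a concrete pattern base.
    """
    pattern = validate_iupac(pattern)
    text = validate_iupac(text)
    if len(pattern) != len(text):
        raise ContractError(
            f"pattern length {len(pattern)} != text length {len(text)}"
        )
    return all(
        IUPAC_EXPANSION[t] <= IUPAC_EXPANSION[p] for p, t in zip(pattern, text)
    )


class GenomeIndex:
    """In-memory multi-contig genome with 1-based inclusive lookups."""

    def __init__(self, contigs: Optional[dict[str, str]] = None,
                 canonical_only: bool = False, species: str = "mouse"):
        self.contigs: dict[str, str] = {}
        self.canonical_only = canonical_only
        self.species = species
        if contigs:
            for name, seq in contigs.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self.contigs:
            raise FormatError(f"duplicate contig name {name!r}")
        if self.canonical_only:
            if normalize_chrom(name) not in CANONICAL_CHROMS[self.species]:
                return
        self.contigs[name] = validate_iupac(seq, name)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __len__(self) -> int:
        return len(self.contigs)

    def contig_length(self, chrom: str) -> int:
        if chrom not in self.contigs:
            raise CoordinateError(chrom, 0, 0, "unknown contig")
        return len(self.contigs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases [start, end], 1-based inclusive."""
        n = self.contig_length(chrom)
        if start < 1 or end > n or start > end + 1:
            raise CoordinateError(chrom, start if start < 1 else end, n)
        return self.contigs[chrom][start - 1:end]

    def reverse_complemented(self) -> "GenomeIndex":
        """A copy with every contig reverse-complemented (for strand
        symmetry checks; position p maps to length - p + 1)."""
        out = GenomeIndex()
        for name, seq in self.contigs.items():
            out.add(name, reverse_complement(seq))
        return out


def fetch_context(genome: GenomeIndex, chrom: str, pos: int, flank: int) -> str:
    """Substring of length 2*flank+1 centred on *pos* (1-based)."""
    n = genome.contig_length(chrom)
    if pos - flank < 1 or pos + flank > n:
        raise CoordinateError(chrom, pos, n,
                              f"window +/-{flank} overflows contig")
    return genome.fetch(chrom, pos - flank, pos + flank)


def read_fasta(path, canonical_only: bool = False,
               species: str = "mouse") -> GenomeIndex:
    index = GenomeIndex(canonical_only=canonical_only, species=species)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        index.add(rec.id, str(rec.seq))
        n += 1
    if n == 0:
        log.warning("FASTA file %s contained no records", path)
    return index


def write_fasta(index: GenomeIndex, path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in index.contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


@dataclass(frozen=True)
class CdsModel:
    """Minimal coding-frame model: the strand the CDS is read on, the
    genomic position of any codon first base, and (optionally) the
    genomic interval covered by the frame."""

    strand: str  # '+' or '-'
    frame_anchor: int  # 1-based genomic position of a codon first base
    region: Optional[tuple[int, int]] = None  # inclusive genomic interval

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ContractError(f"CDS strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One single-nucleotide variant, 1-based, allele-explicit."""

    chrom: str
    pos: int
    ref: str
    alt: str
    significance: str = ""
    gene: str = ""
    cds: Optional[CdsModel] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ContractError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele.upper() not in "ACGT":
                raise ContractError(
                    f"SNV alleles must be single ACGT bases, got "
                    f"ref={self.ref!r} alt={self.alt!r}"
                )
        if self.ref.upper() == self.alt.upper():
            raise ContractError("ref and alt must differ")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


REQUIRED_TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "significance")


def _is_snv_allele(a: str) -> bool:
    return len(a) == 1 and a.upper() in "ACGT"


def read_variant_table(path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read a ClinVar-style TSV or a VCF into SNV records.

    Only single-base ref/alt rows are retained; multi-allelic VCF rows
    are split one record per alt; non-SNV alleles are dropped with a
    counted warning.
    """
    if dialect == "tsv":
        return _read_tsv_variants(path)
    if dialect == "vcf":
        return _read_vcf_variants(path)
    raise ContractError(f"unknown variant table dialect {dialect!r}")


def _read_tsv_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"variant table missing columns {missing}; found "
            f"{list(df.columns)}"
        )
    records: list[VariantRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        if not (_is_snv_allele(str(row.ref)) and _is_snv_allele(str(row.alt))):
            dropped += 1
            continue
        records.append(VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos),
            ref=str(row.ref), alt=str(row.alt),
            significance=str(row.significance),
            gene=str(getattr(row, "gene", "") or ""),
        ))
    if dropped:
        log.warning("dropped %d non-SNV rows from %s", dropped, path)
    return records


def _read_vcf_variants(path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    dropped = 0
    for v in VCF(str(path)):
        for alt in v.ALT:
            if _is_snv_allele(v.REF) and _is_snv_allele(alt):
                records.append(VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    significance=str(v.FILTER or "pathogenic"),
                ))
            else:
                dropped += 1
    if dropped:
        log.warning("dropped %d non-SNV alleles from %s", dropped, path)
    return records


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
         "significance": r.significance, "gene": r.gene}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_TSV_COLUMNS) + ["gene"]).to_csv(
        path, sep="\t", index=False
    )
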