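"""Readers, writers, and validation for the tables and sequence formats the
pipeline consumes.

Conventions
-----------
* Internal coordinates are 0-based half-open on the forward strand.  GFF3
  emission converts back to 1-based inclusive; BED6 stays 0-based half-open.
* Missing phenotype values are empty cells or ``NA``; missing alleles are
  ``N``.
* CSV dialect is fixed: comma-separated, UTF-8, ``.`` decimal separator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gff3",
    "write_bed6",
    "read_table",
    "load_table1",
    "TABLE_SCHEMAS",
    "ALLELE_SOURCE_COLUMNS",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTN")
ALLELE_CHARS = {"A", "C", "G", "T", "-", "N"}
MISSING_TOKENS = {"", "NA"}

#: allele-source columns of the multi-assembly matrix, in role order:
#: two G. hirsutum reference assemblies, the two BIL parents, the
#: G. barbadense parent's own assembly, and two further G. barbadense
#: reference assemblies.
ALLELE_SOURCE_COLUMNS = [
    "TM-1_NAU",
    "TM-1_JGI",
    "CCRI 36",
    "Hai 7124",
    "Hai 7124_ZJU",
    "Xinhai 21_NAU",
    "3-79_HAU",
]

#: required columns per table kind; extra columns are preserved.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "qtl": ["qtl_id", "trait", "chrom", "cM"],
    "marker_anchor": ["marker_id", "chrom", "cM", "bp"],
    "allele_matrix": ["gene_id", "site_id", *ALLELE_SOURCE_COLUMNS],
    "genotype": ["line_id"],
    "phenotype": ["line_id", "environment"],
    "expression": ["gene_id", "allele", "stage", "value"],
    "ct": ["sample", "gene", "ct"],
}


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an explicit molecule type."""

    id: str
    seq: str
    moltype: str = "protein"  # or "dna"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        for pos, residue in enumerate(self.seq):
            if residue not in alphabet:
                raise ValueError(
                    f"illegal {self.moltype} residue {residue!r} at position "
                    f"{pos} in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus in internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id!r} has an empty chrom")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased, line folding is joined, and input order is
    preserved.  Raises on an empty file, duplicate ids, or residues illegal
    for *moltype*.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper().strip(), moltype))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with *width*-column line wrapping."""
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def from_gff(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_gff(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file.

    Only rows whose feature type is ``gene`` are consumed; the full feature
    hierarchy is out of scope.  Coordinates are converted to the internal
    0-based half-open convention and the gene id is taken from the ``ID``
    attribute.  Errors carry the offending line number.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            start1, end1 = int(start_s), int(end_s)
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start ({start1}) > end ({end1})")
            attributes = _gff_attributes(attrs)
            if "ID" not in attributes:
                raise ValueError(f"{path}:{lineno}: gene row missing ID attribute")
            gene_id = attributes["ID"]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            start, end = from_gff(start1, end1)
            genes.append(GeneModel(gene_id, chrom, start, end, strand if strand in "+-" else "."))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "fiberfam") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = to_gff(g.start, g.end)
            handle.write(
                f"{g.chrom}\t{source}\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as handle:
        for chrom, start, end, name, score, strand in intervals:
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a CSV table of the given *kind*.

    Enforces the required-column schema for *kind*; extra columns are
    preserved.  Allele-matrix cells are restricted to ``{A,C,G,T,-,N}``
    (error names the offending cell); phenotype trait cells must be numeric
    or missing-coded (empty/``NA`` parse to NaN and are excluded from
    downstream pairwise computations).
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(TABLE_SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = TABLE_SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: {kind} table is missing required columns {missing}")

    if kind == "allele_matrix":
        for col in ALLELE_SOURCE_COLUMNS:
            bad = ~df[col].isin(ALLELE_CHARS)
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"{path}: non-allele character {df.loc[row, col]!r} in column "
                    f"{col!r}, row {row + 2}"
                )
    elif kind in {"qtl", "marker_anchor"}:
        numeric_cols = ["cM"] if kind == "qtl" else ["cM", "bp"]
        for col in numeric_cols:
            df[col] = pd.to_numeric(df[col])
    elif kind == "genotype":
        marker_cols = [c for c in df.columns if c != "line_id"]
        if not marker_cols:
            raise ValueError(f"{path}: genotype table has no marker columns")
        for col in marker_cols:
            values = df[col].where(~df[col].isin(MISSING_TOKENS))
            parsed = pd.to_numeric(values)
            if not parsed.dropna().isin([0, 1]).all():
                raise ValueError(f"{path}: genotype column {col!r} has values outside {{0,1}}")
            df[col] = parsed
    elif kind == "phenotype":
        for col in df.columns:
            if col in ("line_id", "environment"):
                continue
            df[col] = pd.to_numeric(df[col].where(~df[col].isin(MISSING_TOKENS)))
    elif kind == "expression":
        df["value"] = pd.to_numeric(df["value"])
    elif kind == "ct":
        df["ct"] = pd.to_numeric(df["ct"].where(~df["ct"].isin(MISSING_TOKENS)))
    return df


def load_table1() -> pd.DataFrame:
    """Load the packaged 27-site parental allele matrix fixture.

    The printed classification is kept in the extra ``snp_type`` column; it is
    not part of the ``allele_matrix`` input schema and is used only for
    cross-checks.
    """
    resource = importlib.resources.files("fiberfam").joinpath(
        "fixtures/table1_allele_matrix.csv"
    )
    with importlib.resources.as_file(resource) as path:
        return read_table(path, "allele_matrix")
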