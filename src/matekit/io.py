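"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything on disk is tab-separated UTF-8 with ``#`` comment lines and ``.``
as the decimal separator, FASTA for sequences, and Newick for trees.
Coordinates are 1-based inclusive throughout (GFF3 convention); any
half-open arithmetic is internal and converts at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violated the format contract (bad column count, bad value...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: chromosome, 1-based inclusive span, strand."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id!r}: start {self.start} < 1")
        if self.strand not in _STRANDS:
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HomologyHit:
    """One line of 12-column blast-tabular output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}/{self.subject_id}: evalue < 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain assignment (e.g. a Pfam envelope)."""

    protein_id: str
    domain_id: str
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise FormatError(
                f"domain hit {self.protein_id}/{self.domain_id}: "
                f"env_start {self.env_start} > env_end {self.env_end}"
            )


# ---------------------------------------------------------------------------
# chromosome ordering
# ---------------------------------------------------------------------------

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key putting 'Chr2' before 'Chr10' (digit runs compare numerically)."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in _NAT_SPLIT.split(name.strip())
        if part != ""
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file to ``[(id, SEQUENCE), ...]`` in file order.

    Sequences are uppercased with gaps and whitespace stripped. Duplicate
    identifiers and empty sequences are hard errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# blast tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLS = 12


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column blast-tabular TSV; ``#`` lines are skipped."""
    hits: list[HomologyHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST_COLS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.percent_identity,
                        h.alignment_length, h.mismatches, h.gap_opens,
                        h.q_start, h.q_end, h.s_start, h.s_end,
                        h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene tables (TSV or GFF3 gene lines)
# ---------------------------------------------------------------------------

_GENE_HEADER = ["gene_id", "chromosome", "start", "end", "strand"]
_GFF3_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _is_gff3(path: Path) -> bool:
    with open(path) as handle:
        for line in handle:
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) == 9
    return False


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene loci from a headered TSV or from GFF3 ``gene`` lines.

    Both dialects yield identical :class:`GeneModel` values; duplicate
    gene ids are a hard error.
    """
    path = Path(path)
    genes = _read_genes_gff3(path) if _is_gff3(path) else _read_genes_tsv(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _read_genes_tsv(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    header: list[str] | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != _GENE_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {_GENE_HEADER}, got {header}"
                    )
                continue
            if len(fields) != len(_GENE_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_GENE_HEADER)} columns, "
                    f"found {len(fields)}"
                )
            try:
                genes.append(
                    GeneModel(fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_genes_gff3(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            m = _GFF3_ID.search(fields[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: gene line without ID attribute")
            try:
                genes.append(
                    GeneModel(m.group(1), fields[0], int(fields[3]), int(fields[4]), fields[6])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_GENE_HEADER) + "\n")
        for g in genes:
            handle.write(f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# domain-hit tables
# ---------------------------------------------------------------------------

_DOMAIN_HEADER = ["protein_id", "domain_id", "env_start", "env_end"]


def read_domain_table(path: str | Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    header_seen = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _DOMAIN_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {_DOMAIN_HEADER}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            hits.append(DomainHit(fields[0], fields[1], int(fields[2]), int(fields[3])))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_DOMAIN_HEADER) + "\n")
        for h in hits:
            handle.write(f"{h.protein_id}\t{h.domain_id}\t{h.env_start}\t{h.env_end}\n")


# ---------------------------------------------------------------------------
# expression matrices (genes x tissues)
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes-by-tissues abundance matrix (FPKM-like, non-negative floats).

    First column holds gene ids (index), remaining columns are tissues.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in {path}: {dupes}")
    values = df.to_numpy()
    if (values < 0).any():
        raise FormatError(f"negative abundance values in {path}")
    return df.astype(float)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

_CT_COLS = ["gene", "genotype", "treatment", "timepoint", "replicate", "ct"]
_DILUTION_COLS = ["gene", "dilution_factor", "replicate", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _CT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing Ct-table columns {missing}")
    if (df["ct"] <= 0).any():
        raise FormatError(f"{path}: Ct values must be > 0")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dilution_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _DILUTION_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing dilution-table columns {missing}")
    if (df["dilution_factor"] <= 0).any():
        raise FormatError(f"{path}: dilution factors must be > 0")
    return df


# ---------------------------------------------------------------------------
# motif catalogs
# ---------------------------------------------------------------------------


def read_motif_catalog(path: str | Path) -> list[tuple[str, str]]:
    """Catalog TSV (name, consensus) -> ordered list; duplicate names error."""
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    header_seen = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen and fields[0].lower() == "name":
                header_seen = True
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>consensus")
            name, consensus = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate element name {name!r}")
            seen.add(name)
            entries.append((name, consensus))
    return entries
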