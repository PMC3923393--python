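"""Readers and writers for the formats the pipeline consumes and produces.

The pipeline never runs similarity searches, HMM scans or tree inference
itself; it consumes their standard outputs: protein FASTA, 12-column BLAST
tabular hit tables, domain-annotation TSVs (Pfam/SMART style) and Newick
gene trees with numeric internal-node supports.

FASTA headers carry optional metadata as ``key=value`` tokens after the
accession (``>ACC organism=Hsa gene=G1``); public databases disagree on
header conventions, so organism and gene attribution are explicit here and
fall back to a per-file default organism and to the accession respectively.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "SimilarityHit",
    "DomainHit",
    "MultipleAlignment",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "read_domain_table",
    "best_hits_per_pair",
]

#: Column order of the BLAST tabular ("outfmt 6") dialect consumed here.
BLAST_TABULAR_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with organism and gene attribution.

    ``gene_id`` groups alternative isoforms of the same gene; when a source
    database provides no gene attribution it equals the accession, making
    every record its own gene.
    """

    accession: str
    organism: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityHit:
    """A single HSP from a similarity search (query vs subject).

    The same (query, subject) pair may appear several times (multiple HSPs);
    consumers collapse to the minimum E-value per pair.
    """

    query: str
    subject: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query}/{self.subject}")


@dataclass(frozen=True)
class DomainHit:
    """A domain annotation on a protein; coordinates are 1-based inclusive."""

    protein: str
    domain: str
    evalue: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.protein}/{self.domain}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad coordinates {self.start}..{self.end} for {self.protein}"
            )


@dataclass
class MultipleAlignment:
    """A gapped multiple alignment; rows are (accession, gapped sequence)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)


def _parse_header(header: str, default_organism: str | None) -> tuple[str, str, str]:
    """Split a FASTA header into (accession, organism, gene_id)."""
    tokens = header.split()
    accession = tokens[0]
    meta: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key] = value
    organism = meta.get("organism", default_organism or "unknown")
    gene_id = meta.get("gene", accession)
    return accession, organism, gene_id


def read_fasta(
    path: str | Path,
    *,
    default_organism: str | None = None,
) -> list[ProteinRecord]:
    """Read protein FASTA into records, preserving entry order.

    Sequences are uppercased and a terminal ``*`` (stop) is stripped.
    An empty file yields an empty list with a warning; a duplicate
    accession is an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, organism, gene_id = _parse_header(entry.description, default_organism)
        if accession in seen:
            raise ValueError(f"duplicate accession in {path}: {accession}")
        seen.add(accession)
        seq = str(entry.seq).upper().rstrip("*")
        records.append(ProteinRecord(accession, organism, gene_id, seq))
    if not records:
        warnings.warn(f"no FASTA entries in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA with key=value metadata."""
    seq_records = []
    for rec in records:
        description = f"organism={rec.organism} gene={rec.gene_id}"
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.accession, description=description)
        )
    buf = _io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(seq_records)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    """Read a 12-column tab-separated BLAST tabular file.

    Lines starting with ``#`` are ignored. Only qseqid, sseqid, evalue and
    bitscore are retained.
    """
    hits: list[SimilarityHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_TABULAR_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(BLAST_TABULAR_COLUMNS)} "
                    f"tab-separated columns, found {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable evalue/bitscore") from exc
            hits.append(SimilarityHit(fields[0], fields[1], evalue, bitscore))
    return hits


def write_hit_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (unused columns zeroed)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def best_hits_per_pair(hits: Iterable[SimilarityHit]) -> dict[tuple[str, str], float]:
    """Collapse HSPs to the minimum E-value per (query, subject) pair."""
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.query, h.subject)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    return best


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read a domain-annotation TSV: protein, domain, evalue, start, end."""
    out: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            protein, domain, evalue, start, end = fields
            try:
                hit = DomainHit(protein, domain, float(evalue), int(start), int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(hit)
    return out


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(f"{h.protein}\t{h.domain}\t{h.evalue:.3g}\t{h.start}\t{h.end}\n")
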