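"""Reading and writing of FASTA/GFF3 inputs and the optional taxonomy table.

All coordinates are normalized to a single internal convention: 0-based,
half-open ``[start, end)``.  GFF3's 1-based inclusive spans are converted on
read.  Both FASTA and GFF3 may be plain text or gzip-compressed; compression
is detected from the file's magic bytes, not its name.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Replicons shorter than this are too noisy to model faithfully.
DEFAULT_MIN_LENGTH = 100_000

#: Placeholder used when an accession has no taxonomy entry.
UNKNOWN_TAXON = ("unknown",) * 5

# GFF3 feature types that carry codon phase; "protein-coding gene" for all
# downstream bookkeeping means CDS.
_CODING_FEATURE_TYPES = frozenset({"CDS"})


@dataclass
class SequenceRecord:
    """One FASTA record with its header split into accession and description."""

    accession: str
    description: str
    residues: str
    is_plasmid: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.accession!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneAnnotation:
    """A protein-coding feature in internal 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: int
    feature_type: str = "CDS"
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for {self.seq_id}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    def __len__(self) -> int:
        return self.end - self.start


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_plasmid(description: str) -> bool:
    return "plasmid" in description.lower()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Residues are upper-cased; records are returned in file order.  A record
    with an empty sequence raises :class:`ValueError` naming the record.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = str(rec.seq).upper()
            if not residues:
                raise ValueError(f"zero-length sequence for record {rec.id!r}")
            description = rec.description[len(rec.id) :].strip()
            records.append(
                SequenceRecord(
                    accession=rec.id,
                    description=description,
                    residues=residues,
                    is_plasmid=_is_plasmid(rec.description),
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to a plain-text FASTA file (round-trips with read_fasta)."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def _parse_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in column.split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read protein-coding (CDS) features from a (possibly gzipped) GFF3 file.

    Coordinates are converted from GFF3's 1-based inclusive spans to 0-based
    half-open.  The gene symbol is taken from the ``gene=`` or ``Name=``
    attribute when present.
    """
    genes: list[GeneAnnotation] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            columns = line.split("\t")
            if len(columns) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(columns)}"
                )
            seq_id, _source, ftype, start, end, _score, strand, _phase, attrs = columns
            if ftype not in _CODING_FEATURE_TYPES:
                continue
            if strand not in ("+", "-"):
                logger.warning(
                    "%s: line %d: CDS without strand, skipped", path, lineno
                )
                continue
            attributes = _parse_attributes(attrs)
            name = attributes.get("gene", attributes.get("Name", ""))
            genes.append(
                GeneAnnotation(
                    seq_id=seq_id,
                    start=int(start) - 1,
                    end=int(end),
                    strand=1 if strand == "+" else -1,
                    feature_type=ftype,
                    name=name,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write annotations as GFF3 (round-trips with read_gff3)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, g in enumerate(genes, start=1):
            attrs = f"ID=cds{i}"
            if g.name:
                attrs += f";gene={g.name}"
            handle.write(
                "\t".join(
                    [
                        g.seq_id,
                        "repliskew",
                        g.feature_type,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        "+" if g.strand == 1 else "-",
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def filter_min_length(
    records: list[SequenceRecord], threshold: int = DEFAULT_MIN_LENGTH
) -> list[SequenceRecord]:
    """Keep only records of at least ``threshold`` nucleotides, preserving order."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = [r for r in records if len(r) >= threshold]
    for r in records:
        if len(r) < threshold:
            logger.warning(
                "ignoring %s: %d nt < minimum %d", r.accession, len(r), threshold
            )
    return kept


def load_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Load an ``accession<TAB>realm1..realm5`` mapping.

    Malformed lines are skipped with a warning; on duplicate accessions the
    last entry wins.  Use ``mapping.get(acc, UNKNOWN_TAXON)`` for lookups.
    """
    mapping: dict[str, tuple[str, ...]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                logger.warning(
                    "%s: line %d: expected 6 tab-separated fields, got %d; skipped",
                    path,
                    lineno,
                    len(fields),
                )
                continue
            accession = fields[0]
            if accession in mapping:
                logger.warning(
                    "%s: line %d: duplicate accession %s, last entry wins",
                    path,
                    lineno,
                    accession,
                )
            mapping[accession] = tuple(fields[1:6])
    return mapping
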