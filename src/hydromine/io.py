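"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing goes through Biopython; GFF3 goes through gffutils.  BLAST
tabular (outfmt 6/7) is a fixed 12-column dialect, parsed directly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AnnotationTable,
    FormatError,
    GeneFeature,
    GenomeFeatures,
    ProteinRecord,
    validate_sequence,
)

logger = logging.getLogger(__name__)

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA file into (header, sequence) pairs.

    Sequences are uppercased, whitespace stripped, record order preserved.
    Raises :class:`FormatError` on empty sequences or residues outside the
    20-letter alphabet plus X.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        seq = str(rec.seq).replace(" ", "").replace("\t", "")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {header!r}")
        records.append((header, validate_sequence(seq, context=header)))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write (header, sequence) pairs as FASTA with fixed line wrapping."""
    seqrecords = []
    for header, seq in records:
        ident = header.split()[0]
        desc = header[len(ident):].strip()
        seqrecords.append(SeqRecord(Seq(seq), id=ident, description=desc))
    writer_path = Path(path)
    with writer_path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_proteome(path: str | Path, genome_id: str = "") -> list[ProteinRecord]:
    """Read a proteome FASTA into ProteinRecords.

    The first whitespace-separated header token is used as both protein_id
    and locus_tag; the remainder (if any) becomes the product string.
    """
    records = []
    seen: set[str] = set()
    for header, seq in read_fasta(path):
        ident = header.split()[0]
        if ident in seen:
            raise FormatError(f"{path}: duplicate locus_tag {ident!r}")
        seen.add(ident)
        product = header[len(ident):].strip()
        records.append(
            ProteinRecord(
                protein_id=ident,
                locus_tag=ident,
                sequence=seq,
                genome_id=genome_id,
                product=product,
            )
        )
    return records


def read_features(
    path: str | Path,
    proteome: Sequence[ProteinRecord],
    genome_id: str = "",
) -> GenomeFeatures:
    """Read CDS features from a GFF3 file and join them to a proteome.

    Returns per-contig gene lists sorted by start coordinate.  A locus_tag
    present in the GFF but absent from the proteome is retained without a
    sequence (with a warning); a duplicated locus_tag is an error.
    """
    by_tag = {rec.locus_tag: rec for rec in proteome}
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    contigs: dict[str, list[GeneFeature]] = {}
    for feat in db.features_of_type("CDS"):
        tags = feat.attributes.get("locus_tag")
        if not tags:
            raise FormatError(f"{path}: CDS at {feat.seqid}:{feat.start} lacks locus_tag")
        tag = tags[0]
        record = by_tag.get(tag)
        if record is None:
            logger.warning("%s: locus_tag %s not found in proteome", path, tag)
        else:
            record.contig_id = feat.seqid
            record.start = feat.start
            record.end = feat.end
            record.strand = feat.strand
        product = (feat.attributes.get("product") or [""])[0]
        if record is not None and not record.product:
            record.product = product
        contigs.setdefault(feat.seqid, []).append(
            GeneFeature(
                locus_tag=tag,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=product or (record.product if record else ""),
                record=record,
            )
        )
    return GenomeFeatures(genome_id=genome_id or Path(path).stem, contigs=contigs)


@dataclass
class BlastRow:
    """One row of BLAST tabular output (outfmt 6/7)."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def read_blast_tab(path: str | Path) -> list[BlastRow]:
    """Parse BLAST tabular output; '#' comment lines (outfmt 7) are skipped."""
    rows: list[BlastRow] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    BlastRow(
                        qseqid=parts[0],
                        sseqid=parts[1],
                        pident=float(parts[2]),
                        length=int(parts[3]),
                        mismatch=int(parts[4]),
                        gapopen=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_blast_tab(path: str | Path, rows: Iterable[BlastRow]) -> None:
    """Write rows in the 12-column tabular dialect.

    Floats are written in shortest round-trip form so that a parse of the
    written file reproduces every numeric field bit-exactly.
    """
    with Path(path).open("w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.qseqid,
                        r.sseqid,
                        str(r.pident),
                        str(r.length),
                        str(r.mismatch),
                        str(r.gapopen),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        str(r.evalue),
                        str(r.bitscore),
                    ]
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a 3-column TSV (locus_tag, source, domain_label)."""
    table = AnnotationTable()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            table.add(*parts)
    return table


def write_annotations(path: str | Path, table: AnnotationTable) -> None:
    with Path(path).open("w") as fh:
        for locus in table.entries:
            for source, label in table.entries[locus]:
                fh.write(f"{locus}\t{source}\t{label}\n")


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a TSV report with a header row."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(["" if v is None else v for v in row])
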