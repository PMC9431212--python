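"""Query-vs-reference alignment: search, best-first sorting, hit selection.

Hits can come from the internal Smith-Waterman engine or be ingested from
BLAST tabular output (outfmt 6/7); downstream behavior is identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import align as _align
from .core import HydClass, ProteinRecord
from .io import BlastRow
from .reference import ClassThresholdTable, ReferenceCatalog

logger = logging.getLogger(__name__)

#: Reporting floor of the internal engine (expect-value), matching the
#: default reporting behavior of protein-protein BLAST.
DEFAULT_E_FLOOR = 10.0

#: Hit-selection expect-value cutoff (inclusive).
DEFAULT_E_MAX = 0.01


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-reference alignment result."""

    query_id: str
    subject_id: str
    subject_class: HydClass
    percent_identity: float
    e_value: float
    alignment_length: int
    query_length: int
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent_identity {self.percent_identity} out of [0,100]")
        if self.e_value < 0:
            raise ValueError("negative e_value")
        if self.alignment_length < 1:
            raise ValueError("alignment_length < 1")


def search(
    proteome: Sequence[ProteinRecord],
    catalog: ReferenceCatalog,
    e_floor: float = DEFAULT_E_FLOOR,
) -> dict[str, list[AlignmentHit]]:
    """Align every query against every reference entry.

    Returns hits grouped by query locus_tag, each list sorted best-first
    (see :func:`sort_hits`).  The expect value uses the query length and
    the total residue count of the catalog as the search space.
    """
    if not catalog.entries:
        raise ValueError("reference catalog is empty")
    space = catalog.total_residues
    results: dict[str, list[AlignmentHit]] = {}
    for record in proteome:
        hits: list[AlignmentHit] = []
        for entry in catalog.entries:
            aln = _align.align_local(record.sequence, entry.sequence)
            if aln is None:
                continue
            e = _align.evalue(aln.score, len(record.sequence), space)
            if e > e_floor:
                continue
            hits.append(
                AlignmentHit(
                    query_id=record.locus_tag,
                    subject_id=entry.entry_id,
                    subject_class=entry.hyd_class,
                    percent_identity=aln.percent_identity,
                    e_value=e,
                    alignment_length=aln.length,
                    query_length=len(record.sequence),
                    bitscore=_align.bitscore(aln.score),
                )
            )
        if hits:
            results[record.locus_tag] = sort_hits(hits)
    return results


def hits_from_blast(
    rows: Iterable[BlastRow],
    catalog: ReferenceCatalog,
    proteome: Sequence[ProteinRecord],
) -> dict[str, list[AlignmentHit]]:
    """Convert ingested BLAST tabular rows into grouped, sorted hits.

    Subject class labels are resolved against the reference catalog and
    query lengths against the proteome; rows whose subject is not in the
    catalog are dropped with a warning.
    """
    lengths = {rec.locus_tag: len(rec.sequence) for rec in proteome}
    grouped: dict[str, list[AlignmentHit]] = {}
    for row in rows:
        if row.sseqid not in catalog.by_id:
            logger.warning("blast subject %s not in reference catalog; dropped", row.sseqid)
            continue
        qlen = lengths.get(row.qseqid, row.qend)
        grouped.setdefault(row.qseqid, []).append(
            AlignmentHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                subject_class=catalog.class_of(row.sseqid),
                percent_identity=row.pident,
                e_value=row.evalue,
                alignment_length=row.length,
                query_length=qlen,
                bitscore=row.bitscore,
            )
        )
    return {q: sort_hits(hits) for q, hits in grouped.items()}


def hits_to_blast_rows(hits: Iterable[AlignmentHit]) -> list[BlastRow]:
    """Serialize hits in the 12-column tabular dialect.

    Coordinate columns not tracked by the internal engine (qstart/qend,
    sstart/send, mismatch/gapopen) are filled with whole-sequence spans
    and zeros; identity, length, e-value and bitscore are authoritative.
    """
    rows = []
    for h in hits:
        rows.append(
            BlastRow(
                qseqid=h.query_id,
                sseqid=h.subject_id,
                pident=h.percent_identity,
                length=h.alignment_length,
                mismatch=0,
                gapopen=0,
                qstart=1,
                qend=h.query_length,
                sstart=1,
                send=h.alignment_length,
                evalue=h.e_value,
                bitscore=h.bitscore,
            )
        )
    return rows


def sort_hits(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Best-first stable sort of hits.

    Priority order: percent identity (descending), expect value
    (ascending — lower is better), query length (descending), then
    subject id (ascending) as a determinism tie-break.
    """
    return sorted(
        hits,
        key=lambda h: (-h.percent_identity, h.e_value, -h.query_length, h.subject_id),
    )


def filter_hits(
    sorted_hits: Sequence[AlignmentHit],
    thresholds: ClassThresholdTable,
    e_max: float = DEFAULT_E_MAX,
) -> list[AlignmentHit]:
    """Hit selection: keep hits with E <= e_max (inclusive) and identity
    strictly greater than the subject class's minimum-identity threshold.
    Input order is preserved."""
    return [
        h
        for h in sorted_hits
        if h.e_value <= e_max
        and h.percent_identity > thresholds.threshold_for(h.subject_class)
    ]
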