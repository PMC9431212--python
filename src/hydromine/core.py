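"""Core domain types shared across the pipeline.

The classification scheme follows the HydDB convention: hydrogenases are
split by active-site metal ([NiFe] vs [FeFe]) into groups (NiFe 1-4;
FeFe A-C) and, where phylogeny supports it, subgroups (1a, 4f, A3, A4,
C2, ...).  A class label like ``[FeFe] Group A3`` therefore carries up to
three levels of information; voting and threshold lookup operate on the
canonical rendering produced by :meth:`HydClass.label`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue codes accepted in input sequences ('X' = unknown; it never
#: satisfies a motif position, including the wildcard).
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

METAL_TYPES = ("NiFe", "FeFe")


class FormatError(ValueError):
    """Malformed input file (FASTA / GFF3 / tabular)."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (templates, profiles, catalogs)."""


@dataclass(frozen=True, order=True)
class HydClass:
    """A hydrogenase functional class: metal type, group, optional subgroup."""

    metal_type: str
    group: str
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.metal_type not in METAL_TYPES:
            raise ValueError(f"unknown metal type {self.metal_type!r}")
        if self.subgroup is not None and not self.subgroup.startswith(self.group):
            raise ValueError(
                f"subgroup {self.subgroup!r} inconsistent with group {self.group!r}"
            )

    @classmethod
    def parse(cls, metal_type: str, token: str) -> "HydClass":
        """Parse a class token such as ``1a``, ``4f``, ``A3``, or ``B``.

        The leading character is the group; any remainder makes the token a
        subgroup of that group.
        """
        token = token.strip()
        if not token:
            raise ValueError("empty class token")
        group = token[0].upper() if token[0].isalpha() else token[0]
        subgroup = token if len(token) > 1 else None
        return cls(metal_type=metal_type, group=group, subgroup=subgroup)

    @property
    def token(self) -> str:
        """Shortest unambiguous token (subgroup if known, else group)."""
        return self.subgroup if self.subgroup is not None else self.group

    @property
    def label(self) -> str:
        """Canonical rendering, e.g. ``[FeFe] Group A3``."""
        return f"[{self.metal_type}] Group {self.token}"

    def at_group_level(self) -> "HydClass":
        """The same class with subgroup information dropped."""
        if self.subgroup is None:
            return self
        return HydClass(self.metal_type, self.group)


def validate_sequence(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and validate an amino-acid sequence; raise on bad residues."""
    seq = sequence.upper()
    if not seq:
        raise FormatError(f"{context}: empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise FormatError(f"{context}: invalid residue code(s) {sorted(bad)}")
    return seq


@dataclass
class ProteinRecord:
    """A protein-coding gene product with its genomic context.

    Coordinates are 1-based inclusive on the nucleotide sequence of
    ``contig_id``, matching GFF3 conventions.
    """

    protein_id: str
    locus_tag: str
    sequence: str
    genome_id: str = ""
    contig_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.sequence:
            self.sequence = validate_sequence(self.sequence, context=self.locus_tag)
        if self.start and self.end and self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")


@dataclass
class GeneFeature:
    """One CDS feature from a GFF3 file, joined (when possible) to its protein."""

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    record: ProteinRecord | None = None

    @property
    def sequence(self) -> str | None:
        return self.record.sequence if self.record is not None else None


@dataclass
class GenomeFeatures:
    """Per-contig, start-sorted gene lists for one genome."""

    genome_id: str
    contigs: dict[str, list[GeneFeature]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[str, int]] = {}
        self.reindex()

    def reindex(self) -> None:
        self._index.clear()
        for contig, genes in self.contigs.items():
            genes.sort(key=lambda g: (g.start, g.end, g.locus_tag))
            for i, gene in enumerate(genes):
                if gene.locus_tag in self._index:
                    raise FormatError(
                        f"duplicate locus_tag {gene.locus_tag!r} in {self.genome_id}"
                    )
                self._index[gene.locus_tag] = (contig, i)

    def locate(self, locus_tag: str) -> tuple[str, int]:
        """Return (contig_id, positional index) of a locus."""
        return self._index[locus_tag]

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._index

    def gene(self, locus_tag: str) -> GeneFeature:
        contig, i = self.locate(locus_tag)
        return self.contigs[contig][i]


@dataclass
class AnnotationTable:
    """Local per-locus domain annotations (a stand-in for InterPro/CDD lookups).

    Maps locus_tag -> list of (source, domain_label) pairs.
    """

    entries: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def labels_for(self, locus_tag: str) -> list[str]:
        return [label for _, label in self.entries.get(locus_tag, [])]

    def add(self, locus_tag: str, source: str, label: str) -> None:
        self.entries.setdefault(locus_tag, []).append((source, label))
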