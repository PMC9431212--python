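"""Class-labeled reference catalog and class-specific identity thresholds.

The hit-selection stage retains an alignment only if its identity to the
query exceeds the *minimum* of the within-class pairwise-identity
distribution of the subject's class — classes differ widely in internal
diversity, so a single global identity cutoff would over- or
under-collect depending on the class.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from . import io as hio
from .align import pairwise_identity
from .core import FormatError, HydClass

logger = logging.getLogger(__name__)

#: Identity floor applied to classes whose threshold cannot be estimated
#: (fewer than two reference entries): a conservative twilight-zone floor.
DEFAULT_FALLBACK_THRESHOLD = 25.0

DEFAULT_MAX_PAIRS_PER_CLASS = 5000


@dataclass
class ReferenceEntry:
    """A curated catalytic-subunit sequence with its class label.

    For [FeFe] entries the sequence is, by source-database convention,
    the H-domain only; for [NiFe] entries it is the full large subunit.
    """

    entry_id: str
    sequence: str
    hyd_class: HydClass


def parse_reference_header(header: str) -> tuple[str, HydClass]:
    """Parse the default ``id|type|class`` header dialect.

    Example: ``WP_010890826.1|FeFe|A4`` -> ("WP_010890826.1",
    [FeFe] Group A4).  Pass a different parser to
    :func:`load_reference` for other dialects.
    """
    parts = header.split()[0].split("|")
    if len(parts) != 3:
        raise FormatError(f"reference header {header!r} not in id|type|class form")
    entry_id, metal, token = parts
    try:
        return entry_id, HydClass.parse(metal, token)
    except ValueError as exc:
        raise FormatError(f"reference header {header!r}: {exc}") from exc


@dataclass
class ReferenceCatalog:
    """Reference entries indexed by canonical class label and by entry id."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.by_class: dict[str, list[ReferenceEntry]] = {}
        self.by_id: dict[str, ReferenceEntry] = {}
        for entry in self.entries:
            self.by_class.setdefault(entry.hyd_class.label, []).append(entry)
            self.by_id[entry.entry_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def class_of(self, entry_id: str) -> HydClass:
        return self.by_id[entry_id].hyd_class

    @property
    def total_residues(self) -> int:
        return sum(len(e.sequence) for e in self.entries)

    def class_counts(self) -> dict[str, int]:
        return {label: len(v) for label, v in sorted(self.by_class.items())}


def load_reference(
    path: str | Path,
    header_parser: Callable[[str], tuple[str, HydClass]] = parse_reference_header,
) -> ReferenceCatalog:
    """Load a class-tagged reference FASTA into a catalog."""
    records = hio.read_fasta(path)
    if not records:
        logger.warning("%s: empty reference catalog", path)
    entries = []
    bad: list[str] = []
    for header, seq in records:
        try:
            entry_id, hyd_class = header_parser(header)
        except FormatError:
            bad.append(header)
            continue
        entries.append(ReferenceEntry(entry_id=entry_id, sequence=seq, hyd_class=hyd_class))
    if bad:
        raise FormatError(f"{path}: unparseable class tag in headers: {bad}")
    catalog = ReferenceCatalog(entries=entries)
    logger.info("loaded %d reference entries: %s", len(catalog), catalog.class_counts())
    return catalog


@dataclass
class ClassThresholdTable:
    """Minimum within-class identity per class, with sampling provenance."""

    thresholds: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, tuple[int, str]] = field(default_factory=dict)  # label -> (n_pairs, mode)
    fallback: float = DEFAULT_FALLBACK_THRESHOLD

    def threshold_for(self, hyd_class: HydClass) -> float:
        return self.thresholds.get(hyd_class.label, self.fallback)

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            (label, str(self.thresholds[label]), *map(str, self.provenance[label]))
            for label in sorted(self.thresholds)
        ]
        hio.write_tsv(path, ["class", "min_identity", "n_pairs", "mode"], rows)

    @classmethod
    def read_tsv(cls, path: str | Path, fallback: float = DEFAULT_FALLBACK_THRESHOLD) -> "ClassThresholdTable":
        table = cls(fallback=fallback)
        with Path(path).open() as fh:
            next(fh)  # header
            for line in fh:
                label, value, n_pairs, mode = line.rstrip("\n").split("\t")
                table.thresholds[label] = float(value)
                table.provenance[label] = (int(n_pairs), mode)
        return table


def _pair_from_index(idx: int, n: int) -> tuple[int, int]:
    """Decode a flat index in [0, n(n-1)/2) into an (i, j) pair, i<j."""
    i = 0
    remaining = idx
    row = n - 1
    while remaining >= row:
        remaining -= row
        i += 1
        row -= 1
    return i, i + 1 + remaining


def class_min_identity_thresholds(
    catalog: ReferenceCatalog,
    max_pairs_per_class: int = DEFAULT_MAX_PAIRS_PER_CLASS,
    seed: int = 0,
    fallback: float = DEFAULT_FALLBACK_THRESHOLD,
) -> ClassThresholdTable:
    """Per-class minimum of the within-class pairwise-identity distribution.

    All pairs are enumerated when a class has at most ``max_pairs_per_class``
    of them; larger classes use a seeded uniform subsample (the exact
    minimum is guaranteed only under full enumeration, hence the mode tag
    in the provenance).  Classes with a single entry fall back to the
    configured floor.
    """
    table = ClassThresholdTable(fallback=fallback)
    for label in sorted(catalog.by_class):
        entries = catalog.by_class[label]
        n = len(entries)
        n_total_pairs = n * (n - 1) // 2
        if n < 2:
            logger.info("class %s has %d entry; using fallback %.1f", label, n, fallback)
            continue
        if n_total_pairs <= max_pairs_per_class:
            pairs = itertools.combinations(range(n), 2)
            n_used, mode = n_total_pairs, "full"
        else:
            rng = random.Random(seed)
            idxs = rng.sample(range(n_total_pairs), max_pairs_per_class)
            pairs = (_pair_from_index(ix, n) for ix in sorted(idxs))
            n_used, mode = max_pairs_per_class, "sampled"
        minimum = min(
            pairwise_identity(entries[i].sequence, entries[j].sequence) for i, j in pairs
        )
        table.thresholds[label] = minimum
        table.provenance[label] = (n_used, mode)
    return table
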