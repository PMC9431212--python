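"""Validation of classified catalytic subunits and complex reconstruction.

An [FeFe] call is validated on the catalytic sequence alone: the
H-cluster metal-binding motifs (P1, P2, P3) must be present (all three by
default — a candidate carrying only two of the three is rejected).  A
[NiFe] call must additionally have a small-subunit gene in its
neighborhood: a flanking gene annotated as a [NiFe]-hydrogenase small
subunit *and* carrying at least one small-subunit Fe-S ligand motif.

Beyond the validation verdict, flanking genes are matched against a
class-specific subunit template (the subunit composition known for the
class) and diaphorase subunits of bifurcating [FeFe]-hydrogenases are
profiled for the NuoF-like Gly-rich loop and the Rossmann first-loop
variant that tracks NAD vs NADP specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import ClassAssignment
from .core import AnnotationTable, ConfigurationError, GeneFeature, GenomeFeatures, ProteinRecord
from .motifs import MotifCatalog, MotifMatch

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 5

#: Annotation keywords recognizing a [NiFe]-hydrogenase small subunit
#: (checked as case-insensitive substrings of domain labels / products).
SMALL_SUBUNIT_KEYWORDS = ("small subunit", "nife hydrogenase small", "ipr027394")

#: Annotation keywords recognizing a NuoF-like diaphorase subunit.
NUOF_KEYWORDS = ("nuof", "cog1894", "cl34375")


@dataclass
class GeneNeighborhood:
    """Genes flanking an anchor locus, with signed gene offsets."""

    anchor: GeneFeature
    flanking: list[tuple[GeneFeature, int]] = field(default_factory=list)
    window_size: int = DEFAULT_WINDOW_SIZE

    def nearest_first(self) -> list[tuple[GeneFeature, int]]:
        """Flanking genes ordered by |offset| (upstream before downstream on ties)."""
        return sorted(self.flanking, key=lambda t: (abs(t[1]), t[1]))


@dataclass(frozen=True)
class SubunitRole:
    name: str
    required: bool = True
    keywords: tuple[str, ...] = ()
    catalytic: bool = False


@dataclass(frozen=True)
class SubunitTemplate:
    """Expected subunit composition for a hydrogenase class."""

    class_token: str
    roles: tuple[SubunitRole, ...]

    def __post_init__(self) -> None:
        if sum(1 for r in self.roles if r.catalytic) != 1:
            raise ConfigurationError(
                f"template {self.class_token}: exactly one catalytic role required"
            )


#: Default class templates (subunit composition as catalogued for each
#: class): 1a = large + small (+ optional cytochrome); B = monomeric;
#: A3 = trimeric bifurcating (catalytic + diaphorase + thioredoxin-like);
#: A4 = hexameric formate-dehydrogenase-linked Hyt complex.
DEFAULT_TEMPLATES: dict[str, SubunitTemplate] = {
    "1a": SubunitTemplate(
        "1a",
        (
            SubunitRole("large_subunit", catalytic=True),
            SubunitRole("small_subunit", required=True, keywords=SMALL_SUBUNIT_KEYWORDS),
            SubunitRole("cytochrome", required=False, keywords=("cytochrome",)),
        ),
    ),
    "B": SubunitTemplate("B", (SubunitRole("catalytic", catalytic=True),)),
    "A3": SubunitTemplate(
        "A3",
        (
            SubunitRole("catalytic", catalytic=True),
            SubunitRole("diaphorase", required=True, keywords=NUOF_KEYWORDS + ("flavoprotein", "cofactor-binding")),
            SubunitRole("thioredoxin", required=True, keywords=("thioredoxin",)),
        ),
    ),
    "A4": SubunitTemplate(
        "A4",
        (
            SubunitRole("catalytic_HytA", catalytic=True),
            SubunitRole("diaphorase_HytB", required=True, keywords=NUOF_KEYWORDS + ("flavoprotein", "cofactor-binding")),
            SubunitRole("fes_HytC", required=True, keywords=("iron-sulfur", "fe-s", "4fe-4s")),
            SubunitRole("fes_HytD", required=True, keywords=("iron-sulfur", "fe-s", "4fe-4s")),
            SubunitRole("fes_HytE1", required=True, keywords=("iron-sulfur", "fe-s", "4fe-4s")),
            SubunitRole("fes_HytE2", required=True, keywords=("iron-sulfur", "fe-s", "4fe-4s")),
        ),
    ),
}


@dataclass
class DiaphoraseProfile:
    """Cofactor-loop profile of a NuoF-like diaphorase subunit."""

    locus_tag: str
    nterm_loop: str  # A4-type | A3-type | absent
    rossmann_loop: str  # G-type | A-type | absent
    cofactor_hypothesis: str  # NADP-associated | NAD-associated | undetermined


@dataclass
class HydrogenaseCall:
    """A candidate catalytic subunit with verdict and evidence."""

    anchor: ProteinRecord
    assignment: ClassAssignment
    validation_status: str = "candidate"  # validated | validated_with_warnings | rejected
    motif_evidence: dict[str, list[MotifMatch]] = field(default_factory=dict)
    small_subunit_locus: str | None = None
    tat_signal: bool | None = None
    role_map: dict[str, str] = field(default_factory=dict)  # role name -> locus_tag
    warnings: list[str] = field(default_factory=list)
    diaphorase: DiaphoraseProfile | None = None


def neighborhood(
    anchor_locus: str,
    features: GenomeFeatures,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> GeneNeighborhood:
    """Up to ``window_size`` genes on each side of the anchor, same contig.

    Contig edges truncate the window; offsets are signed gene counts in
    genomic (start-sorted) order.
    """
    contig, idx = features.locate(anchor_locus)
    genes = features.contigs[contig]
    flanking = [
        (genes[i], i - idx)
        for i in range(max(0, idx - window_size), min(len(genes), idx + window_size + 1))
        if i != idx
    ]
    return GeneNeighborhood(anchor=genes[idx], flanking=flanking, window_size=window_size)


def _labels(gene: GeneFeature, annotations: AnnotationTable) -> list[str]:
    labels = annotations.labels_for(gene.locus_tag)
    if gene.product:
        labels.append(gene.product)
    return [s.lower() for s in labels]


def _matches_keywords(gene: GeneFeature, annotations: AnnotationTable, keywords: tuple[str, ...]) -> bool:
    labels = _labels(gene, annotations)
    return any(kw.lower() in label for kw in keywords for label in labels)


def validate_fefe(
    call: HydrogenaseCall,
    catalog: MotifCatalog,
    mode: str = "all_three",
) -> HydrogenaseCall:
    """Validate an [FeFe] call from its H-cluster motif content.

    ``all_three`` requires at least one match in each of the P1, P2 and
    P3 slots; ``any_one`` accepts any single slot (sensitivity mode).
    """
    if call.assignment.predicted_class.metal_type != "FeFe":
        raise ValueError("validate_fefe requires an FeFe assignment")
    if mode not in ("all_three", "any_one"):
        raise ValueError(f"unknown FeFe validation mode {mode!r}")
    seq = call.anchor.sequence
    slots = {}
    for slot in ("h_cluster_p1", "h_cluster_p2", "h_cluster_p3"):
        slots[slot] = catalog.scan_role(seq, slot)
    call.motif_evidence.update(slots)
    present = [bool(v) for v in slots.values()]
    ok = all(present) if mode == "all_three" else any(present)
    call.validation_status = "validated" if ok else "rejected"
    if not ok:
        missing = [s for s, v in slots.items() if not v]
        call.warnings.append(f"missing H-cluster motif slot(s): {', '.join(missing)}")
    return call


def find_small_subunit(
    nbhd: GeneNeighborhood,
    annotations: AnnotationTable,
    catalog: MotifCatalog,
    keywords: tuple[str, ...] = SMALL_SUBUNIT_KEYWORDS,
) -> str | None:
    """First flanking gene (nearest-first) that is annotated as a [NiFe]
    small subunit AND carries at least one small-subunit Fe-S ligand motif."""
    for gene, _offset in nbhd.nearest_first():
        if gene.sequence is None:
            continue
        if not _matches_keywords(gene, annotations, keywords):
            continue
        if catalog.scan_role(gene.sequence, "nife_small_fes"):
            return gene.locus_tag
    return None


def check_tat_signal(
    small_subunit: ProteinRecord,
    catalog: MotifCatalog,
) -> tuple[bool, list[MotifMatch]]:
    """Twin-arginine (R-R-x-F-x-K) export signal in the N-terminal window."""
    matches = catalog.scan_role(small_subunit.sequence, "tat")
    return bool(matches), matches


def validate_nife(
    call: HydrogenaseCall,
    nbhd: GeneNeighborhood,
    annotations: AnnotationTable,
    catalog: MotifCatalog,
) -> HydrogenaseCall:
    """Validate a [NiFe] call: Ni-ligating L1 and L2 motifs on the large
    subunit plus a qualifying small-subunit gene in the neighborhood."""
    if call.assignment.predicted_class.metal_type != "NiFe":
        raise ValueError("validate_nife requires a NiFe assignment")
    seq = call.anchor.sequence
    slots = {slot: catalog.scan_role(seq, slot) for slot in ("nife_l1", "nife_l2")}
    call.motif_evidence.update(slots)
    small = find_small_subunit(nbhd, annotations, catalog)
    call.small_subunit_locus = small
    if not all(slots.values()):
        missing = [s for s, v in slots.items() if not v]
        call.warnings.append(f"missing Ni-ligating motif slot(s): {', '.join(missing)}")
        call.validation_status = "rejected"
        return call
    if small is None:
        call.warnings.append("no qualifying small-subunit gene in neighborhood")
        call.validation_status = "rejected"
        return call
    small_gene = next(g for g, _ in nbhd.flanking if g.locus_tag == small)
    if small_gene.record is not None:
        has_tat, _ = check_tat_signal(small_gene.record, catalog)
        call.tat_signal = has_tat
    call.validation_status = "validated"
    return call


def assign_subunit_roles(
    call: HydrogenaseCall,
    nbhd: GeneNeighborhood,
    annotations: AnnotationTable,
    template: SubunitTemplate,
) -> HydrogenaseCall:
    """Greedy nearest-first assignment of flanking genes to template roles.

    Each flanking gene may fill at most one role; required roles without
    a match produce warnings (not rejection), optional ones notes.  The
    nearest-first order makes the assignment invariant to reversing the
    contig orientation.
    """
    role_map: dict[str, str] = {}
    used: set[str] = set()
    for role in template.roles:
        if role.catalytic:
            role_map[role.name] = call.anchor.locus_tag
            continue
        for gene, _offset in nbhd.nearest_first():
            if gene.locus_tag in used:
                continue
            if _matches_keywords(gene, annotations, role.keywords):
                role_map[role.name] = gene.locus_tag
                used.add(gene.locus_tag)
                break
        else:
            kind = "expected" if role.required else "optional"
            call.warnings.append(f"{kind} subunit role {role.name!r} not found in neighborhood")
            if call.validation_status == "validated":
                call.validation_status = "validated_with_warnings"
    call.role_map.update(role_map)
    return call


def diaphorase_profile(
    subunit: ProteinRecord,
    annotations: AnnotationTable,
    catalog: MotifCatalog,
) -> DiaphoraseProfile:
    """Profile a diaphorase subunit's cofactor-binding loops.

    The N-terminal NuoF-like Gly-rich loop distinguishes A4-type
    (R-G-G-A-G-F-P) from A3-type (R-G-G-G-G-F-P) subunits; the Rossmann
    first loop tracks the cofactor hypothesis: the Gly form
    (G-D-E-G-D-P-G) is NADP-associated, the Ala form (A-D-E-G-D-P-G)
    NAD-associated.
    """
    seq = subunit.sequence
    if catalog.scan_role(seq, "diaphorase_nterm_a4"):
        nterm = "A4-type"
    elif catalog.scan_role(seq, "diaphorase_nterm_a3"):
        nterm = "A3-type"
    else:
        nterm = "absent"
    if catalog.scan_role(seq, "rossmann_loop_g"):
        rossmann = "G-type"
    elif catalog.scan_role(seq, "rossmann_loop_a"):
        rossmann = "A-type"
    else:
        rossmann = "absent"
    cofactor = {
        "G-type": "NADP-associated",
        "A-type": "NAD-associated",
        "absent": "undetermined",
    }[rossmann]
    return DiaphoraseProfile(
        locus_tag=subunit.locus_tag,
        nterm_loop=nterm,
        rossmann_loop=rossmann,
        cofactor_hypothesis=cofactor,
    )


def validate_call(
    call: HydrogenaseCall,
    features: GenomeFeatures,
    annotations: AnnotationTable,
    catalog: MotifCatalog,
    templates: dict[str, SubunitTemplate] = DEFAULT_TEMPLATES,
    window_size: int = DEFAULT_WINDOW_SIZE,
    fefe_mode: str = "all_three",
) -> HydrogenaseCall:
    """Full validation of one classified catalytic subunit.

    Runs the metal-type-specific motif/neighborhood checks, then template
    role assignment and (for bifurcating [FeFe] classes) diaphorase
    profiling.
    """
    nbhd = neighborhood(call.anchor.locus_tag, features, window_size)
    cls = call.assignment.predicted_class
    if cls.metal_type == "FeFe":
        validate_fefe(call, catalog, mode=fefe_mode)
    else:
        validate_nife(call, nbhd, annotations, catalog)
    if call.validation_status == "rejected":
        return call
    template = templates.get(cls.token)
    if template is None:
        template = templates.get(cls.group)
    if template is not None:
        assign_subunit_roles(call, nbhd, annotations, template)
        dia_role = next((r for r in template.roles if "diaphorase" in r.name), None)
        if dia_role is not None and dia_role.name in call.role_map:
            gene = features.gene(call.role_map[dia_role.name])
            if gene.record is not None:
                call.diaphorase = diaphorase_profile(gene.record, annotations, catalog)
    else:
        logger.info("no subunit template for class %s; role assignment skipped", cls.label)
    return call
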