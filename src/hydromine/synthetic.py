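"""Seeded synthetic benchmark: reference catalogs, planted genomes, truth tables.

The generator emulates the statistical structure the pipeline assumes:

* a class-labeled reference catalog in which within-class identity
  clearly exceeds between-class identity (verified post hoc against the
  same alignment engine the pipeline uses);
* genomes carrying planted hydrogenase operons laid out per the class
  subunit templates — an uptake [NiFe] 1a large+small pair (cytochrome
  optional), a monomeric [FeFe] B enzyme, a trimeric bifurcating A3
  complex, and a hexameric formate-dehydrogenase-linked A4 (Hyt-like)
  complex — with the metal-binding motifs spliced into the catalytic
  subunits and the NuoF-like loops into the diaphorases;
* maturation genes (HydE/F/G, HypA-F) planted intact, as atypical
  variants, or omitted per genome;
* motif-ablated operons and motif-free random decoys.

Everything is a pure function of the seed; two runs write byte-identical
files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import io as hio
from .align import align_local, evalue, pairwise_identity
from .core import AMINO_ACIDS, AnnotationTable, GeneFeature, GenomeFeatures, ProteinRecord
from .motifs import MotifCatalog, MotifPattern, load_motif_catalog, scan
from .reference import ReferenceCatalog, ReferenceEntry, parse_reference_header


# ---------------------------------------------------------------- config

@dataclass(frozen=True)
class ClassSpec:
    metal_type: str
    token: str
    n_refs: int = 5
    ancestor_len: int = 300
    sub_rate: float = 0.12


@dataclass(frozen=True)
class OperonSpec:
    """One planted hydrogenase operon.

    ``ablate`` names motif slots removed from the construction:
    P1/P2/P3 (H-cluster), L1/L2 (Ni ligation), small_motif (small-subunit
    Fe-S ligands).  ``cytochrome`` only applies to class 1a;
    ``rossmann`` selects the diaphorase first-loop form (A = Ala form,
    G = Gly form) for A3/A4 operons.
    """

    class_token: str
    ablate: tuple[str, ...] = ()
    cytochrome: bool = False
    rossmann: str = ""  # default per class: A4 -> G, A3 -> A


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str
    operons: tuple[OperonSpec, ...]
    maturases: tuple[tuple[str, str], ...] = ()  # (name, intact|variant|absent)
    n_decoys: int = 4


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 42
    classes: tuple[ClassSpec, ...] = (
        ClassSpec("NiFe", "1a", ancestor_len=320),
        ClassSpec("FeFe", "B"),
        ClassSpec("FeFe", "A3"),
        ClassSpec("FeFe", "A4"),
    )
    genomes: tuple[GenomeSpec, ...] = ()
    copy_rate: float = 0.03  # divergence of planted subunits from their reference
    margin: float = 10.0  # required min-within minus max-between identity gap
    intergenic: int = 60  # nucleotides between adjacent genes
    plant_tat: bool = False  # twin-arginine signal on small subunits (off: the
    #                          default panel emulates its absence)
    max_retries: int = 5


MATURASE_LENGTHS = {
    "HydE": 360,
    "HydF": 400,
    "HydG": 450,
    "HypA": 110,
    "HypB": 270,
    "HypC": 90,
    "HypD": 370,
    "HypE": 340,
    "HypF": 620,
}

ALL_MATURASES = tuple(MATURASE_LENGTHS)


def default_panel(seed: int = 42, n_genomes: int = 8) -> SynthConfig:
    """The default eight-genome study panel.

    Every genome carries the minimal repertoire common to the modelled
    acetogen panel (1a pair, B singleton, A3 trio, A4 hexamer) plus one
    H-cluster-ablated A3 operon and one small-subunit-ablated 1a pair as
    planted negatives.  Cytochrome accessory subunits and maturase
    presence/absence follow the heterogeneous pattern of the modelled
    panel: genomes 1, 5 and 7 (0-based indices) carry the cytochrome and
    the complete NiFe machinery; HydG is intact in genomes 0, 5 and 7
    and an atypical variant elsewhere; the A3 diaphorases of genomes 5
    and 7 carry the Gly-form Rossmann loop (the exception pattern).
    """
    genomes = []
    for i in range(n_genomes):
        gid = f"SYN{i + 1:02d}"
        has_cyt = i in (1, 5, 7)
        hydg = "intact" if i in (0, 5, 7) else "variant"
        hyp_ab = "intact" if i in (1, 5, 7) else "absent"
        a3_loop = "G" if i in (5, 7) else "A"
        operons = (
            OperonSpec("1a", cytochrome=has_cyt),
            OperonSpec("B"),
            OperonSpec("A3", rossmann=a3_loop),
            OperonSpec("A4"),
            OperonSpec("A3", ablate=("P3",)),
            OperonSpec("1a", ablate=("small_motif",), cytochrome=False),
        )
        maturases = (
            ("HydE", "intact"),
            ("HydF", "intact"),
            ("HydG", hydg),
            ("HypA", hyp_ab),
            ("HypB", hyp_ab),
            ("HypC", "intact"),
            ("HypD", "intact"),
            ("HypE", "intact"),
            ("HypF", "intact"),
        )
        genomes.append(GenomeSpec(genome_id=gid, operons=operons, maturases=maturases))
    return SynthConfig(seed=seed, genomes=tuple(genomes))


# ---------------------------------------------------------------- truth

@dataclass(frozen=True)
class TruthRow:
    genome_id: str
    locus_tag: str
    kind: str  # hydrogenase | subunit | maturase | decoy
    label: str  # class token, role name, or protein name
    expected: str  # validated / validated_with_warnings / rejected / detected / ...
    cofactor: str = ""  # expected diaphorase cofactor hypothesis, if any


@dataclass
class SynthGenome:
    genome_id: str
    proteome: list[ProteinRecord]
    features: GenomeFeatures
    annotations: AnnotationTable
    truth: list[TruthRow]


@dataclass
class SynthPanel:
    config: SynthConfig
    reference_records: list[tuple[str, str]]
    catalog: ReferenceCatalog
    maturation_queries: list[tuple[str, str]]
    genomes: list[SynthGenome]

    @property
    def truth(self) -> list[TruthRow]:
        return [row for g in self.genomes for row in g.truth]


# ---------------------------------------------------------------- helpers

def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _full_sequence_pattern(pat: MotifPattern) -> MotifPattern:
    """A region-free view of a pattern (used for motif-free guarantees)."""
    if pat.region == "any":
        return pat
    return MotifPattern(
        name=pat.name, tokens=pat.tokens, region="any", role=pat.role, text=pat.text
    )


def motif_free(sequence: str, catalog: MotifCatalog) -> bool:
    """True iff no catalog pattern matches anywhere in the sequence,
    region constraints ignored (a strictly stronger guarantee)."""
    return not any(
        scan(sequence, _full_sequence_pattern(p)) for p in catalog.patterns.values()
    )


def _motif_free_sequence(rng: random.Random, length: int, catalog: MotifCatalog) -> str:
    for _ in range(200):
        seq = _random_sequence(rng, length)
        if motif_free(seq, catalog):
            return seq
    raise RuntimeError("could not sample a motif-free sequence; catalog too permissive")


def significant_identity(a: str, b: str, search_space: int, e_max: float = 0.01) -> float:
    """Percent identity of the optimal local alignment, or 0.0 when that
    alignment is not statistically significant (E > e_max in the given
    search space).

    Unrelated random proteins routinely share short local alignments with
    high *column* identity but negligible score; those never compete in
    hit selection (the E-value gate removes them), so the class-
    separability margin is defined over significant alignments only.
    """
    aln = align_local(a, b) if a <= b else align_local(b, a)
    if aln is None or evalue(aln.score, len(a), search_space) > e_max:
        return 0.0
    return aln.percent_identity


def mutate(rng: random.Random, sequence: str, rate: float) -> str:
    """Substitute each position with probability ``rate`` (no indels)."""
    out = []
    for ch in sequence:
        if rng.random() < rate:
            repl = rng.choice(AMINO_ACIDS)
            while repl == ch:
                repl = rng.choice(AMINO_ACIDS)
            out.append(repl)
        else:
            out.append(ch)
    return "".join(out)


def realize_pattern(rng: random.Random, pattern: MotifPattern) -> str:
    """A concrete string satisfying the pattern (widths and residues drawn
    from the generator's stream)."""
    parts = []
    for tok in pattern.tokens:
        width = rng.randint(tok.min_repeat, tok.max_repeat)
        choices = sorted(tok.residues)
        parts.append("".join(rng.choice(choices) for _ in range(width)))
    return "".join(parts)


def splice(sequence: str, insert: str, pos: int) -> str:
    """Overwrite ``sequence`` with ``insert`` starting at 0-based ``pos``."""
    if pos + len(insert) > len(sequence):
        raise ValueError("splice exceeds sequence length")
    return sequence[:pos] + insert + sequence[pos + len(insert):]


# ---------------------------------------------------------------- reference

def make_reference(
    config: SynthConfig, motif_catalog: MotifCatalog | None = None
) -> tuple[list[tuple[str, str]], ReferenceCatalog]:
    """Build the class-labeled reference set.

    Per class an ancestor is sampled (motif-free, so planted signals come
    only from explicit splicing) and ``n_refs`` copies are mutated at the
    class substitution rate.  The class-separability margin — minimum
    within-class identity minus maximum between-class identity over
    *significant* alignments (see :func:`significant_identity`) — is
    recomputed with the pipeline's own alignment engine and must meet the
    configured value; otherwise the draw is retried.
    """
    if len(config.classes) < 2:
        raise ValueError("need at least 2 classes")
    catalog = motif_catalog or load_motif_catalog()
    rng = random.Random(config.seed)
    for attempt in range(config.max_retries):
        records: list[tuple[str, str]] = []
        by_class: dict[str, list[str]] = {}
        for spec in config.classes:
            ancestor = _motif_free_sequence(rng, spec.ancestor_len, catalog)
            seqs = [mutate(rng, ancestor, spec.sub_rate) for _ in range(spec.n_refs)]
            by_class[spec.token] = seqs
            for i, seq in enumerate(seqs):
                entry_id = f"REF_{spec.token}_{i:03d}"
                header = f"{entry_id}|{spec.metal_type}|{spec.token}"
                records.append((header, seq))
        space = sum(len(seq) for _, seq in records)
        min_within = min(
            pairwise_identity(a, b)
            for seqs in by_class.values()
            for i, a in enumerate(seqs)
            for b in seqs[i + 1:]
        )
        tokens = list(by_class)
        max_between = max(
            significant_identity(a, b, space)
            for i, t1 in enumerate(tokens)
            for t2 in tokens[i + 1:]
            for a in by_class[t1]
            for b in by_class[t2]
        )
        if min_within - max_between >= config.margin:
            entries = [
                ReferenceEntry(
                    entry_id=header.split("|")[0],
                    sequence=seq,
                    hyd_class=parse_reference_header(header)[1],
                )
                for header, seq in records
            ]
            return records, ReferenceCatalog(entries=entries)
    raise RuntimeError(
        f"class-separability margin {config.margin} unreachable after "
        f"{config.max_retries} draws; lower within-class substitution rates "
        "or the margin"
    )


# ---------------------------------------------------------------- genomes

_FES_PRODUCT = "iron-sulfur protein (4Fe-4S)"
_DIA_PRODUCT = "iron-sulfur flavoprotein (NuoF-like cofactor-binding subunit)"


class _GenomeBuilder:
    def __init__(self, genome_id: str, config: SynthConfig):
        self.genome_id = genome_id
        self.config = config
        self.counter = 0
        self.cursor = 101
        self.genes: list[GeneFeature] = []
        self.proteome: list[ProteinRecord] = []
        self.annotations = AnnotationTable()
        self.truth: list[TruthRow] = []

    def next_tag(self) -> str:
        self.counter += 5
        return f"{self.genome_id}_RS{self.counter:05d}"

    def add_gene(
        self,
        sequence: str,
        product: str,
        strand: str = "+",
        domain_labels: tuple[str, ...] = (),
    ) -> str:
        tag = self.next_tag()
        nt_len = 3 * len(sequence) + 3
        record = ProteinRecord(
            protein_id=tag,
            locus_tag=tag,
            sequence=sequence,
            genome_id=self.genome_id,
            contig_id="contig_1",
            start=self.cursor,
            end=self.cursor + nt_len - 1,
            strand=strand,
            product=product,
        )
        self.cursor += nt_len + self.config.intergenic
        self.proteome.append(record)
        self.genes.append(
            GeneFeature(
                locus_tag=tag,
                contig_id="contig_1",
                start=record.start,
                end=record.end,
                strand=strand,
                product=product,
                record=record,
            )
        )
        for label in domain_labels:
            self.annotations.add(tag, "synth", label)
        return tag

    def finish(self) -> SynthGenome:
        features = GenomeFeatures(genome_id=self.genome_id, contigs={"contig_1": self.genes})
        return SynthGenome(
            genome_id=self.genome_id,
            proteome=self.proteome,
            features=features,
            annotations=self.annotations,
            truth=self.truth,
        )


def _catalytic_sequence(
    rng: random.Random,
    ref_catalog: ReferenceCatalog,
    motif_catalog: MotifCatalog,
    spec: OperonSpec,
    metal: str,
    copy_rate: float,
) -> str:
    label = [
        lbl for lbl in ref_catalog.by_class if lbl.endswith(f"Group {spec.class_token}")
    ][0]
    source = rng.choice(ref_catalog.by_class[label])
    seq = mutate(rng, source.sequence, copy_rate)
    n = len(seq)
    if metal == "FeFe":
        slots = (("P1", "h_cluster_p1", 0.30), ("P2", "h_cluster_p2", 0.50), ("P3", "h_cluster_p3", 0.70))
    else:
        slots = (("L1", "nife_l1", 0.25), ("L2", "nife_l2", 0.65))
    for flag, role, frac in slots:
        if flag in spec.ablate:
            continue
        pattern = motif_catalog.require_role(role)[0]
        seq = splice(seq, realize_pattern(rng, pattern), int(frac * n))
    return seq


def _diaphorase_sequence(
    rng: random.Random, motif_catalog: MotifCatalog, nterm_role: str, rossmann: str
) -> str:
    seq = _motif_free_sequence(rng, 320, motif_catalog)
    nterm = realize_pattern(rng, motif_catalog.require_role(nterm_role)[0])
    loop_role = "rossmann_loop_g" if rossmann == "G" else "rossmann_loop_a"
    loop = realize_pattern(rng, motif_catalog.require_role(loop_role)[0])
    seq = splice(seq, nterm, 60)
    return splice(seq, loop, 130)


def _maturase_sequence(
    rng: random.Random,
    motif_catalog: MotifCatalog,
    name: str,
    ancestor: str,
    status: str,
) -> str:
    """Mutated ancestor copy with the family signatures spliced in.

    Rejection-sampled so the construction cannot silently change tier:
    an atypical-variant HydG must not also carry a canonical C-terminal
    triad (stray Cys from the wildcard draws could otherwise complete
    one), and a HydE — whose length falls in the HydG range — must not
    carry either HydG triad class.
    """
    for _ in range(100):
        seq = mutate(rng, ancestor, 0.04)
        n = len(seq)

        def put(role: str, pos: int) -> None:
            nonlocal seq
            pat = motif_catalog.require_role(role)[0]
            seq = splice(seq, realize_pattern(rng, pat), pos)

        if name == "HydE":
            put("radical_sam", 50)
            put("hyde_cterm", n - 40)
            if motif_catalog.scan_role(seq, "hydg_cterm") or motif_catalog.scan_role(
                seq, "hydg_cterm_variant"
            ):
                continue
        elif name == "HydG":
            put("radical_sam", 50)
            if status == "variant":
                put("hydg_cterm_variant", n - 60)
                if motif_catalog.scan_role(seq, "hydg_cterm"):
                    continue
            else:
                put("hydg_cterm", n - 60)
        elif name == "HydF":
            put("hydf_ploop", 10)
            put("hydf_switch", 60)
            put("hydf_nkxd", 100)
            put("hydf_cterm", n - 70)
        elif name == "HypB":
            put("hypb_ploop", 10)
        return seq
    raise RuntimeError(f"could not construct a tier-consistent {name} ({status})")


def make_genomes(
    config: SynthConfig,
    ref_catalog: ReferenceCatalog,
    motif_catalog: MotifCatalog,
) -> tuple[list[SynthGenome], list[tuple[str, str]]]:
    """Build all genomes plus the maturation query FASTA records.

    Returns (genomes, maturation_queries).  Maturase query sequences are
    the shared per-family ancestors; planted maturase genes are mutated
    copies with the family signatures spliced into the regions where the
    profiles expect them.
    """
    rng = random.Random(config.seed + 1)
    ancestors = {
        name: _motif_free_sequence(rng, length, motif_catalog)
        for name, length in MATURASE_LENGTHS.items()
    }
    queries = [(name, ancestors[name]) for name in ALL_MATURASES]
    genomes = []
    for gspec in config.genomes:
        genomes.append(_build_genome(rng, config, gspec, ref_catalog, motif_catalog, ancestors))
    return genomes, queries


def _expected_operon_verdict(spec: OperonSpec, metal: str) -> str:
    if metal == "FeFe":
        if any(f in spec.ablate for f in ("P1", "P2", "P3")):
            return "rejected"
        return "validated"
    if "small_motif" in spec.ablate or "small" in spec.ablate:
        return "rejected"
    if any(f in spec.ablate for f in ("L1", "L2")):
        return "rejected"
    return "validated" if spec.cytochrome else "validated_with_warnings"


def _build_genome(
    rng: random.Random,
    config: SynthConfig,
    gspec: GenomeSpec,
    ref_catalog: ReferenceCatalog,
    motif_catalog: MotifCatalog,
    ancestors: dict[str, str],
) -> SynthGenome:
    b = _GenomeBuilder(gspec.genome_id, config)
    decoys_left = gspec.n_decoys

    def add_decoy() -> None:
        nonlocal decoys_left
        if decoys_left <= 0:
            return
        decoys_left -= 1
        seq = _motif_free_sequence(rng, rng.randint(150, 300), motif_catalog)
        tag = b.add_gene(seq, "hypothetical protein")
        b.truth.append(TruthRow(b.genome_id, tag, "decoy", "decoy", "no_call"))

    for i, ospec in enumerate(gspec.operons):
        add_decoy()
        strand = "+" if i % 2 == 0 else "-"
        metal = "NiFe" if ospec.class_token[0].isdigit() else "FeFe"
        verdict = _expected_operon_verdict(ospec, metal)
        cat_seq = _catalytic_sequence(rng, ref_catalog, motif_catalog, ospec, metal, config.copy_rate)

        if ospec.class_token == "1a":
            tag = b.add_gene(cat_seq, "NiFe hydrogenase large subunit", strand)
            small = _motif_free_sequence(rng, 260, motif_catalog)
            if "small_motif" not in ospec.ablate:
                small = splice(
                    small,
                    realize_pattern(rng, motif_catalog.require_role("nife_small_fes")[0]),
                    100,
                )
            if config.plant_tat:
                small = splice(
                    small, realize_pattern(rng, motif_catalog.require_role("tat")[0]), 3
                )
            if "small" not in ospec.ablate:
                stag = b.add_gene(
                    small,
                    "NiFe hydrogenase small subunit",
                    strand,
                    ("NiFe hydrogenase small subunit",),
                )
                b.truth.append(TruthRow(b.genome_id, stag, "subunit", "small_subunit", ""))
            if ospec.cytochrome:
                ctag = b.add_gene(
                    _motif_free_sequence(rng, 200, motif_catalog),
                    "cytochrome b subunit",
                    strand,
                    ("cytochrome b",),
                )
                b.truth.append(TruthRow(b.genome_id, ctag, "subunit", "cytochrome", ""))
            b.truth.append(TruthRow(b.genome_id, tag, "hydrogenase", "1a", verdict))

        elif ospec.class_token == "B":
            tag = b.add_gene(cat_seq, "FeFe hydrogenase", strand)
            b.truth.append(TruthRow(b.genome_id, tag, "hydrogenase", "B", verdict))

        elif ospec.class_token == "A3":
            rossmann = ospec.rossmann or "A"
            cofactor = "NADP-associated" if rossmann == "G" else "NAD-associated"
            tag = b.add_gene(cat_seq, "FeFe hydrogenase catalytic subunit", strand)
            dia = _diaphorase_sequence(rng, motif_catalog, "diaphorase_nterm_a3", rossmann)
            dtag = b.add_gene(dia, _DIA_PRODUCT, strand, ("NuoF-like subunit COG1894",))
            ttag = b.add_gene(
                _motif_free_sequence(rng, 110, motif_catalog),
                "thioredoxin",
                strand,
                ("thioredoxin",),
            )
            b.truth.append(
                TruthRow(b.genome_id, tag, "hydrogenase", "A3", verdict, cofactor)
            )
            b.truth.append(
                TruthRow(b.genome_id, dtag, "subunit", "diaphorase", "", cofactor)
            )
            b.truth.append(TruthRow(b.genome_id, ttag, "subunit", "thioredoxin", ""))

        elif ospec.class_token == "A4":
            rossmann = ospec.rossmann or "G"
            cofactor = "NADP-associated" if rossmann == "G" else "NAD-associated"
            # Hyt-like gene order: C, B (diaphorase), D, A (catalytic), E1, E2
            ctag = b.add_gene(
                _motif_free_sequence(rng, 180, motif_catalog), _FES_PRODUCT, strand
            )
            dia = _diaphorase_sequence(rng, motif_catalog, "diaphorase_nterm_a4", rossmann)
            dtag = b.add_gene(dia, _DIA_PRODUCT, strand, ("NuoF-like subunit COG1894",))
            d2 = b.add_gene(
                _motif_free_sequence(rng, 170, motif_catalog), _FES_PRODUCT, strand
            )
            tag = b.add_gene(cat_seq, "FeFe hydrogenase catalytic subunit HytA", strand)
            e1 = b.add_gene(
                _motif_free_sequence(rng, 160, motif_catalog), _FES_PRODUCT, strand
            )
            e2 = b.add_gene(
                _motif_free_sequence(rng, 150, motif_catalog), _FES_PRODUCT, strand
            )
            b.truth.append(
                TruthRow(b.genome_id, tag, "hydrogenase", "A4", verdict, cofactor)
            )
            b.truth.append(
                TruthRow(b.genome_id, dtag, "subunit", "diaphorase", "", cofactor)
            )
            for t, role in ((ctag, "fes_HytC"), (d2, "fes_HytD"), (e1, "fes_HytE1"), (e2, "fes_HytE2")):
                b.truth.append(TruthRow(b.genome_id, t, "subunit", role, ""))
        else:
            raise ValueError(f"no operon builder for class {ospec.class_token!r}")

    add_decoy()
    for name, status in gspec.maturases:
        if status == "absent":
            b.truth.append(TruthRow(b.genome_id, "", "maturase", name, "absent"))
            continue
        seq = _maturase_sequence(rng, motif_catalog, name, ancestors[name], status)
        tag = b.add_gene(seq, f"{name} maturation protein")
        expected = "detected" if status == "intact" else "candidate_atypical"
        b.truth.append(TruthRow(b.genome_id, tag, "maturase", name, expected))
    while decoys_left > 0:
        add_decoy()
    return b.finish()


def generate_panel(config: SynthConfig | None = None) -> SynthPanel:
    """Generate the full panel (reference + genomes + queries) in memory."""
    config = config or default_panel()
    motif_catalog = load_motif_catalog()
    records, ref_catalog = make_reference(config, motif_catalog)
    genomes, queries = make_genomes(config, ref_catalog, motif_catalog)
    return SynthPanel(
        config=config,
        reference_records=records,
        catalog=ref_catalog,
        maturation_queries=queries,
        genomes=genomes,
    )


# ---------------------------------------------------------------- writers

def write_panel(panel: SynthPanel, outdir: str | Path) -> dict[str, object]:
    """Write the panel as FASTA/GFF3/TSV files; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_path = outdir / "reference.faa"
    hio.write_fasta(ref_path, panel.reference_records)
    query_path = outdir / "maturation_queries.faa"
    hio.write_fasta(query_path, panel.maturation_queries)
    manifest: dict[str, object] = {
        "reference": str(ref_path),
        "maturation_queries": str(query_path),
        "genomes": [],
    }
    for genome in panel.genomes:
        faa = outdir / f"{genome.genome_id}.faa"
        hio.write_fasta(
            faa,
            [
                (f"{rec.locus_tag} {rec.product}".strip(), rec.sequence)
                for rec in genome.proteome
            ],
        )
        gff = outdir / f"{genome.genome_id}.gff"
        _write_gff(gff, genome)
        ann = outdir / f"{genome.genome_id}_annotations.tsv"
        hio.write_annotations(ann, genome.annotations)
        manifest["genomes"].append(
            {
                "genome_id": genome.genome_id,
                "proteome": str(faa),
                "gff": str(gff),
                "annotations": str(ann),
            }
        )
    truth_path = outdir / "truth.tsv"
    hio.write_tsv(
        truth_path,
        ["genome_id", "locus_tag", "kind", "label", "expected", "cofactor"],
        [
            (r.genome_id, r.locus_tag, r.kind, r.label, r.expected, r.cofactor)
            for r in panel.truth
        ],
    )
    manifest["truth"] = str(truth_path)
    return manifest


def _write_gff(path: Path, genome: SynthGenome) -> None:
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for contig, genes in sorted(genome.features.contigs.items()):
            for i, gene in enumerate(genes):
                attrs = (
                    f"ID=cds-{gene.locus_tag};locus_tag={gene.locus_tag};"
                    f"product={gene.product}"
                )
                fh.write(
                    "\t".join(
                        [
                            contig,
                            "hydromine_synth",
                            "CDS",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_truth(path: str | Path) -> list[TruthRow]:
    rows = []
    with Path(path).open() as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(TruthRow(*parts))
    return rows
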