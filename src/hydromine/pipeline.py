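"""End-to-end orchestration: reference -> thresholds -> search -> filter ->
vote -> validation -> maturation -> reports.

The run is driven by a declarative YAML config (see :class:`RunConfig`)
and writes five reports into the output directory:

* ``candidates.tsv``   every query with at least one retained hit (the
  preliminary identification list)
* ``validated.tsv``    validated catalytic subunits with subunit roles
* ``maturation.tsv``   per-genome maturation-protein calls and machinery
  completeness
* ``diaphorase.tsv``   cofactor-loop profiles of diaphorase subunits
* ``summary.json``     the identification/validation funnel per genome
  and class, plus provenance (config hash, seed)

Reports are deterministic: identical config and inputs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as hio
from .classify import DEFAULT_TOP_K, assign_class
from .core import ProteinRecord
from .homology import DEFAULT_E_MAX, filter_hits, hits_from_blast, search
from .maturation import (
    detect_maturation,
    load_maturation_profiles,
    maturation_completeness,
)
from .motifs import load_motif_catalog
from .reference import (
    DEFAULT_FALLBACK_THRESHOLD,
    DEFAULT_MAX_PAIRS_PER_CLASS,
    ClassThresholdTable,
    class_min_identity_thresholds,
    load_reference,
)
from .validation import DEFAULT_WINDOW_SIZE, HydrogenaseCall, validate_call

logger = logging.getLogger(__name__)


@dataclass
class GenomeInputs:
    genome_id: str
    proteome: str
    gff: str
    annotations: str
    hits: str | None = None  # optional precomputed BLAST tabular


@dataclass
class RunConfig:
    reference: str
    genomes: list[GenomeInputs]
    outdir: str
    maturation_queries: str | None = None
    motif_catalog: str | None = None
    maturation_profiles: str | None = None
    e_max: float = DEFAULT_E_MAX
    top_k: int = DEFAULT_TOP_K
    window_size: int = DEFAULT_WINDOW_SIZE
    fefe_mode: str = "all_three"
    threshold_cap: int = DEFAULT_MAX_PAIRS_PER_CLASS
    threshold_seed: int = 0
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        base = Path(path).parent
        data = yaml.safe_load(Path(path).read_text())

        def resolve(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        genomes = [
            GenomeInputs(
                genome_id=g["genome_id"],
                proteome=resolve(g["proteome"]),
                gff=resolve(g["gff"]),
                annotations=resolve(g["annotations"]),
                hits=resolve(g.get("hits")),
            )
            for g in data["genomes"]
        ]
        return cls(
            reference=resolve(data["reference"]),
            genomes=genomes,
            outdir=resolve(data["outdir"]),
            maturation_queries=resolve(data.get("maturation_queries")),
            motif_catalog=resolve(data.get("motif_catalog")),
            maturation_profiles=resolve(data.get("maturation_profiles")),
            **{
                k: data[k]
                for k in (
                    "e_max",
                    "top_k",
                    "window_size",
                    "fefe_mode",
                    "threshold_cap",
                    "threshold_seed",
                    "fallback_threshold",
                )
                if k in data
            },
        )

    def digest(self) -> str:
        payload = json.dumps(
            {
                "e_max": self.e_max,
                "top_k": self.top_k,
                "window_size": self.window_size,
                "fefe_mode": self.fefe_mode,
                "threshold_cap": self.threshold_cap,
                "threshold_seed": self.threshold_seed,
                "fallback_threshold": self.fallback_threshold,
                "genomes": [g.genome_id for g in self.genomes],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    thresholds: ClassThresholdTable
    calls: dict[str, list[HydrogenaseCall]] = field(default_factory=dict)
    maturation: dict[str, list] = field(default_factory=dict)
    completeness: dict[str, list] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = load_reference(config.reference)
    motif_catalog = load_motif_catalog(config.motif_catalog)
    profiles = load_maturation_profiles(config.maturation_profiles)
    thresholds = class_min_identity_thresholds(
        catalog,
        max_pairs_per_class=config.threshold_cap,
        seed=config.threshold_seed,
        fallback=config.fallback_threshold,
    )
    thresholds.write_tsv(outdir / "thresholds.tsv")

    queries = (
        hio.read_fasta(config.maturation_queries) if config.maturation_queries else []
    )

    candidate_rows = []
    validated_rows = []
    diaphorase_rows = []
    maturation_rows = []
    result = RunResult(thresholds=thresholds)
    summary: dict = {"genomes": {}, "provenance": {"config_hash": config.digest()}}

    for genome in config.genomes:
        proteome = hio.read_proteome(genome.proteome, genome_id=genome.genome_id)
        features = hio.read_features(genome.gff, proteome, genome_id=genome.genome_id)
        annotations = hio.read_annotations(genome.annotations)
        if genome.hits:
            grouped = hits_from_blast(hio.read_blast_tab(genome.hits), catalog, proteome)
        else:
            grouped = search(proteome, catalog)
        by_tag = {rec.locus_tag: rec for rec in proteome}

        calls: list[HydrogenaseCall] = []
        n_identified = 0
        per_class_identified: dict[str, int] = {}
        per_class_validated: dict[str, int] = {}
        for record in proteome:
            hits = grouped.get(record.locus_tag, [])
            retained = filter_hits(hits, thresholds, e_max=config.e_max)
            if not retained:
                continue
            assignment = assign_class(retained, k=config.top_k)
            if assignment is None:
                continue
            n_identified += 1
            label = assignment.predicted_class.label
            per_class_identified[label] = per_class_identified.get(label, 0) + 1
            top = retained[0]
            candidate_rows.append(
                (
                    genome.genome_id,
                    record.locus_tag,
                    label,
                    assignment.n_hits_used,
                    str(assignment.tie_broken).lower(),
                    f"{top.percent_identity:.2f}",
                    f"{top.e_value:.3g}",
                    ";".join(s for s, _ in assignment.vote_detail),
                )
            )
            call = HydrogenaseCall(anchor=by_tag[record.locus_tag], assignment=assignment)
            validate_call(
                call,
                features,
                annotations,
                motif_catalog,
                window_size=config.window_size,
                fefe_mode=config.fefe_mode,
            )
            calls.append(call)
            if call.validation_status.startswith("validated"):
                per_class_validated[label] = per_class_validated.get(label, 0) + 1
                roles = ";".join(f"{r}={t}" for r, t in sorted(call.role_map.items()))
                validated_rows.append(
                    (
                        genome.genome_id,
                        label,
                        record.locus_tag,
                        call.validation_status,
                        call.small_subunit_locus or "",
                        roles,
                        "|".join(call.warnings),
                    )
                )
                if call.diaphorase is not None:
                    d = call.diaphorase
                    diaphorase_rows.append(
                        (
                            genome.genome_id,
                            record.locus_tag,
                            d.locus_tag,
                            d.nterm_loop,
                            d.rossmann_loop,
                            d.cofactor_hypothesis,
                        )
                    )
        result.calls[genome.genome_id] = calls

        mat_calls = []
        statuses = []
        if queries:
            mat_calls = detect_maturation(
                proteome, queries, profiles, motif_catalog, genome_id=genome.genome_id
            )
            statuses = maturation_completeness(mat_calls, genome.genome_id)
            for mc in mat_calls:
                maturation_rows.append(
                    (
                        genome.genome_id,
                        mc.protein_name,
                        mc.locus_tag or "",
                        mc.verdict,
                        "GTP" if mc.gtpase else "",
                        f"{mc.identity:.2f}" if mc.identity is not None else "",
                        ";".join(mc.atypical_slots),
                    )
                )
        result.maturation[genome.genome_id] = mat_calls
        result.completeness[genome.genome_id] = statuses

        n_validated = sum(v for v in per_class_validated.values())
        summary["genomes"][genome.genome_id] = {
            "n_identified": n_identified,
            "n_validated": n_validated,
            "per_class_identified": dict(sorted(per_class_identified.items())),
            "per_class_validated": dict(sorted(per_class_validated.items())),
            "machinery": {
                s.machinery: {"complete": s.complete, "missing": s.missing}
                for s in statuses
            },
        }

    summary["total_identified"] = sum(
        g["n_identified"] for g in summary["genomes"].values()
    )
    summary["total_validated"] = sum(
        g["n_validated"] for g in summary["genomes"].values()
    )
    result.summary = summary

    hio.write_tsv(
        outdir / "candidates.tsv",
        [
            "genome_id",
            "query",
            "predicted_class",
            "n_hits_used",
            "tie_broken",
            "top_identity",
            "top_evalue",
            "supporting_subjects",
        ],
        candidate_rows,
    )
    hio.write_tsv(
        outdir / "validated.tsv",
        [
            "genome_id",
            "class",
            "catalytic_locus",
            "status",
            "small_subunit",
            "subunit_roles",
            "warnings",
        ],
        validated_rows,
    )
    hio.write_tsv(
        outdir / "maturation.tsv",
        ["genome_id", "protein", "locus_tag", "verdict", "gtpase", "identity", "atypical_slots"],
        maturation_rows,
    )
    hio.write_tsv(
        outdir / "diaphorase.tsv",
        ["genome_id", "catalytic_locus", "diaphorase_locus", "nterm_loop", "rossmann_loop", "cofactor_hypothesis"],
        diaphorase_rows,
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return result
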