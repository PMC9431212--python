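"""Detection of hydrogenase maturation proteins.

[FeFe]-hydrogenases need HydE, HydF and HydG to assemble the H cluster;
[NiFe]-hydrogenases need the HypA-HypF machinery for the Fe(CN)2CO
moiety and Ni insertion.  Detection is homology-first (known maturation
proteins aligned against each proteome), followed by inspection of every
hit for the conserved signatures of the family: radical-SAM Cys triads
and C-terminal Fe-S ligand sets for HydE/HydG, the GTPase nucleotide-
binding elements plus the C-terminal [4Fe-4S] ligands for HydF.

Verdict tiers per (genome, protein name):
  detected           - all required signature slots satisfied canonically
  candidate_atypical - homology plus required slots, but at least one slot
                       satisfied only by a configured atypical variant
  absent             - no hit fulfils the profile
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .core import ConfigurationError, ProteinRecord
from . import align as _align
from .motifs import MotifCatalog, MotifMatch

logger = logging.getLogger(__name__)

FEFE_MACHINERY = ("HydE", "HydF", "HydG")
NIFE_MACHINERY = ("HypA", "HypB", "HypC", "HypD", "HypE", "HypF")


@dataclass(frozen=True)
class ProfileSlot:
    name: str
    roles: tuple[str, ...]
    variant_roles: tuple[str, ...] = ()
    required: bool = True


@dataclass(frozen=True)
class MaturationProfile:
    protein_name: str
    slots: tuple[ProfileSlot, ...]
    length_range: tuple[int, int] | None = None
    min_identity: float = 0.0
    max_evalue: float | None = None


def load_maturation_profiles(path: str | Path | None = None) -> dict[str, MaturationProfile]:
    """Load per-protein profiles from YAML (bundled default if no path)."""
    if path is None:
        data = yaml.safe_load(
            resources.files("hydromine.data").joinpath("maturation_profiles.yaml").read_text()
        )
    else:
        data = yaml.safe_load(Path(path).read_text())
    profiles: dict[str, MaturationProfile] = {}
    for name, spec in data["profiles"].items():
        slots = tuple(
            ProfileSlot(
                name=s["name"],
                roles=tuple(s.get("roles", ())),
                variant_roles=tuple(s.get("variant_roles", ())),
                required=bool(s.get("required", True)),
            )
            for s in spec.get("slots", [])
        )
        lr = spec.get("length_range")
        profiles[name] = MaturationProfile(
            protein_name=name,
            slots=slots,
            length_range=tuple(lr) if lr else None,
            min_identity=float(spec.get("min_identity", 0.0)),
            max_evalue=(
                float(spec["max_evalue"]) if spec.get("max_evalue") is not None else None
            ),
        )
    return profiles


@dataclass
class MaturationCall:
    genome_id: str
    protein_name: str
    locus_tag: str | None
    verdict: str  # detected | candidate_atypical | absent
    identity: float | None = None
    e_value: float | None = None
    slot_evidence: dict[str, list[MotifMatch]] = field(default_factory=dict)
    atypical_slots: list[str] = field(default_factory=list)
    gtpase: bool = False


_VERDICT_RANK = {"detected": 2, "candidate_atypical": 1, "absent": 0}


def _inspect_candidate(
    record: ProteinRecord,
    profile: MaturationProfile,
    catalog: MotifCatalog,
) -> tuple[str, dict[str, list[MotifMatch]], list[str], bool]:
    """Check one homology hit against a profile.

    Returns (verdict, per-slot evidence, atypical slot names, gtpase flag).
    """
    seq = record.sequence
    if profile.length_range is not None:
        lo, hi = profile.length_range
        if not (lo <= len(seq) <= hi):
            return "absent", {}, [], False
    evidence: dict[str, list[MotifMatch]] = {}
    atypical: list[str] = []
    gtpase = False
    verdict = "detected"
    for slot in profile.slots:
        canonical: list[MotifMatch] = []
        for role in slot.roles:
            canonical.extend(catalog.scan_role(seq, role))
        if canonical:
            evidence[slot.name] = canonical
            if slot.name == "ploop":
                gtpase = True
            continue
        variant: list[MotifMatch] = []
        for role in slot.variant_roles:
            variant.extend(catalog.scan_role(seq, role))
        if variant:
            evidence[slot.name] = variant
            atypical.append(slot.name)
            if slot.required:
                verdict = "candidate_atypical"
            continue
        evidence[slot.name] = []
        if slot.required:
            return "absent", evidence, atypical, gtpase
    return verdict, evidence, atypical, gtpase


def detect_maturation(
    proteome: Sequence[ProteinRecord],
    query_set: Sequence[tuple[str, str]],
    profiles: dict[str, MaturationProfile],
    catalog: MotifCatalog,
    genome_id: str = "",
    e_max: float | None = None,
    e_floor: float = 10.0,
) -> list[MaturationCall]:
    """Detect maturation proteins in one proteome.

    ``query_set`` holds (header, sequence) pairs whose first header token
    names the protein (HydE, HypB, ...).  Every reported hit of every
    query is inspected against the protein's profile regardless of rank;
    no expect-value gate is applied by default (signatures decide), an
    optional ``e_max`` prefilter is available.  All loci reaching the
    best verdict tier for a protein are reported (paralogs are kept, not
    collapsed).
    """
    by_name: dict[str, list[str]] = {}
    for header, seq in query_set:
        by_name.setdefault(header.split()[0].split("|")[0], []).append(seq)
    missing = [n for n in by_name if n not in profiles]
    if missing:
        raise ConfigurationError(f"no maturation profile for query protein(s): {missing}")

    space = sum(len(r.sequence) for r in proteome)
    calls: list[MaturationCall] = []
    for name in sorted(by_name):
        profile = profiles[name]
        per_locus: dict[str, MaturationCall] = {}
        for qseq in by_name[name]:
            for record in proteome:
                aln = _align.align_local(qseq, record.sequence)
                if aln is None:
                    continue
                e = _align.evalue(aln.score, len(qseq), space)
                if e > e_floor:
                    continue
                if e_max is not None and e > e_max:
                    continue
                if profile.max_evalue is not None and e > profile.max_evalue:
                    continue
                if aln.percent_identity < profile.min_identity:
                    continue
                verdict, evidence, atypical, gtpase = _inspect_candidate(record, profile, catalog)
                if verdict == "absent":
                    continue
                call = MaturationCall(
                    genome_id=genome_id,
                    protein_name=name,
                    locus_tag=record.locus_tag,
                    verdict=verdict,
                    identity=aln.percent_identity,
                    e_value=e,
                    slot_evidence=evidence,
                    atypical_slots=atypical,
                    gtpase=gtpase,
                )
                prev = per_locus.get(record.locus_tag)
                if prev is None or _VERDICT_RANK[verdict] > _VERDICT_RANK[prev.verdict]:
                    per_locus[record.locus_tag] = call
        if not per_locus:
            calls.append(MaturationCall(genome_id, name, None, "absent"))
            continue
        best_rank = max(_VERDICT_RANK[c.verdict] for c in per_locus.values())
        for locus in sorted(per_locus):
            if _VERDICT_RANK[per_locus[locus].verdict] == best_rank:
                calls.append(per_locus[locus])
    return calls


@dataclass
class MachineryStatus:
    genome_id: str
    machinery: str  # FeFe | NiFe
    complete: bool
    missing: list[str] = field(default_factory=list)


def maturation_completeness(calls: Sequence[MaturationCall], genome_id: str) -> list[MachineryStatus]:
    """Per-machinery completeness: complete iff every member is detected."""
    verdicts: dict[str, str] = {}
    for call in calls:
        if call.genome_id != genome_id:
            continue
        current = verdicts.get(call.protein_name, "absent")
        if _VERDICT_RANK[call.verdict] >= _VERDICT_RANK[current]:
            verdicts[call.protein_name] = call.verdict
    statuses = []
    for machinery, members in (("FeFe", FEFE_MACHINERY), ("NiFe", NIFE_MACHINERY)):
        missing = [m for m in members if verdicts.get(m, "absent") != "detected"]
        statuses.append(
            MachineryStatus(
                genome_id=genome_id,
                machinery=machinery,
                complete=not missing,
                missing=missing,
            )
        )
    return statuses
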