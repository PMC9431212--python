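"""Maturation-protein detection, verdict tiers, and machinery completeness."""

import random

import pytest

from hydromine.core import ProteinRecord
from hydromine.maturation import (
    MaturationCall,
    detect_maturation,
    load_maturation_profiles,
    maturation_completeness,
)
from hydromine.synthetic import MATURASE_LENGTHS, _maturase_sequence, _motif_free_sequence, mutate


@pytest.fixture(scope="module")
def profiles():
    return load_maturation_profiles()


@pytest.fixture(scope="module")
def maturase_world(motif_catalog):
    """Ancestors plus planted intact/variant maturase sequences (seeded)."""
    rng = random.Random(99)
    ancestors = {
        name: _motif_free_sequence(rng, length, motif_catalog)
        for name, length in MATURASE_LENGTHS.items()
    }
    planted = {
        name: _maturase_sequence(rng, motif_catalog, name, anc, "intact")
        for name, anc in ancestors.items()
    }
    planted["HydG_variant"] = _maturase_sequence(
        rng, motif_catalog, "HydG", ancestors["HydG"], "variant"
    )
    return ancestors, planted


def _proteome(seqs):
    return [
        ProteinRecord(protein_id=f"m{i}", locus_tag=f"m{i}", sequence=s)
        for i, s in enumerate(seqs)
    ]


def _queries(ancestors, names=None):
    return [(n, ancestors[n]) for n in (names or ancestors)]


def _verdict(calls, name):
    hits = [c for c in calls if c.protein_name == name]
    best = max(hits, key=lambda c: {"absent": 0, "candidate_atypical": 1, "detected": 2}[c.verdict])
    return best.verdict


class TestDetect:
    def test_planted_hydf_with_all_four_motifs_detected(self, profiles, motif_catalog, maturase_world):
        ancestors, planted = maturase_world
        calls = detect_maturation(
            _proteome([planted["HydF"]]), _queries(ancestors, ["HydF"]),
            profiles, motif_catalog, genome_id="g",
        )
        assert _verdict(calls, "HydF") == "detected"

    def test_hydg_atypical_cterm_variant_is_candidate(self, profiles, motif_catalog, maturase_world):
        ancestors, planted = maturase_world
        calls = detect_maturation(
            _proteome([planted["HydG_variant"]]), _queries(ancestors, ["HydG"]),
            profiles, motif_catalog, genome_id="g",
        )
        assert _verdict(calls, "HydG") == "candidate_atypical"
        (call,) = [c for c in calls if c.locus_tag]
        assert call.atypical_slots == ["cterm_fes"]

    def test_radical_sam_without_cterm_triad_not_called_hydg(self, profiles, motif_catalog, maturase_world):
        """A close homolog carrying the radical-SAM core but no C-terminal
        Cys triad must not be reported as HydG."""
        ancestors, _ = maturase_world
        rng = random.Random(5)
        near_miss = mutate(rng, ancestors["HydG"], 0.04)
        from hydromine.motifs import scan
        from hydromine.synthetic import realize_pattern, splice

        core = realize_pattern(rng, motif_catalog.require_role("radical_sam")[0])
        near_miss = splice(near_miss, core, 50)
        calls = detect_maturation(
            _proteome([near_miss]), _queries(ancestors, ["HydG"]),
            profiles, motif_catalog, genome_id="g",
        )
        assert _verdict(calls, "HydG") == "absent"

    def test_hyde_detected_without_optional_cterm(self, profiles, motif_catalog, maturase_world):
        ancestors, _ = maturase_world
        rng = random.Random(6)
        from hydromine.synthetic import realize_pattern, splice

        seq = mutate(rng, ancestors["HydE"], 0.04)
        seq = splice(seq, realize_pattern(rng, motif_catalog.require_role("radical_sam")[0]), 50)
        calls = detect_maturation(
            _proteome([seq]), _queries(ancestors, ["HydE"]), profiles, motif_catalog, genome_id="g"
        )
        assert _verdict(calls, "HydE") == "detected"

    def test_hypb_gtpase_flag_fires_iff_ploop_present(self, profiles, motif_catalog, maturase_world):
        ancestors, planted = maturase_world
        with_ploop = detect_maturation(
            _proteome([planted["HypB"]]), _queries(ancestors, ["HypB"]),
            profiles, motif_catalog, genome_id="g",
        )
        assert _verdict(with_ploop, "HypB") == "detected"
        assert [c.gtpase for c in with_ploop if c.locus_tag] == [True]
        rng = random.Random(7)
        without = mutate(rng, ancestors["HypB"], 0.04)
        no_ploop = detect_maturation(
            _proteome([without]), _queries(ancestors, ["HypB"]),
            profiles, motif_catalog, genome_id="g",
        )
        assert [c.gtpase for c in no_ploop if c.locus_tag] == [False]

    def test_unrelated_proteins_absent(self, profiles, motif_catalog, maturase_world):
        ancestors, _ = maturase_world
        rng = random.Random(8)
        proteome = _proteome(
            [_motif_free_sequence(rng, 250, motif_catalog) for _ in range(4)]
        )
        calls = detect_maturation(proteome, _queries(ancestors), profiles, motif_catalog, genome_id="g")
        assert all(c.verdict == "absent" for c in calls)

    def test_paralogs_both_reported(self, profiles, motif_catalog, maturase_world):
        ancestors, planted = maturase_world
        rng = random.Random(9)
        second = _maturase_sequence(rng, motif_catalog, "HydF", ancestors["HydF"], "intact")
        calls = detect_maturation(
            _proteome([planted["HydF"], second]), _queries(ancestors, ["HydF"]),
            profiles, motif_catalog, genome_id="g",
        )
        assert sorted(c.locus_tag for c in calls) == ["m0", "m1"]

    def test_missing_profile_is_configuration_error(self, profiles, motif_catalog):
        from hydromine.core import ConfigurationError

        with pytest.raises(ConfigurationError):
            detect_maturation(_proteome(["MKVL" * 30]), [("NovelProt", "MKVL" * 30)], profiles, motif_catalog)


class TestMonotonicity:
    def test_ablating_any_required_hydf_motif_demotes(self, profiles, motif_catalog, maturase_world):
        """Conjunctive slots: removing any one required signature from a
        detected HydF drops the verdict."""
        ancestors, _ = maturase_world
        rng = random.Random(10)
        from hydromine.synthetic import realize_pattern, splice

        anc = ancestors["HydF"]
        n = len(anc)
        placements = {
            "hydf_ploop": 10, "hydf_switch": 60, "hydf_nkxd": 100, "hydf_cterm": n - 70,
        }
        for omitted in placements:
            seq = mutate(rng, anc, 0.04)
            for role, pos in placements.items():
                if role == omitted:
                    continue
                seq = splice(seq, realize_pattern(rng, motif_catalog.require_role(role)[0]), pos)
            calls = detect_maturation(
                _proteome([seq]), _queries(ancestors, ["HydF"]), profiles, motif_catalog, genome_id="g"
            )
            assert _verdict(calls, "HydF") == "absent", omitted


class TestCompleteness:
    def _calls(self, present, genome="g"):
        calls = []
        for name, verdict in present.items():
            calls.append(MaturationCall(genome, name, f"loc_{name}" if verdict != "absent" else None, verdict))
        return calls

    def test_all_nine_complete(self):
        calls = self._calls({n: "detected" for n in
                             ("HydE", "HydF", "HydG", "HypA", "HypB", "HypC", "HypD", "HypE", "HypF")})
        statuses = {s.machinery: s for s in maturation_completeness(calls, "g")}
        assert statuses["FeFe"].complete and statuses["NiFe"].complete

    def test_hypa_hypb_missing(self):
        present = {n: "detected" for n in ("HydE", "HydF", "HydG", "HypC", "HypD", "HypE", "HypF")}
        present.update({"HypA": "absent", "HypB": "absent"})
        statuses = {s.machinery: s for s in maturation_completeness(self._calls(present), "g")}
        assert statuses["FeFe"].complete
        assert not statuses["NiFe"].complete
        assert statuses["NiFe"].missing == ["HypA", "HypB"]

    def test_atypical_hydg_does_not_complete_machinery(self):
        present = {n: "detected" for n in ("HydE", "HydF")}
        present["HydG"] = "candidate_atypical"
        statuses = {s.machinery: s for s in maturation_completeness(self._calls(present), "g")}
        assert not statuses["FeFe"].complete
        assert statuses["FeFe"].missing == ["HydG"]
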