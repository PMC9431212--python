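"""Catalytic-subunit validation, neighborhoods, roles, diaphorase profiling."""

import pytest

from hydromine.classify import ClassAssignment
from hydromine.core import AnnotationTable, GeneFeature, GenomeFeatures, HydClass, ProteinRecord
from hydromine.validation import (
    DEFAULT_TEMPLATES,
    HydrogenaseCall,
    check_tat_signal,
    diaphorase_profile,
    find_small_subunit,
    neighborhood,
    validate_fefe,
    validate_nife,
)


def _features(tags, contig="c1"):
    genes = []
    for i, (tag, seq, product) in enumerate(tags):
        rec = ProteinRecord(protein_id=tag, locus_tag=tag, sequence=seq,
                            contig_id=contig, start=1 + i * 1000, end=900 + i * 1000)
        genes.append(GeneFeature(locus_tag=tag, contig_id=contig, start=rec.start,
                                 end=rec.end, strand="+", product=product, record=rec))
    return GenomeFeatures(genome_id="g", contigs={contig: genes})


def _call(seq, metal="FeFe", token="A3"):
    cls = HydClass.parse(metal, token)
    anchor = ProteinRecord(protein_id="anchor", locus_tag="anchor", sequence=seq)
    assignment = ClassAssignment(query_id="anchor", predicted_class=cls, n_hits_used=4)
    return HydrogenaseCall(anchor=anchor, assignment=assignment)


# H-cluster motif instances satisfying the bundled P1/P2/P3 consensus strings
P1, P2, P3 = "TSCCPVW", "MPCTAKKAE", "EFMACAAGCAGG"
PAD = "LNQRSTVE"


def _fefe_seq(p1=P1, p2=P2, p3=P3):
    return (PAD * 5) + p1 + (PAD * 5) + p2 + (PAD * 5) + p3 + (PAD * 5)


class TestNeighborhood:
    def _ten_genes(self):
        return _features([(f"g{i}", "MKVL", "") for i in range(11)])

    def test_mid_contig_full_window(self):
        nbhd = neighborhood("g5", self._ten_genes(), window_size=5)
        assert len(nbhd.flanking) == 10
        assert [off for _, off in nbhd.flanking] == [-5, -4, -3, -2, -1, 1, 2, 3, 4, 5]

    def test_contig_edge_truncates(self):
        nbhd = neighborhood("g0", self._ten_genes(), window_size=5)
        assert [off for _, off in nbhd.flanking] == [1, 2, 3, 4, 5]

    def test_window_one(self):
        nbhd = neighborhood("g5", self._ten_genes(), window_size=1)
        assert len(nbhd.flanking) == 2

    def test_nearest_first_order(self):
        nbhd = neighborhood("g5", self._ten_genes(), window_size=3)
        assert [off for _, off in nbhd.nearest_first()] == [-1, 1, -2, 2, -3, 3]


class TestValidateFefe:
    def test_all_three_planted_validated(self, motif_catalog):
        call = validate_fefe(_call(_fefe_seq()), motif_catalog)
        assert call.validation_status == "validated"
        assert all(call.motif_evidence[f"h_cluster_p{i}"] for i in (1, 2, 3))

    @pytest.mark.parametrize("ablated", ["p1", "p2", "p3"])
    def test_ablating_any_slot_rejects(self, motif_catalog, ablated):
        kwargs = {ablated: PAD[:len({"p1": P1, "p2": P2, "p3": P3}[ablated])]}
        call = validate_fefe(_call(_fefe_seq(**kwargs)), motif_catalog)
        assert call.validation_status == "rejected"

    def test_two_of_three_rejected_under_all_three_but_not_any_one(self, motif_catalog):
        seq = _fefe_seq(p3="L" * len(P3))
        assert validate_fefe(_call(seq), motif_catalog, mode="all_three").validation_status == "rejected"
        assert validate_fefe(_call(seq), motif_catalog, mode="any_one").validation_status == "validated"

    def test_motif_free_decoy_rejected_under_both_modes(self, motif_catalog):
        for mode in ("all_three", "any_one"):
            assert validate_fefe(_call(PAD * 20), motif_catalog, mode=mode).validation_status == "rejected"

    def test_wrong_metal_type_rejected(self, motif_catalog):
        with pytest.raises(ValueError):
            validate_fefe(_call(_fefe_seq(), metal="NiFe", token="1a"), motif_catalog)


SMALL_FES = "CAACAAAC"  # satisfies C-x-x-C-x-x-x-C


class TestFindSmallSubunit:
    def _setup(self, small_seq=None, annotate=True):
        small = small_seq if small_seq is not None else PAD * 6 + SMALL_FES + PAD * 6
        feats = _features([
            ("large", _fefe_seq(), "NiFe hydrogenase large subunit"),
            ("small", small, "hypothetical"),
            ("other", PAD * 10, "hypothetical"),
        ])
        ann = AnnotationTable()
        if annotate:
            ann.add("small", "synth", "NiFe hydrogenase small subunit")
        return neighborhood("large", feats), ann

    def test_annotated_with_motif_found(self, motif_catalog):
        nbhd, ann = self._setup()
        assert find_small_subunit(nbhd, ann, motif_catalog) == "small"

    def test_annotated_but_motif_ablated_skipped(self, motif_catalog):
        nbhd, ann = self._setup(small_seq=PAD * 12)
        assert find_small_subunit(nbhd, ann, motif_catalog) is None

    def test_unannotated_skipped(self, motif_catalog):
        nbhd, ann = self._setup(annotate=False)
        assert find_small_subunit(nbhd, ann, motif_catalog) is None

    def test_nearest_of_two_qualifying(self, motif_catalog):
        small = PAD * 6 + SMALL_FES + PAD * 6
        feats = _features([
            ("far", small, ""), ("near", small, ""), ("large", _fefe_seq(), ""),
        ])
        ann = AnnotationTable()
        for tag in ("far", "near"):
            ann.add(tag, "synth", "NiFe hydrogenase small subunit")
        nbhd = neighborhood("large", feats)
        assert find_small_subunit(nbhd, ann, motif_catalog) == "near"


L1, L2 = "RICGVCAAAH", "DPCLACAVH"  # satisfy the bundled L1/L2 consensus


def _nife_operon(l_ok=True, small_motif=True, annotate=True):
    large = PAD * 5 + (L1 if l_ok else "A" * len(L1)) + PAD * 5 + L2 + PAD * 5
    small = PAD * 6 + (SMALL_FES if small_motif else "") + PAD * 6
    feats = _features([
        ("large", large, "NiFe hydrogenase large subunit"),
        ("small", small, "hypothetical"),
    ])
    ann = AnnotationTable()
    if annotate:
        ann.add("small", "synth", "NiFe hydrogenase small subunit")
    call = _call(large, metal="NiFe", token="1a")
    call.anchor = feats.gene("large").record
    return call, feats, ann


class TestValidateNife:
    def test_planted_pair_validated(self, motif_catalog):
        call, feats, ann = _nife_operon()
        validate_nife(call, neighborhood("large", feats), ann, motif_catalog)
        assert call.validation_status == "validated"
        assert call.small_subunit_locus == "small"
        assert call.tat_signal is False  # generator-style subunits carry no Tat signal

    def test_missing_l_motif_rejected(self, motif_catalog):
        call, feats, ann = _nife_operon(l_ok=False)
        validate_nife(call, neighborhood("large", feats), ann, motif_catalog)
        assert call.validation_status == "rejected"

    def test_no_small_subunit_rejected(self, motif_catalog):
        call, feats, ann = _nife_operon(small_motif=False)
        validate_nife(call, neighborhood("large", feats), ann, motif_catalog)
        assert call.validation_status == "rejected"
        assert "small-subunit" in call.warnings[0]


class TestTatSignal:
    def test_nterminal_match(self, motif_catalog):
        rec = ProteinRecord(protein_id="s", locus_tag="s", sequence="MGSRRQFLKAA" + "L" * 60)
        ok, matches = check_tat_signal(rec, motif_catalog)
        assert ok and matches[0].start == 4

    def test_cterminal_occurrence_does_not_count(self, motif_catalog):
        rec = ProteinRecord(protein_id="s", locus_tag="s", sequence="M" + "L" * 80 + "RRQFLK")
        ok, _ = check_tat_signal(rec, motif_catalog)
        assert not ok


class TestRolesAndOrientation:
    def _a3_trio(self, reverse=False):
        dia = PAD * 6 + "RGGGGFP" + PAD * 4 + "ADEGDPG" + PAD * 8
        genes = [
            ("cat", _fefe_seq(), "FeFe hydrogenase catalytic subunit"),
            ("dia", dia, "iron-sulfur flavoprotein (NuoF-like cofactor-binding subunit)"),
            ("trx", PAD * 8, "thioredoxin"),
        ]
        if reverse:
            genes = genes[::-1]
        feats = _features(genes)
        ann = AnnotationTable()
        ann.add("dia", "synth", "NuoF-like subunit COG1894")
        ann.add("trx", "synth", "thioredoxin")
        return feats, ann

    def test_trio_roles_assigned(self, motif_catalog):
        from hydromine.validation import assign_subunit_roles

        feats, ann = self._a3_trio()
        call = _call(_fefe_seq())
        call.anchor = feats.gene("cat").record
        call.validation_status = "validated"
        assign_subunit_roles(call, neighborhood("cat", feats), ann, DEFAULT_TEMPLATES["A3"])
        assert call.role_map == {"catalytic": "cat", "diaphorase": "dia", "thioredoxin": "trx"}
        assert call.validation_status == "validated"

    def test_roles_invariant_under_contig_reversal(self, motif_catalog):
        from hydromine.validation import assign_subunit_roles

        maps = []
        for reverse in (False, True):
            feats, ann = self._a3_trio(reverse=reverse)
            call = _call(_fefe_seq())
            call.anchor = feats.gene("cat").record
            call.validation_status = "validated"
            assign_subunit_roles(call, neighborhood("cat", feats), ann, DEFAULT_TEMPLATES["A3"])
            maps.append(call.role_map)
        assert maps[0] == maps[1]

    def test_missing_role_downgrades_with_warning(self, motif_catalog):
        from hydromine.validation import assign_subunit_roles

        feats, ann = self._a3_trio()
        ann.entries.pop("trx")
        feats.gene("trx").product = "hypothetical"
        call = _call(_fefe_seq())
        call.anchor = feats.gene("cat").record
        call.validation_status = "validated"
        assign_subunit_roles(call, neighborhood("cat", feats), ann, DEFAULT_TEMPLATES["A3"])
        assert call.validation_status == "validated_with_warnings"
        assert any("thioredoxin" in w for w in call.warnings)


class TestDiaphoraseProfile:
    def _profile(self, nterm, loop, motif_catalog):
        seq = PAD * 6 + nterm + PAD * 4 + loop + PAD * 8
        rec = ProteinRecord(protein_id="d", locus_tag="d", sequence=seq)
        return diaphorase_profile(rec, AnnotationTable(), motif_catalog)

    def test_a4_gly_form_is_nadp(self, motif_catalog):
        p = self._profile("RGGAGFP", "GDEGDPG", motif_catalog)
        assert (p.nterm_loop, p.rossmann_loop, p.cofactor_hypothesis) == (
            "A4-type", "G-type", "NADP-associated",
        )

    def test_a3_ala_form_is_nad(self, motif_catalog):
        p = self._profile("RGGGGFP", "ADEGDPG", motif_catalog)
        assert (p.nterm_loop, p.rossmann_loop, p.cofactor_hypothesis) == (
            "A3-type", "A-type", "NAD-associated",
        )

    def test_a3_with_gly_loop_exception_is_nadp(self, motif_catalog):
        # the exception pattern: A3-type N-terminal loop with the Gly-form
        # Rossmann loop still reads as NADP-associated
        p = self._profile("RGGGGFP", "GDEGDPG", motif_catalog)
        assert (p.nterm_loop, p.cofactor_hypothesis) == ("A3-type", "NADP-associated")

    def test_neither_loop_undetermined(self, motif_catalog):
        p = self._profile(PAD[:7], PAD[:7], motif_catalog)
        assert (p.nterm_loop, p.rossmann_loop, p.cofactor_hypothesis) == (
            "absent", "absent", "undetermined",
        )
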