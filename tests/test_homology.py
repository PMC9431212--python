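"""Hit search, best-first sorting, and hit selection (E and identity gates)."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydromine.align import bitscore, evalue
from hydromine.core import HydClass, ProteinRecord
from hydromine.homology import (
    AlignmentHit,
    filter_hits,
    hits_from_blast,
    hits_to_blast_rows,
    search,
    sort_hits,
)
from hydromine.io import read_blast_tab, write_blast_tab
from hydromine.reference import ClassThresholdTable, ReferenceCatalog, ReferenceEntry

A3 = HydClass("FeFe", "A", "A3")
B = HydClass("FeFe", "B")


def _hit(pident=90.0, e=1e-20, qlen=300, subject="s1", cls=A3, alen=250):
    return AlignmentHit(
        query_id="q1",
        subject_id=subject,
        subject_class=cls,
        percent_identity=pident,
        e_value=e,
        alignment_length=alen,
        query_length=qlen,
        bitscore=bitscore(100.0),
    )


def _catalog(rng, n=4, length=120):
    entries = []
    for i in range(n):
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
        entries.append(ReferenceEntry(f"r{i}", seq, A3 if i % 2 == 0 else B))
    return ReferenceCatalog(entries=entries)


class TestSearch:
    def test_self_hit_is_top_with_full_identity(self):
        rng = random.Random(0)
        catalog = _catalog(rng)
        query = ProteinRecord(protein_id="q", locus_tag="q", sequence=catalog.entries[0].sequence)
        hits = search([query], catalog)["q"]
        assert hits[0].subject_id == "r0"
        assert hits[0].percent_identity == 100.0

    def test_planted_homolog_beats_random_queries(self):
        rng = random.Random(1)
        catalog = _catalog(rng, n=3, length=200)
        planted = ProteinRecord(
            protein_id="p", locus_tag="p",
            sequence=catalog.entries[0].sequence[:190] + "AAAAAAAAAA",
        )
        randoms = [
            ProteinRecord(
                protein_id=f"x{i}", locus_tag=f"x{i}",
                sequence="".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200)),
            )
            for i in range(5)
        ]
        grouped = search([planted] + randoms, catalog)
        planted_e = grouped["p"][0].e_value
        for rec in randoms:
            for hit in grouped.get(rec.locus_tag, []):
                assert hit.e_value >= planted_e

    def test_empty_proteome(self):
        assert search([], _catalog(random.Random(2))) == {}

    def test_evalue_monotone_in_score(self):
        es = [evalue(s, 300, 10_000) for s in range(50, 500, 50)]
        assert es == sorted(es, reverse=True)

    def test_blast_tab_round_trip_preserves_downstream_fields(self, tmp_path):
        rng = random.Random(3)
        catalog = _catalog(rng)
        query = ProteinRecord(protein_id="q", locus_tag="q", sequence=catalog.entries[1].sequence)
        direct = search([query], catalog)["q"]
        p = tmp_path / "hits.tsv"
        write_blast_tab(p, hits_to_blast_rows(direct))
        ingested = hits_from_blast(read_blast_tab(p), catalog, [query])["q"]
        assert [
            (h.subject_id, h.percent_identity, h.e_value, h.subject_class.label)
            for h in ingested
        ] == [
            (h.subject_id, h.percent_identity, h.e_value, h.subject_class.label)
            for h in direct
        ]


class TestSortHits:
    def test_identity_then_evalue(self):
        hits = [
            _hit(pident=80.0, e=1e-40, subject="a"),
            _hit(pident=95.0, e=1e-3, subject="b"),
            _hit(pident=95.0, e=1e-9, subject="c"),
        ]
        assert [h.subject_id for h in sort_hits(hits)] == ["c", "b", "a"]

    def test_subject_id_tiebreak(self):
        hits = [_hit(subject=s) for s in ("z", "a", "m")]
        assert [h.subject_id for h in sort_hits(hits)] == ["a", "m", "z"]

    @settings(max_examples=50, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariant(self, rnd):
        hits = [
            _hit(pident=p, e=e, qlen=q, subject=s)
            for p, e, q, s in [
                (95.0, 1e-9, 300, "a"), (95.0, 1e-9, 200, "b"), (80.0, 1e-3, 300, "c"),
                (80.0, 1e-3, 300, "d"), (99.9, 1e-50, 100, "e"),
            ]
        ]
        shuffled = hits[:]
        rnd.shuffle(shuffled)
        assert sort_hits(shuffled) == sort_hits(hits)


class TestFilterHits:
    def _thresholds(self):
        return ClassThresholdTable(thresholds={A3.label: 40.0}, fallback=25.0)

    def test_e_boundary_inclusive(self):
        keep = _hit(pident=90.0, e=0.01)
        drop = _hit(pident=90.0, e=0.02)
        assert filter_hits([keep, drop], self._thresholds()) == [keep]

    def test_identity_strictly_greater(self):
        at_threshold = _hit(pident=40.0, e=1e-30)
        above = _hit(pident=41.0, e=0.01)
        assert filter_hits([at_threshold, above], self._thresholds()) == [above]

    def test_fallback_for_unknown_class(self):
        hit = _hit(pident=26.0, e=1e-5, cls=B)
        assert filter_hits([hit], self._thresholds()) == [hit]
        assert filter_hits([_hit(pident=25.0, e=1e-5, cls=B)], self._thresholds()) == []

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_every_retained_hit_satisfies_both_predicates(self, seed):
        rng = random.Random(seed)
        thresholds = self._thresholds()
        hits = sort_hits(
            [
                _hit(
                    pident=round(rng.uniform(0, 100), 2),
                    e=10 ** rng.uniform(-50, 1),
                    subject=f"s{i}",
                    cls=A3 if rng.random() < 0.5 else B,
                )
                for i in range(20)
            ]
        )
        retained = filter_hits(hits, thresholds)
        for h in retained:
            assert h.e_value <= 0.01
            assert h.percent_identity > thresholds.threshold_for(h.subject_class)
        # idempotent and order-preserving
        assert filter_hits(retained, thresholds) == retained
        assert retained == [h for h in hits if h in retained]


def test_hit_invariants_enforced():
    with pytest.raises(ValueError):
        _hit(pident=101.0)
    with pytest.raises(ValueError):
        _hit(e=-1.0)
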