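"""Unit and property tests for the matrisome classification rule engine."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import planmat as pm
from planmat.annotate import (
    AnnotationConfig,
    apply_exclusions,
    assign_confidence,
    assign_gpi,
    categorize_by_blast,
    categorize_by_domains,
    deduplicate_domains,
    filter_transmembrane,
    reciprocal_best_hits,
    reconcile_categories,
    representative_contig,
)
from planmat.types import (
    BlastHit,
    DomainCatalog,
    DomainHit,
    HumanMatrisomeMap,
    MatrisomeCall,
    ProteinRecord,
    to_dataframe,
)


def hit(domain, ev, start, end, contig="c1", desc="d"):
    return DomainHit(contig, domain, desc, ev, start, end)


class TestDeduplicateDomains:
    def test_identical_intervals_keep_lowest_evalue(self):
        out = deduplicate_domains([hit("A", 1e-3, 1, 50), hit("A", 1e-5, 1, 50)])
        assert len(out) == 1 and out[0].evalue == 1e-5

    def test_overlap_resolved_by_evalue_rank(self):
        # A[1,50] best, B overlaps A and loses, C is disjoint
        a, b, c = hit("A", 1e-8, 1, 50), hit("B", 1e-4, 40, 90), hit("C", 1e-2, 100, 150)
        out = deduplicate_domains([b, c, a])
        assert [h.domain_id for h in out] == ["A", "C"]

    def test_non_overlapping_unchanged(self):
        hits = [hit("A", 1e-3, 1, 10), hit("B", 1e-2, 20, 30)]
        assert deduplicate_domains(hits) == hits

    def test_empty(self):
        assert deduplicate_domains([]) == []

    def test_mixed_contigs_rejected(self):
        with pytest.raises(ValueError):
            deduplicate_domains([hit("A", 1e-3, 1, 10), hit("B", 1e-3, 1, 10, contig="c2")])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ABCDEFGH"),
                st.floats(1e-30, 0.5),
                st.integers(1, 80),
                st.integers(1, 40),
            ),
            max_size=8,
        )
    )
    def test_greedy_selection_properties(self, raw):
        """Output intervals are pairwise disjoint and every kept hit has the
        minimum selection rank among the input hits it overlaps."""
        hits = [hit(d, e, s, s + ln) for d, e, s, ln in raw]
        out = deduplicate_domains(hits)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert not a.overlaps(b)
        # oracle: independent select-and-eliminate formulation of the rule —
        # repeatedly take the best remaining hit and discard what it overlaps
        remaining = sorted(hits, key=lambda h: (h.evalue, -(h.end - h.start), h.domain_id))
        expected = []
        while remaining:
            best = remaining.pop(0)
            expected.append(best)
            remaining = [h for h in remaining if not h.overlaps(best)]
        assert sorted(out, key=lambda h: (h.start, h.end, h.domain_id)) == sorted(
            expected, key=lambda h: (h.start, h.end, h.domain_id)
        )
        # every dropped hit overlaps some kept hit with a better selection rank
        rank = {
            h: i
            for i, h in enumerate(
                sorted(hits, key=lambda h: (h.evalue, -(h.end - h.start), h.domain_id))
            )
        }
        for h in hits:
            if h not in out:
                assert any(h.overlaps(k) and rank[k] < rank[h] for k in out)


class TestCategorizeByDomains:
    def test_majority_wins(self, catalog):
        hits = [hit("IPR008160", 1e-9, 1, 60), hit("IPR000885", 1e-9, 70, 140),
                hit("IPR000215", 1e-9, 150, 220)]
        cat, tie = categorize_by_domains(hits, catalog)
        assert cat == "core" and not tie

    def test_tie_resolves_by_priority_and_flags(self, catalog):
        hits = [hit("IPR008160", 1e-9, 1, 60), hit("IPR000215", 1e-9, 70, 140)]
        cat, tie = categorize_by_domains(hits, catalog)
        assert cat == "core" and tie

    def test_no_defining_domains(self, catalog):
        assert categorize_by_domains([hit("IPR999999", 1e-9, 1, 60)], catalog) == (None, False)


class TestExclusions:
    def test_kinase_domain_excludes(self, catalog):
        hits = [hit("IPR008160", 1e-9, 1, 60), hit("IPR000719", 1e-9, 70, 140)]
        cat, reason = apply_exclusions("core", hits, catalog)
        assert cat is None and "IPR000719" in reason

    def test_til_exception_retained(self, catalog):
        """TIL (IPR002919) would veto the core matrisome but is on the
        planarian exception list, so a mucin-like contig survives."""
        hits = [hit("IPR001846", 1e-9, 1, 60), hit("IPR002919", 1e-9, 70, 140)]
        assert apply_exclusions("core", hits, catalog) == ("core", None)

    def test_no_excluding_domains(self, catalog):
        hits = [hit("IPR008160", 1e-9, 1, 60)]
        assert apply_exclusions("core", hits, catalog) == ("core", None)

    def test_exception_list_purged_on_load(self, catalog):
        assert not (catalog.exceptions & set(catalog.excluding))


class TestCategorizeByBlast:
    MAP = HumanMatrisomeMap({"P1": "core", "P2": "regulator", "P3": "non_matrisome"})

    def test_strong_hit_maps_category(self):
        hits = [BlastHit("c1", "P1", 1e-30, 200, "blastx")]
        assert categorize_by_blast(hits, self.MAP) == "core"

    def test_threshold_is_strict(self):
        assert categorize_by_blast([BlastHit("c1", "P1", 0.05, 50, "blastx")], self.MAP) is None

    def test_best_hit_by_evalue(self):
        hits = [BlastHit("c1", "P2", 1e-3, 60, "blastx"),
                BlastHit("c1", "P1", 1e-10, 120, "tblastn")]
        assert categorize_by_blast(hits, self.MAP) == "core"

    def test_non_matrisome_best_hit(self):
        assert categorize_by_blast([BlastHit("c1", "P3", 1e-30, 300, "blastx")], self.MAP) is None


class TestReciprocalBestHits:
    def test_mutual_best(self):
        fwd = [BlastHit("A", "P", 1e-20, 100, "blastx")]
        rev = [BlastHit("P", "A", 1e-20, 100, "tblastn")]
        assert reciprocal_best_hits(fwd, rev) == {("A", "P")}

    def test_one_sided_best_excluded(self):
        fwd = [BlastHit("A", "P", 1e-20, 100, "blastx")]
        rev = [BlastHit("P", "B", 1e-30, 150, "tblastn"),
               BlastHit("P", "A", 1e-10, 80, "tblastn")]
        assert reciprocal_best_hits(fwd, rev) == set()

    def test_three_by_three_single_pair(self):
        """Exhaustive 3-contig / 3-protein table with exactly one mutual pair."""
        fwd = [
            BlastHit("A", "P1", 1e-30, 200, "blastx"),
            BlastHit("A", "P2", 1e-5, 50, "blastx"),
            BlastHit("B", "P1", 1e-10, 90, "blastx"),
            BlastHit("C", "P3", 1e-8, 70, "blastx"),
        ]
        rev = [
            BlastHit("P1", "A", 1e-30, 200, "tblastn"),
            BlastHit("P2", "B", 1e-9, 60, "tblastn"),
            BlastHit("P3", "A", 1e-12, 100, "tblastn"),
        ]
        assert reciprocal_best_hits(fwd, rev) == {("A", "P1")}


class TestReconcile:
    @pytest.mark.parametrize(
        "dom,bla,expect,conflict",
        [
            ("core", "core", "core", False),
            ("regulator", "core", "regulator", True),
            (None, "secreted", "secreted", False),
            ("affiliated", None, "affiliated", False),
        ],
    )
    def test_rules(self, dom, bla, expect, conflict):
        assert reconcile_categories(dom, bla) == (expect, conflict)

    def test_both_absent_raises(self):
        with pytest.raises(ValueError):
            reconcile_categories(None, None)


def _call(category="core"):
    return MatrisomeCall("c1", category=category, confidence="low", provenance={"domain"})


class TestTransmembraneFilter:
    def test_sp_like_segment_retained(self, catalog):
        rec = ProteinRecord("c1", 400, signal_peptide=True, sp_cleavage_pos=24,
                            tm_segments=[(7, 29)])
        call = filter_transmembrane(rec, _call(), catalog)
        assert call.category == "core" and "tm_removed" not in call.flags

    def test_collagen_keep_list(self, catalog):
        rec = ProteinRecord("c1", 400, signal_peptide=True, sp_cleavage_pos=24,
                            tm_segments=[(300, 322)])
        hits = [hit("IPR008160", 1e-9, 1, 60)]
        call = filter_transmembrane(rec, _call(), catalog, hits)
        assert call.category == "core" and "keep_list" in call.flags

    def test_glycoprotein_with_tm_excluded(self, catalog):
        rec = ProteinRecord("c1", 400, signal_peptide=True, sp_cleavage_pos=24,
                            tm_segments=[(300, 322)])
        hits = [hit("IPR002035", 1e-9, 1, 60)]
        call = filter_transmembrane(rec, _call(), catalog, hits)
        assert call.category is None and "tm_removed" in call.flags

    def test_fallback_window_without_cleavage_site(self, catalog):
        rec = ProteinRecord("c1", 400, signal_peptide=True, tm_segments=[(30, 52)])
        call = filter_transmembrane(rec, _call(), catalog, sp_window=35)
        assert call.category == "core"


class TestGpi:
    def test_gpi_forces_affiliated(self):
        rec = ProteinRecord("c1", 300, gpi_anchor=True)
        call = assign_gpi(rec, _call("core"))
        assert call.category == "affiliated" and "gpi" in call.provenance

    def test_no_gpi_unchanged(self):
        call = assign_gpi(ProteinRecord("c1", 300), _call("core"))
        assert call.category == "core" and "gpi" not in call.provenance

    def test_excluded_stays_excluded(self):
        call = MatrisomeCall("c1")
        call.exclude("tm", "tm_removed")
        out = assign_gpi(ProteinRecord("c1", 300, gpi_anchor=True), call)
        assert out.category is None and out.confidence == "excluded"


class TestConfidence:
    CFG = AnnotationConfig()

    def run(self, record, has_def=True, rbh=False):
        return assign_confidence(record, _call(), has_def, rbh, self.CFG)

    def test_sp_plus_defining_domain_is_high(self):
        rec = ProteinRecord("c1", 400, signal_peptide=True, sp_cleavage_pos=22)
        assert self.run(rec).confidence == "high"

    def test_defining_domain_without_sp_is_low(self):
        assert self.run(ProteinRecord("c1", 400)).confidence == "low"

    def test_rbh_without_sp_is_high(self):
        assert self.run(ProteinRecord("c1", 400), rbh=True).confidence == "high"

    def test_small_secreted_factor_is_low(self):
        rec = ProteinRecord("c1", 150, signal_peptide=True, sp_cleavage_pos=20)
        call = self.run(rec, has_def=False)
        assert call.confidence == "low" and "confidence_rule:4" in call.flags

    def test_intracellular_pathway_list_is_low(self):
        cfg = AnnotationConfig(intracellular_pathway_contigs=frozenset({"c1"}))
        rec = ProteinRecord("c1", 400, signal_peptide=True, sp_cleavage_pos=22)
        call = assign_confidence(rec, _call(), True, False, cfg)
        assert call.confidence == "low" and "confidence_rule:5" in call.flags


class TestRepresentativeContig:
    def test_largest_read_count_wins(self):
        group = [ProteinRecord("A", 100, avg_read_count=3.1),
                 ProteinRecord("B", 100, avg_read_count=0.4)]
        assert representative_contig(group) == ("A", False)

    def test_singleton(self):
        assert representative_contig([ProteinRecord("X", 50, avg_read_count=0.0)]) == ("X", False)

    def test_tie_breaks_lexicographically_with_flag(self):
        group = [ProteinRecord("B", 100, avg_read_count=2.0),
                 ProteinRecord("A", 100, avg_read_count=2.0)]
        assert representative_contig(group) == ("A", True)


class TestAnnotatePipeline:
    def test_truth_recovered_on_synthetic_bundle(self, default_bundle, catalog):
        bundle, human_map, truth = default_bundle
        calls = pm.annotate_matrisome(bundle, catalog, human_map)
        df = to_dataframe(calls).merge(truth.table, on="contig_id")
        non_conflict = df[df["class"] != "conflict"]
        assert (non_conflict["category"] == non_conflict["true_category"]).all()
        retained = df[df["confidence"] != "excluded"]
        assert (retained["confidence"] == retained["true_confidence"]).all()

    def test_pure_decoy_bundle_retains_nothing(self, catalog):
        bundle, human_map, _ = pm.gen_evidence_bundle(
            {"kinase_decoy": 10, "tm_receptor_decoy": 10, "intracellular_decoy": 10},
            seed=2,
        )
        calls = pm.annotate_matrisome(bundle, catalog, pm.HumanMatrisomeMap(human_map))
        assert sum(c.retained for c in calls) == 0

    def test_idempotent_and_row_order_independent(self, catalog):
        bundle, human_map, _ = pm.gen_evidence_bundle(5, seed=3)
        hm = pm.HumanMatrisomeMap(human_map)
        ref = to_dataframe(pm.annotate_matrisome(bundle, catalog, hm))
        again = to_dataframe(pm.annotate_matrisome(bundle, catalog, hm))
        shuffled = copy.deepcopy(bundle)
        for contig in shuffled.domain_hits:
            shuffled.domain_hits[contig] = shuffled.domain_hits[contig][::-1]
        shuffled.blast_reverse = shuffled.blast_reverse[::-1]
        third = to_dataframe(pm.annotate_matrisome(shuffled, catalog, hm))
        assert ref.equals(again) and ref.equals(third)

    def test_exclusion_is_terminal_and_calls_are_consistent(self, default_bundle, catalog):
        bundle, human_map, _ = default_bundle
        for call in pm.annotate_matrisome(bundle, catalog, human_map):
            call.validate()
            if call.retained:
                assert call.category in ("core", "affiliated", "regulator", "secreted")
                assert not ({"excluding_domain", "tm_removed"} & call.flags)
                assert call.provenance
            if call.exclusion_reason:
                for exc in catalog.exceptions:
                    assert exc not in call.exclusion_reason

    def test_missing_evidence_table_named(self, catalog):
        bundle = pm.EvidenceBundle()
        bundle.records = None
        with pytest.raises(ValueError, match="records"):
            pm.annotate_matrisome(bundle, catalog, HumanMatrisomeMap())


class TestLongestOrf:
    def test_single_embedded_orf(self):
        seq = "CCC" + "ATG" + "GCTGCAGAA" * 12 + "TAA" + "GGG"
        orf = pm.longest_orf(seq, min_aa=30)
        assert orf is not None
        assert orf.protein.startswith("M") and len(orf.protein) == 37
        assert orf.frame == 1

    def test_all_n_sequence(self):
        assert pm.longest_orf("N" * 300) is None

    def test_forward_frame_preferred_on_equal_length(self):
        fwd = "ATG" + "GCA" * 30 + "TAA"
        from Bio.Seq import Seq
        rev = str(Seq("ATG" + "GTT" * 30 + "TGA").reverse_complement())
        orf = pm.longest_orf(fwd + "C" + rev, min_aa=30)
        assert orf.frame > 0

    def test_below_min_length(self):
        assert pm.longest_orf("ATG" + "GCA" * 5 + "TAA", min_aa=30) is None
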