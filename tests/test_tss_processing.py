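"""TSS consolidation: merge, filter, name, classify, novelty, domains."""

import numpy as np
import pytest

import conftest as fx
from promoterome import tss_processing as tp
from promoterome.io_formats import GenomicRegion


def run_pipeline(expr, raw):
    merged = tp.merge_tss(raw, expr)
    kept, discarded = tp.filter_tss(merged, expr)
    named = tp.name_promoters(kept)
    return merged, named, discarded


class TestHandTracedFixture:
    """The 12-TSS fixture reproduces its hand-traced consolidation."""

    def test_cluster_memberships(self, tss_fixture):
        expr, raw = tss_fixture
        merged = tp.merge_tss(raw, expr)
        got = sorted(map(frozenset, (r.members for r in merged)),
                     key=sorted)
        assert got == sorted(map(frozenset, fx.EXPECTED_CLUSTERS), key=sorted)

    def test_filter_and_names(self, tss_fixture):
        expr, raw = tss_fixture
        _, named, discarded = run_pipeline(expr, raw)
        assert [set(r.members) for r in discarded] == fx.EXPECTED_DISCARDED
        assert {r.name: set(r.members) for r in named} == fx.EXPECTED_NAMES

    def test_classification_labels(self, tss_fixture):
        expr, raw = tss_fixture
        _, named, _ = run_pipeline(expr, raw)
        labels = {r.name: tp.classify_expression(r, expr).label
                  for r in named}
        assert labels == fx.EXPECTED_LABELS
        for name, organ in fx.EXPECTED_DOMINANT.items():
            rec = next(r for r in named if r.name == name)
            assert tp.classify_expression(rec, expr).dominant_organ == organ

    def test_merging_conserves_tpm(self, tss_fixture):
        expr, raw = tss_fixture
        merged = tp.merge_tss(raw, expr)
        total_raw = np.sum([r.profile for r in raw], axis=0)
        total_merged = np.sum([r.profile for r in merged], axis=0)
        np.testing.assert_allclose(total_merged, total_raw)
        assert len(merged) <= len(raw)

    def test_merge_is_idempotent(self, tss_fixture):
        expr, raw = tss_fixture
        merged = tp.merge_tss(raw, expr)
        as_raw = [tp.RawTss(r.span, r.gene, r.profile) for r in merged]
        again = tp.merge_tss(as_raw, expr)
        assert sorted(len(r.members) for r in again) == [1] * len(merged)

    def test_cluster_members_satisfy_distance_rule(self, tss_fixture):
        expr, raw = tss_fixture
        points = {r.tss_id: r.region.tss_point for r in raw}
        for rec in tp.merge_tss(raw, expr):
            for m in rec.members:
                assert any(abs(points[m] - points[o]) <= 100
                           for o in rec.members if o != m) \
                    or len(rec.members) == 1


class TestMergeRules:
    def _expr_raw(self, profiles, positions, tss_fixture):
        expr, _ = tss_fixture
        raw = [
            tp.RawTss(GenomicRegion("chr9", p, p + 10, "+", f"x{i}"),
                      "G", prof)
            for i, (p, prof) in enumerate(zip(positions, profiles))
        ]
        return expr, raw

    def test_chain_merges_via_nearest_member(self, tss_fixture):
        """0/80/160: 160 is within 100 bp of member 80, so all merge."""
        expr, raw = self._expr_raw([fx.BASE] * 3, [0, 80, 160], tss_fixture)
        (rec,) = tp.merge_tss(raw, expr)
        assert set(rec.members) == {"x0", "x1", "x2"}
        np.testing.assert_allclose(rec.profile, 3 * fx.BASE)

    def test_anticorrelated_profiles_never_merge(self, tss_fixture):
        expr, raw = self._expr_raw([fx.BASE, fx.ANTI], [0, 50], tss_fixture)
        assert len(tp.merge_tss(raw, expr)) == 2

    def test_zero_variance_tissue_vector_never_merges(self, tss_fixture):
        flat = np.concatenate([np.full(12, 7.0), [1, 1, 1, 1]])
        expr, raw = self._expr_raw([flat, flat], [0, 50], tss_fixture)
        assert len(tp.merge_tss(raw, expr)) == 2

    def test_mixed_strands_within_gene_rejected(self, tss_fixture):
        expr, _ = tss_fixture
        raw = [
            tp.RawTss(GenomicRegion("chr9", 0, 10, "+", "x0"), "G", fx.BASE),
            tp.RawTss(GenomicRegion("chr9", 50, 60, "-", "x1"), "G", fx.BASE),
        ]
        with pytest.raises(ValueError, match="strand"):
            tp.merge_tss(raw, expr)


class TestFilterBoundaries:
    @pytest.mark.parametrize("tissue,pc,cl,kept", [
        (0.5, 1.0, 6.0, True),    # cell-line rescue
        (0.5, 4.9, 4.9, False),   # below every rescue boundary
        (1.0, 0.0, 0.0, True),    # tissue boundary inclusive
        (0.5, 5.0, 0.0, True),    # primary-cell rescue boundary inclusive
    ])
    def test_rescue_rules(self, tss_fixture, tissue, pc, cl, kept):
        expr, _ = tss_fixture
        profile = np.concatenate([np.full(12, tissue), [pc, 0], [cl, 0]])
        rec = tp.PromoterRecord("G", GenomicRegion("chr9", 0, 10, "+", "x"),
                                ["x"], profile)
        kept_list, _ = tp.filter_tss([rec], expr)
        assert bool(kept_list) is kept


class TestNaming:
    @staticmethod
    def _rec(gene, start, total):
        profile = np.array([total], dtype=float)
        return tp.PromoterRecord(
            gene, GenomicRegion("chr1", start, start + 10, "+"), ["m"],
            profile)

    def test_descending_total_order(self):
        recs = [self._rec("G", 0, 12.0), self._rec("G", 50, 90.5),
                self._rec("G", 100, 3.3)]
        named = tp.name_promoters(recs)
        assert {r.rank_name: r.total_tpm for r in named} == {
            "pA": 90.5, "pB": 12.0, "pC": 3.3}

    def test_tie_broken_by_coordinate(self):
        recs = [self._rec("G", 500, 10.0), self._rec("G", 100, 10.0)]
        named = sorted(tp.name_promoters(recs), key=lambda r: r.rank_name)
        assert named[0].span.start == 100  # pA at the lower coordinate

    def test_rank_names_extend_spreadsheet_style(self):
        assert tp._rank_letters(0) == "A"
        assert tp._rank_letters(25) == "Z"
        assert tp._rank_letters(26) == "AA"
        recs = [self._rec("G", i * 100, 1000.0 - i) for i in range(28)]
        named = tp.name_promoters(recs)
        by_start = sorted(named, key=lambda r: r.span.start)
        assert by_start[26].rank_name == "pAA"
        assert by_start[27].rank_name == "pAB"


class TestClassifyBoundaries:
    def _classify(self, tss_fixture, tissue_profile):
        expr, _ = tss_fixture
        profile = np.concatenate([tissue_profile, [0, 0, 0, 0]])
        rec = tp.PromoterRecord("G", GenomicRegion("chr9", 0, 10, "+"),
                                ["x"], profile)
        return tp.classify_expression(rec, expr)

    def test_exactly_ten_tissues_over5_is_specific(self, tss_fixture):
        profile = np.concatenate([np.linspace(6, 20, 10), [0.5, 0.5]])
        cls = self._classify(tss_fixture, profile)
        assert cls.n_tissues_over5 == 10
        assert cls.label == "specific"

    def test_eleven_tissues_over5_is_broad(self, tss_fixture):
        profile = np.concatenate([np.linspace(6, 20, 11), [0.5]])
        assert self._classify(tss_fixture, profile).label == "broad"

    def test_max_tissue_below_one_is_noise(self, tss_fixture):
        assert self._classify(
            tss_fixture, np.full(12, 0.8)).label == "noise"

    def test_exactly_one_label_per_record(self, tss_fixture):
        expr, raw = tss_fixture
        _, named, _ = run_pipeline(expr, raw)
        for rec in named:
            assert tp.classify_expression(rec, expr).label in (
                "broad", "specific", "low", "noise")


class TestCallNovel:
    REC = tp.PromoterRecord(
        "G", GenomicRegion("chr1", 1000, 1020, "+", "p"), ["p"],
        np.array([1.0]))

    @staticmethod
    def _ann(point, strand="+", name="a"):
        return GenomicRegion("chr1", point, point + 1, strand, name)

    def test_within_50_matches(self):
        match, novel = tp.call_novel(self.REC, [self._ann(1030)])
        assert match == "a" and not novel

    def test_51_bp_away_is_novel(self):
        match, novel = tp.call_novel(self.REC, [self._ann(1051)])
        assert match is None and novel

    def test_other_strand_ignored(self):
        _, novel = tp.call_novel(self.REC, [self._ann(1000, strand="-")])
        assert novel

    def test_equidistant_tie_resolves_to_5prime_most(self):
        match, _ = tp.call_novel(
            self.REC, [self._ann(1040, name="down"),
                       self._ann(960, name="up")])
        assert match == "up"

    def test_minus_strand_tie_resolves_to_higher_coordinate(self):
        rec = tp.PromoterRecord(
            "G", GenomicRegion("chr1", 1000, 1020, "-", "p"), ["p"],
            np.array([1.0]))
        # tss point = 1019; candidates at 979 and 1059, both 40 bp away
        cands = [GenomicRegion("chr1", 979, 980, "-", "low"),
                 GenomicRegion("chr1", 1059, 1060, "-", "high")]
        match, _ = tp.call_novel(rec, cands)
        assert match == "high"


class TestDomainGroups:
    @pytest.mark.parametrize("domains,group", [
        ((True, True, True, True, True), "1"),
        ((False, True, True, True, True), "2"),
        ((False, True, False, False, False), "3"),
        ((True, False, True, True, True), "4"),
        ((False, False, False, False, False), "4"),
        ((True, True, False, False, False), "other"),
    ])
    def test_group_assignment(self, domains, group):
        dc = tp.DomainComposition(*domains)
        assert tp.assign_domain_group(dc) == group
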