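import pytest

from vdjloci.annotate import (GeneSegment, assign_names, build_locus_map,
                              call_segments, count_inversions, find_c_regions)
from vdjloci.rss import default_model, scan
from vdjloci.seq_core import Interval, SeqRecord, revcomp
from vdjloci.simulate import LocusConfig, generate_locus


def annotate_locus(locus, truth, models):
    m12, m23 = models
    hits12 = scan(locus.seq, m12)
    hits23 = scan(locus.seq, m23)
    c_ivls = [
        Interval(r.start, r.end, r.strand)
        for r in truth.segments[truth.segments.kind == "C"].itertuples()
    ]
    return call_segments(locus.seq, hits12, hits23, c_ivls)


def as_tuples(segments):
    return sorted((s.kind, s.ivl.start, s.ivl.end, s.strand) for s in segments)


def truth_tuples(truth):
    return sorted(
        (r.kind, r.start, r.end, r.strand) for r in truth.segments.itertuples()
    )


class TestCallSegments:
    def test_planted_locus_recovered_exactly(self, small_locus, models):
        _, locus, truth = small_locus
        segs = annotate_locus(locus, truth, models)
        assert as_tuples(segs) == truth_tuples(truth)

    def test_inverted_v_reported_on_minus_strand(self, small_locus, models):
        _, locus, truth = small_locus
        segs = annotate_locus(locus, truth, models)
        minus_v = [s for s in segs if s.kind == "V" and s.strand == "-"]
        assert len(minus_v) == 1
        # coding sequence is reverse-complemented and starts with the ORF ATG
        assert minus_v[0].sequence.startswith("ATG")
        c_end = max(s.ivl.end for s in segs if s.kind == "C")
        assert minus_v[0].ivl.start > c_end  # 3' of C

    def test_empty_hit_lists_give_empty_calls(self):
        assert call_segments("ACGT" * 100, [], [], []) == []

    def test_whole_locus_revcomp_mirrors_all_calls(self, models):
        locus, truth = generate_locus(LocusConfig(n_v=4, n_d=1, n_j=2, n_families=2,
                                                  n_inverted_v=1, seed=9))
        fwd = annotate_locus(locus, truth, models)
        m12, m23 = models
        rc = revcomp(locus.seq)
        L = len(locus.seq)
        c_ivls = [
            Interval(L - r.end, L - r.start, "-" if r.strand == "+" else "+")
            for r in truth.segments[truth.segments.kind == "C"].itertuples()
        ]
        rev = call_segments(rc, scan(rc, m12), scan(rc, m23), c_ivls)
        mirrored = sorted(
            (s.kind, L - s.ivl.end, L - s.ivl.start, "-" if s.strand == "+" else "+")
            for s in rev
        )
        assert mirrored == as_tuples(fwd)

    def test_12_23_architecture_on_every_call(self, small_locus, models):
        _, locus, truth = small_locus
        for seg in annotate_locus(locus, truth, models):
            if seg.kind == "V":
                assert seg.rss5 is None and seg.rss3.spacer_class == 23
            elif seg.kind == "D":
                assert seg.rss5.spacer_class == 12 and seg.rss3.spacer_class == 23
            elif seg.kind == "J":
                assert seg.rss5.spacer_class == 12 and seg.rss3 is None
            else:
                assert seg.rss5 is None and seg.rss3 is None

    def test_rss_heptamer_abuts_segment_boundary(self, small_locus, models):
        _, locus, truth = small_locus
        for seg in annotate_locus(locus, truth, models):
            if seg.kind in ("V", "D"):
                rss = seg.rss3
                boundary = seg.ivl.end if seg.strand == "+" else seg.ivl.start
                assert rss.coding_boundary == boundary
            if seg.kind in ("J", "D"):
                rss = seg.rss5
                boundary = seg.ivl.start if seg.strand == "+" else seg.ivl.end
                assert rss.coding_boundary == boundary


class TestSegmentInvariants:
    def test_v_with_12_rss_rejected(self, small_locus, models):
        _, locus, truth = small_locus
        m12, _ = models
        hit12 = scan(locus.seq, m12)[0]
        with pytest.raises(ValueError, match="spacer class"):
            GeneSegment(name="x", kind="V", ivl=Interval(0, 300), strand="+",
                        sequence="ATG" + "A" * 297, rss3=hit12)

    def test_c_with_rss_rejected(self, small_locus, models):
        _, locus, truth = small_locus
        hit = scan(locus.seq, models[1])[0]
        with pytest.raises(ValueError, match="must not carry"):
            GeneSegment(name="x", kind="C", ivl=Interval(0, 10), strand="+",
                        sequence="A" * 10, rss3=hit)


class TestAssignNames:
    def _mk(self, kind, start, end, **kw):
        defaults = dict(name="", strand="+", sequence="A" * (end - start))
        defaults.update(kw)
        return GeneSegment(kind=kind, ivl=Interval(start, end), **defaults)

    def test_j_segments_numbered_in_order(self):
        segs = [self._mk("J", s, s + 40) for s in (500, 100, 900)]
        named = assign_names(segs, "TRB")
        assert [s.name for s in named] == ["TRBJ1", "TRBJ2", "TRBJ3"]

    def test_v_family_member_numbering(self):
        segs = [self._mk("V", s, s + 300) for s in (0, 1000, 2000)]
        named = assign_names(segs, "TRB", families={0: 2, 1: 2, 2: 1})
        assert [s.name for s in named] == ["TRBV2.1", "TRBV2.2", "TRBV1.1"]

    def test_single_c_unnumbered(self):
        named = assign_names([self._mk("C", 0, 400)], "TRE")
        assert named[0].name == "TREC"

    def test_missing_family_raises(self):
        with pytest.raises(ValueError, match="family"):
            assign_names([self._mk("V", 0, 300)], "TRB", families={})


class TestLocusMap:
    def test_span_and_counts_match_construction(self, small_locus, models):
        cfg, locus, truth = small_locus
        segs = annotate_locus(locus, truth, models)
        fams = {i: 1 for i in range(cfg.n_v)}
        locus_map = build_locus_map(assign_names(segs, "TRB", fams))
        t = truth.segments
        assert locus_map.span_bp == t.end.max() - t.start.min()
        assert locus_map.counts() == {"V": cfg.n_v, "D": cfg.n_d, "J": cfg.n_j,
                                      "C": cfg.n_c}

    def test_single_segment_span_is_its_length(self):
        seg = GeneSegment(name="TRBC", kind="C", ivl=Interval(10, 400), strand="+",
                          sequence="A" * 390)
        assert build_locus_map([seg]).span_bp == 390

    def test_overlapping_segments_rejected(self):
        a = GeneSegment(name="TRBC", kind="C", ivl=Interval(0, 100), strand="+",
                        sequence="A" * 100)
        b = GeneSegment(name="TRBC2", kind="C", ivl=Interval(50, 150), strand="+",
                        sequence="A" * 100)
        with pytest.raises(ValueError, match="overlap"):
            build_locus_map([a, b])


class TestInversionCount:
    def test_planted_inversions_counted(self, models):
        locus, truth = generate_locus(LocusConfig(n_v=6, n_d=1, n_j=2, n_families=3,
                                                  n_inverted_v=2, seed=5))
        segs = annotate_locus(locus, truth, models)
        fams = {i: 1 for i in range(6)}
        assert count_inversions(build_locus_map(assign_names(segs, "TRB", fams))) == 2

    def test_uniform_strand_counts_zero(self, small_locus, models):
        _, locus, truth = small_locus
        segs = [s for s in annotate_locus(locus, truth, models) if s.strand == "+"]
        fams = {i: 1 for i in range(sum(1 for s in segs if s.kind == "V"))}
        assert count_inversions(build_locus_map(assign_names(segs, "TRB", fams))) == 0


class TestFindCRegions:
    def test_known_c_located_exactly(self, small_locus):
        _, locus, truth = small_locus
        row = truth.segments[truth.segments.kind == "C"].iloc[0]
        (ivl,) = find_c_regions(locus.seq, [SeqRecord(id="C", seq=row.sequence)])
        assert (ivl.start, ivl.end, ivl.strand) == (row.start, row.end, "+")
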