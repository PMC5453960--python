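import numpy as np
import pytest

from helpers import feature, hit_key, peak, tables_repr
from peakanno.annotate import (
    anchor_positions,
    annotate_peak,
    annotate_peaks,
    evaluate_query,
    overlap_fractions,
    passes_filters,
    rank_hits,
    relative_location,
    signed_offset,
    within_window,
)
from peakanno.config import ConfigSpec, QuerySpec
from peakanno.fixtures import brute_force_annotate, random_instance
from peakanno.io_genomic import build_index


class TestAnchors:
    def test_plus_strand_start_is_left_edge(self):
        (pos,) = anchor_positions(feature(999, 2000, strand="+"), ("start",))
        assert pos == ("start", 999)

    def test_minus_strand_start_is_right_edge(self):
        (pos,) = anchor_positions(feature(999, 2000, strand="-"), ("start",))
        assert pos == ("start", 1999)

    def test_all_three_anchors_plus_strand(self):
        got = anchor_positions(feature(999, 2000, strand="+"), ("start", "center", "end"))
        assert got == [("start", 999), ("center", 1499), ("end", 1999)]

    def test_center_same_for_both_strands(self):
        plus = dict(anchor_positions(feature(0, 11, strand="+"), ("center",)))
        minus = dict(anchor_positions(feature(0, 11, strand="-"), ("center",)))
        assert plus["center"] == minus["center"] == 5


class TestSignedOffset:
    @pytest.mark.parametrize(
        "center,anchor,strand,expected",
        [
            (1200, 1000, "+", 200),
            (1200, 1000, "-", -200),
            (1200, 1000, ".", 200),
            (1000, 1000, "+", 0),
            (1000, 1000, "-", 0),
            (800, 1000, "+", -200),
        ],
    )
    def test_orientation_convention(self, center, anchor, strand, expected):
        assert signed_offset(center, anchor, strand) == expected


class TestWithinWindow:
    @pytest.mark.parametrize(
        "offset,up,down,expected",
        [
            (-800, 1000, 500, True),
            (800, 1000, 500, False),
            (-1000, 1000, 500, True),  # inclusive boundary
            (500, 1000, 500, True),
            (501, 1000, 500, False),
            (0, 0, 0, True),
        ],
    )
    def test_asymmetric_inclusive_window(self, offset, up, down, expected):
        assert within_window(offset, up, down) is expected


class TestFilters:
    def test_feature_type_filter(self):
        q = QuerySpec(features=["gene"])
        assert passes_filters(peak(0, 10), feature(0, 10, ftype="transcript"), q) is False
        assert passes_filters(peak(0, 10), feature(0, 10, ftype="gene"), q) is True

    def test_attribute_filter(self):
        q = QuerySpec(filter_attribute="gene_biotype", attribute_values=["protein_coding"])
        f_ok = feature(0, 10, gene_biotype="protein_coding")
        f_bad = feature(0, 10, gene_biotype="pseudogene")
        f_missing = feature(0, 10, gene_id="g")
        assert passes_filters(peak(0, 10), f_ok, q)
        assert not passes_filters(peak(0, 10), f_bad, q)
        assert not passes_filters(peak(0, 10), f_missing, q)

    @pytest.mark.parametrize(
        "mode,pstrand,fstrand,expected",
        [
            ("ignore", ".", "+", True),
            ("same", "+", "+", True),
            ("same", "+", "-", False),
            ("same", ".", "+", False),
            ("opposite", "+", "-", True),
            ("opposite", "+", "+", False),
            ("opposite", "+", ".", False),
            ("opposite", ".", "-", False),
        ],
    )
    def test_strand_modes(self, mode, pstrand, fstrand, expected):
        q = QuerySpec(strand_mode=mode)
        assert passes_filters(peak(0, 10, strand=pstrand), feature(0, 10, strand=fstrand), q) is expected

    def test_direction_upstream_enumerated_around_toy_feature(self):
        # + strand feature [5000, 6000): upstream = center strictly < 5000
        f = feature(5000, 6000, strand="+")
        q = QuerySpec(direction="upstream")
        for center in range(4990, 5010):
            p = peak(center - 10, center + 10)
            assert passes_filters(p, f, q) is (center < 5000)

    def test_direction_downstream_minus_strand(self):
        # - strand feature [5000, 6000): 3' end at 5000; downstream = center < 5000
        f = feature(5000, 6000, strand="-")
        q = QuerySpec(direction="downstream")
        for center in range(4990, 5010):
            p = peak(center - 10, center + 10)
            assert passes_filters(p, f, q) is (center < 5000)

    def test_peak_inside_feature_fails_both_directions(self):
        f = feature(1000, 2000, strand="+")
        p = peak(1400, 1600)
        assert not passes_filters(p, f, QuerySpec(direction="upstream"))
        assert not passes_filters(p, f, QuerySpec(direction="downstream"))


class TestRelativeLocation:
    @pytest.mark.parametrize(
        "pstart,pend,fstrand,expected",
        [
            (100, 200, "+", "PeakInsideFeature"),
            (0, 120, "+", "OverlapStart"),
            (0, 120, "-", "OverlapEnd"),
            (450, 600, "+", "OverlapEnd"),
            (450, 600, "-", "OverlapStart"),
            (0, 50, "+", "Upstream"),
            (0, 50, "-", "Downstream"),
            (600, 700, "+", "Downstream"),
            (600, 700, "-", "Upstream"),
            (40, 600, "+", "FeatureInsidePeak"),
        ],
    )
    def test_categories(self, pstart, pend, fstrand, expected):
        assert relative_location(peak(pstart, pend), feature(100, 500, strand=fstrand)) == expected

    def test_identical_spans_count_as_peak_inside(self):
        assert relative_location(peak(100, 500), feature(100, 500)) == "PeakInsideFeature"

    def test_exhaustive_sweep_partitions_positions(self):
        """A 10-bp peak swept across a 50-bp feature hits every category
        exactly once per position, in the expected left-to-right order."""
        f = feature(100, 150, strand="+")
        seen = []
        for start in range(80, 160):
            cat = relative_location(peak(start, start + 10), f)
            if not seen or seen[-1][0] != cat:
                seen.append((cat, start))
        assert [c for c, _ in seen] == [
            "Upstream", "OverlapStart", "PeakInsideFeature", "OverlapEnd", "Downstream",
        ]
        # boundaries: overlap begins when peak end enters the feature
        assert dict(seen)["OverlapStart"] == 91
        assert dict(seen)["PeakInsideFeature"] == 100
        assert dict(seen)["OverlapEnd"] == 141
        assert dict(seen)["Downstream"] == 150


class TestOverlapFractions:
    @pytest.mark.parametrize(
        "pstart,pend,fstart,fend,expected",
        [
            (100, 200, 150, 400, (0.5, 0.2)),
            (0, 50, 100, 200, (0.0, 0.0)),
            (100, 200, 100, 200, (1.0, 1.0)),
        ],
    )
    def test_fractions(self, pstart, pend, fstart, fend, expected):
        got = overlap_fractions(peak(pstart, pend), feature(fstart, fend))
        assert got == pytest.approx(expected)


class TestEvaluateQuery:
    def test_peak_on_tss_distance_zero(self):
        f = feature(1000, 2000, strand="+", gene_id="g1")
        idx = build_index([f])
        p = peak(950, 1050)  # center exactly 1000
        q = QuerySpec(features=["gene"], anchors=("start",),
                      distance_upstream=1000, distance_downstream=500)
        (hit,) = evaluate_query(p, idx, q)
        assert hit.distance == 0
        assert hit.best_anchor == "start"
        assert hit.via_internals is False

    def test_internals_accepts_peak_deep_inside_large_gene(self):
        f = feature(0, 500_000, strand="+", gene_id="big")
        idx = build_index([f])
        p = peak(200_000, 200_100)  # center 200050, far beyond the window
        q = QuerySpec(anchors=("start",), distance_upstream=5000,
                      distance_downstream=5000, internals=True)
        (hit,) = evaluate_query(p, idx, q)
        assert hit.via_internals is True
        assert hit.distance == 200_050  # |center - 5' end|, exceeds the window
        assert hit.distance > max(q.distance_upstream, q.distance_downstream)
        # without internals, no hit at all
        q_off = QuerySpec(anchors=("start",), distance_upstream=5000,
                          distance_downstream=5000, internals=False)
        assert evaluate_query(p, idx, q_off) == []

    def test_internals_finds_feature_contained_in_peak(self):
        # every anchor of the small feature is beyond the 10-bp window of
        # the huge peak's center, but the feature sits wholly inside the peak
        f = feature(1000, 1100, gene_id="tiny")
        idx = build_index([f])
        p = peak(0, 10_000)  # center 5000, all anchors ~3900+ bp away
        q = QuerySpec(distance_upstream=10, distance_downstream=10, internals=True)
        (hit,) = evaluate_query(p, idx, q)
        assert hit.via_internals is True
        assert hit.relative_location == "FeatureInsidePeak"

    def test_best_anchor_minimizes_absolute_offset(self):
        f = feature(1000, 3000, strand="+")
        idx = build_index([f])
        p = peak(2800, 3000)  # center 2900: end anchor (2999) closest
        q = QuerySpec(anchors=("start", "center", "end"),
                      distance_upstream=5000, distance_downstream=5000)
        (hit,) = evaluate_query(p, idx, q)
        assert hit.best_anchor == "end"
        assert hit.distance == 99

    def test_window_anchor_preferred_over_closer_failing_anchor(self):
        """When the nearest anchor fails the asymmetric window but another
        passes, the hit reports the passing anchor (offsets stay within
        the window unless the internals rule fired)."""
        f = feature(1000, 1600, strand="+")
        idx = build_index([f])
        p = peak(1700, 1900)  # center 1800: end offset +201, start offset +800
        q = QuerySpec(anchors=("start", "end"), distance_upstream=100,
                      distance_downstream=1000)
        # end offset +201 within [-100, 1000]; start +800 also within; end closer
        (hit,) = evaluate_query(p, idx, q)
        assert hit.best_anchor == "end"
        q2 = QuerySpec(anchors=("start", "end"), distance_upstream=1000,
                       distance_downstream=300)
        # end +201 passes, start +800 fails downstream limit
        (hit2,) = evaluate_query(p, idx, q2)
        assert hit2.best_anchor == "end"
        assert -q2.distance_upstream <= hit2.signed_offset <= q2.distance_downstream


class TestRankHits:
    def test_distance_then_feature_coordinates(self):
        p = peak(0, 100, pid="pk")
        idx = build_index([])
        q = QuerySpec()
        from peakanno.annotate import CandidateHit

        def hit(dist, fstart):
            f = feature(fstart, fstart + 10, gene_id=f"g{fstart}")
            return CandidateHit(peak=p, query_index=0, feature=f, best_anchor="start",
                                anchor_pos=fstart, distance=dist, signed_offset=dist,
                                relative_location="Upstream", feat_ovl_peak=0.0,
                                peak_ovl_feat=0.0)

        hits = [hit(300, 10), hit(50, 500), hit(50, 100)]
        ranked = rank_hits(hits)
        assert [(h.distance, h.feature.start) for h in ranked] == [(50, 100), (50, 500), (300, 10)]

    def test_single_hit_unchanged(self):
        p = peak(0, 100)
        from peakanno.annotate import CandidateHit

        f = feature(0, 10)
        h = CandidateHit(peak=p, query_index=0, feature=f, best_anchor="start",
                         anchor_pos=0, distance=1, signed_offset=1,
                         relative_location="Downstream", feat_ovl_peak=0.1, peak_ovl_feat=1.0)
        assert rank_hits([h]) == [h]

    def test_full_tie_breaks_by_first_show_attribute(self):
        p = peak(100, 200)  # center 150
        f1 = feature(100, 200, gene_id="zzz")
        f2 = feature(100, 200, gene_id="aaa")
        idx = build_index([f1, f2])
        q = QuerySpec(anchors=("center",), distance_upstream=100, distance_downstream=100)
        hits = rank_hits(evaluate_query(p, idx, q), show_attributes=["gene_id"])
        assert [h.feature.attributes["gene_id"] for h in hits] == ["aaa", "zzz"]


class TestPriorityMerge:
    def _setup(self):
        near = feature(1000, 1100, gene_id="near", ftype="exon")
        far = feature(1550, 1650, gene_id="far", ftype="gene")
        idx = build_index([near, far])
        p = peak(1100, 1200, pid="pk")  # center 1150: near at 100/51, far at 400
        q0 = QuerySpec(index=0, features=["gene"], anchors=("start",),
                       distance_upstream=1000, distance_downstream=1000)
        q1 = QuerySpec(index=1, features=["exon"], anchors=("start",),
                       distance_upstream=1000, distance_downstream=1000)
        return p, idx, q0, q1

    def test_priority_true_first_query_wins_despite_distance(self):
        p, idx, q0, q1 = self._setup()
        cfg = ConfigSpec(queries=[q0, q1], priority=True)
        ann = annotate_peak(p, idx, cfg)
        assert ann.final.feature.attributes["gene_id"] == "far"
        assert ann.final.query_index == 0
        # the aborted query leaves no trace in any table
        assert all(h.query_index == 0 for h in ann.all_hits)
        assert ann.best_per_query[1] is None

    def test_priority_false_min_distance_wins(self):
        p, idx, q0, q1 = self._setup()
        cfg = ConfigSpec(queries=[q0, q1], priority=False)
        ann = annotate_peak(p, idx, cfg)
        assert ann.final.feature.attributes["gene_id"] == "near"
        assert ann.final.query_index == 1

    def test_no_hits_gives_na_everywhere(self):
        p = peak(0, 100, chrom="chrX")
        idx = build_index([feature(0, 10, chrom="chr1")])
        cfg = ConfigSpec(queries=[QuerySpec(index=0)])
        ann = annotate_peak(p, idx, cfg)
        assert ann.all_hits == []
        assert ann.best_per_query == [None]
        assert ann.final is None

    def test_cross_query_distance_tie_lower_index_wins(self):
        f1 = feature(1000, 1100, gene_id="a", ftype="gene")
        f2 = feature(1000, 1100, gene_id="b", ftype="exon")
        idx = build_index([f1, f2])
        p = peak(950, 1050)
        q0 = QuerySpec(index=0, features=["exon"], anchors=("start",))
        q1 = QuerySpec(index=1, features=["gene"], anchors=("start",))
        ann = annotate_peak(p, idx, ConfigSpec(queries=[q0, q1]))
        assert ann.final.query_index == 0


class TestOracleEquivalence:
    def test_closest_tss_mode_matches_exhaustive_scan(self):
        from peakanno.fixtures import SyntheticSpec, make_annotation, make_peaks

        spec = SyntheticSpec(n_features=80, chrom_length=500_000, seed=11)
        _, features = make_annotation(spec)
        _, peaks = make_peaks(features, 100, 500_000, seed=12)
        cfg = ConfigSpec(queries=[QuerySpec(index=0, anchors=("start",),
                                            distance_upstream=10**6,
                                            distance_downstream=10**6)])
        rt = annotate_peaks(peaks, build_index(features), cfg)
        for ann in rt.annotations:
            def tss_dist(f):
                tss = f.end - 1 if f.strand == "-" else f.start
                return abs(ann.peak.center - tss)

            best = min(tss_dist(f) for f in features)
            assert ann.final is not None
            assert ann.final.distance == best

    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_match_brute_force(self, seed):
        peaks, features, cfg = random_instance(seed)
        rt = annotate_peaks(peaks, build_index(features), cfg)
        oracle = brute_force_annotate(peaks, features, cfg)
        assert tables_repr(rt) == tables_repr(oracle)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariants_on_random_instances(self, seed):
        peaks, features, cfg = random_instance(seed + 1000)
        rt = annotate_peaks(peaks, build_index(features), cfg)
        assert [a.peak.id for a in rt.annotations] == [p.id for p in peaks]
        for ann in rt.annotations:
            for h in ann.all_hits:
                q = cfg.queries[h.query_index]
                assert h.distance == abs(h.signed_offset)
                if not h.via_internals:
                    assert -q.distance_upstream <= h.signed_offset <= q.distance_downstream
                    assert h.distance <= max(q.distance_upstream, q.distance_downstream)
                overlapping = h.relative_location in (
                    "PeakInsideFeature", "FeatureInsidePeak", "OverlapStart", "OverlapEnd",
                )
                inter = max(0, min(ann.peak.end, h.feature.end) - max(ann.peak.start, h.feature.start))
                assert overlapping == (inter > 0)
            keys = [hit_key(h) for h in ann.all_hits]
            for h in ann.best_per_query:
                if h is not None:
                    assert hit_key(h) in keys
            if ann.final is not None:
                assert hit_key(ann.final) in [
                    hit_key(h) for h in ann.best_per_query if h is not None
                ]
            if cfg.priority and ann.final is not None:
                # final query index is the first query with any candidate
                assert all(h.query_index == ann.final.query_index for h in ann.all_hits)
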