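"""Core annotation algorithm.

For each peak, every query is evaluated against an interval index of the
reference features: candidates passing the query's filters (feature type,
attribute value, strand mode, direction) are kept when the peak center
lies within the asymmetric distance window of any requested feature anchor
— or, when the ``internals`` override is active, when the peak center lies
inside the feature (or the feature inside the peak) regardless of
distance. Candidates are ranked per query by distance and merged into
three granularities: *all hits* (every candidate from any query), *best
per query* (the top candidate per query), and *final hits* (exactly one
winning row per peak). With ``priority=true`` queries form a hierarchy:
the first query producing any candidate for a peak aborts the search for
that peak.

Distances are always measured from the peak center to a feature anchor
(start = 5′ end, end = 3′ end, center), interpreted in feature
orientation; unstranded features default to ``+`` orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ConfigSpec, QuerySpec
from .io_genomic import Feature, FeatureIndex, Peak

__all__ = [
    "CandidateHit",
    "PeakAnnotation",
    "ResultTables",
    "anchor_positions",
    "signed_offset",
    "within_window",
    "passes_filters",
    "evaluate_query",
    "rank_hits",
    "relative_location",
    "overlap_fractions",
    "annotate_peak",
    "annotate_peaks",
]

ANCHOR_ORDER = ("start", "center", "end")


@dataclass
class CandidateHit:
    """A valid (peak, feature, query) match."""

    peak: Peak
    query_index: int
    feature: Feature
    best_anchor: str
    anchor_pos: int
    distance: int
    signed_offset: int
    relative_location: str
    feat_ovl_peak: float  # fraction of the peak covered by the feature
    peak_ovl_feat: float  # fraction of the feature covered by the peak
    via_internals: bool = False


@dataclass
class PeakAnnotation:
    """Per-peak result: all candidates, per-query best, and the winner."""

    peak: Peak
    all_hits: list[CandidateHit] = field(default_factory=list)
    best_per_query: list[CandidateHit | None] = field(default_factory=list)
    final: CandidateHit | None = None


@dataclass
class ResultTables:
    """The three result granularities for a whole run.

    ``annotations`` holds one :class:`PeakAnnotation` per input peak, in
    input order; ``n_queries`` is the query count (fixing the width of the
    best-per-query table).
    """

    annotations: list[PeakAnnotation]
    n_queries: int

    @property
    def peaks(self) -> list[Peak]:
        return [a.peak for a in self.annotations]


def anchor_positions(f: Feature, anchors: tuple[str, ...]) -> list[tuple[str, int]]:
    """Requested anchor positions in feature orientation.

    ``start`` is the 5′ end and ``end`` the 3′ end: for ``-`` strand
    features the genomic positions swap. ``center`` is
    ``floor((start + end - 1) / 2)`` for both strands. Positions are the
    coordinates of the first/middle/last base of the feature.
    """
    first, last = f.start, f.end - 1
    if f.strand == "-":
        pos = {"start": last, "center": (f.start + f.end - 1) // 2, "end": first}
    else:
        pos = {"start": first, "center": (f.start + f.end - 1) // 2, "end": last}
    return [(name, pos[name]) for name in ANCHOR_ORDER if name in anchors]


def signed_offset(peak_center: int, anchor_pos: int, feature_strand: str) -> int:
    """Offset of the peak center from an anchor, in feature orientation.

    Negative = peak center upstream of the anchor (5′ side), positive =
    downstream. Unstranded features are treated as ``+``.
    """
    if feature_strand == "-":
        return anchor_pos - peak_center
    return peak_center - anchor_pos


def within_window(offset: int, up: int, down: int) -> bool:
    """True iff ``-up <= offset <= down`` (both boundaries inclusive)."""
    return -up <= offset <= down


def _intersection(p: Peak, f: Feature) -> int:
    return max(0, min(p.end, f.end) - max(p.start, f.start))


def passes_filters(p: Peak, f: Feature, q: QuerySpec) -> bool:
    """Apply a query's non-distance filters to a (peak, feature) pair.

    Conjunction of the feature-type filter, the attribute filter (a
    feature lacking the key fails), the strand mode, and the direction
    constraint. ``direction=upstream`` requires the peak center strictly
    5′ of the feature's start anchor; ``downstream`` strictly 3′ of its
    end anchor — a peak centered inside the feature fails both.
    """
    if q.features and f.feature_type not in q.features:
        return False
    if q.filter_attribute is not None:
        if f.attributes.get(q.filter_attribute) not in q.attribute_values:
            return False
    if q.strand_mode == "same":
        if p.strand == "." or p.strand != f.strand:
            return False
    elif q.strand_mode == "opposite":
        if p.strand == "." or f.strand == "." or p.strand == f.strand:
            return False
    if q.direction != "any":
        (_, five_prime), = anchor_positions(f, ("start",))
        (_, three_prime), = anchor_positions(f, ("end",))
        if q.direction == "upstream":
            if signed_offset(p.center, five_prime, f.strand) >= 0:
                return False
        else:  # downstream
            if signed_offset(p.center, three_prime, f.strand) <= 0:
                return False
    return True


def relative_location(p: Peak, f: Feature) -> str:
    """Categorize the peak's position relative to the feature.

    Disjoint intervals are Upstream/Downstream of the feature (in feature
    orientation); otherwise containment gives PeakInsideFeature /
    FeatureInsidePeak (identical spans count as PeakInsideFeature), and a
    partial overlap covering the feature's 5′ end is OverlapStart, its 3′
    end OverlapEnd.
    """
    if _intersection(p, f) == 0:
        # peak lies wholly on one genomic side of the feature
        genomically_left = p.end <= f.start
        if f.strand == "-":
            return "Downstream" if genomically_left else "Upstream"
        return "Upstream" if genomically_left else "Downstream"
    if f.start <= p.start and p.end <= f.end:
        return "PeakInsideFeature"
    if p.start <= f.start and f.end <= p.end:
        return "FeatureInsidePeak"
    covers_left_edge = p.start <= f.start < p.end
    if f.strand == "-":
        return "OverlapEnd" if covers_left_edge else "OverlapStart"
    return "OverlapStart" if covers_left_edge else "OverlapEnd"


def overlap_fractions(p: Peak, f: Feature) -> tuple[float, float]:
    """(fraction of peak covered by feature, fraction of feature covered by peak)."""
    i = _intersection(p, f)
    return i / p.length, i / f.length


def _internals_applies(p: Peak, f: Feature) -> bool:
    center_inside = f.start <= p.center < f.end
    feature_inside = p.start <= f.start and f.end <= p.end
    return center_inside or feature_inside


def _make_hit(p: Peak, f: Feature, q: QuerySpec) -> CandidateHit | None:
    """Distance test for one filtered candidate; None when it fails."""
    offsets = [
        (name, pos, signed_offset(p.center, pos, f.strand))
        for name, pos in anchor_positions(f, q.anchors)
    ]
    passing = [o for o in offsets if within_window(o[2], q.distance_upstream, q.distance_downstream)]
    if passing:
        via_internals = False
        name, pos, off = min(passing, key=lambda o: abs(o[2]))
    elif q.internals and _internals_applies(p, f):
        via_internals = True
        name, pos, off = min(offsets, key=lambda o: abs(o[2]))
    else:
        return None
    fo, po = overlap_fractions(p, f)
    return CandidateHit(
        peak=p,
        query_index=q.index,
        feature=f,
        best_anchor=name,
        anchor_pos=pos,
        distance=abs(off),
        signed_offset=off,
        relative_location=relative_location(p, f),
        feat_ovl_peak=fo,
        peak_ovl_feat=po,
        via_internals=via_internals,
    )


def evaluate_query(p: Peak, index: FeatureIndex, q: QuerySpec) -> list[CandidateHit]:
    """All valid candidates of one query for one peak (unranked).

    Candidate retrieval scans the window ``[center - W, center + W + 1)``
    with ``W = max(up, down)``; with ``internals`` active the peak's own
    span is scanned as well, so a fully-overlapping feature is found even
    when all of its anchors lie beyond the window.
    """
    w = max(q.distance_upstream, q.distance_downstream)
    candidates = index.query(p.chrom, p.center - w, p.center + w + 1)
    if q.internals:
        seen = {id(f) for f in candidates}
        for f in index.query(p.chrom, p.start, p.end):
            if id(f) not in seen:
                candidates.append(f)
    hits: list[CandidateHit] = []
    for f in candidates:
        if not passes_filters(p, f, q):
            continue
        hit = _make_hit(p, f, q)
        if hit is not None:
            hits.append(hit)
    return hits


def _rank_key(hit: CandidateHit, show_attributes: list[str]) -> tuple:
    first_attr = hit.feature.attributes.get(show_attributes[0], "") if show_attributes else ""
    return (hit.distance, hit.feature.start, hit.feature.end, first_attr)


def rank_hits(hits: list[CandidateHit], show_attributes: list[str] | None = None) -> list[CandidateHit]:
    """Sort one query's candidates into the deterministic ranking order.

    Ascending distance; ties break by feature start, feature end, then
    the value of the first show-attribute (lexicographic).
    """
    show = show_attributes or []
    return sorted(hits, key=lambda h: _rank_key(h, show))


def annotate_peak(p: Peak, index: FeatureIndex, cfg: ConfigSpec,
                  show_attributes: list[str] | None = None) -> PeakAnnotation:
    """Evaluate every query for one peak and merge into a :class:`PeakAnnotation`.

    With ``priority=false`` all queries contribute and the final hit is
    the minimum-distance per-query best (ties to the lower query index).
    With ``priority=true`` queries run in order and the first one with a
    candidate ends the search; only its candidates appear in the tables.
    """
    show = show_attributes or []
    ann = PeakAnnotation(peak=p, best_per_query=[None] * len(cfg.queries))
    per_query: list[list[CandidateHit]] = [[] for _ in cfg.queries]
    for q in cfg.queries:
        hits = rank_hits(evaluate_query(p, index, q), show)
        per_query[q.index] = hits
        if cfg.priority and hits:
            break
    for qi, hits in enumerate(per_query):
        ann.all_hits.extend(hits)
        if hits:
            ann.best_per_query[qi] = hits[0]
    bests = [h for h in ann.best_per_query if h is not None]
    if bests:
        ann.final = min(bests, key=lambda h: (h.distance, h.query_index))
    return ann


def annotate_peaks(peaks: list[Peak], index: FeatureIndex, cfg: ConfigSpec,
                   show_attributes: list[str] | None = None) -> ResultTables:
    """Annotate a peak list sequentially, preserving input order."""
    annotations = [annotate_peak(p, index, cfg, show_attributes) for p in peaks]
    return ResultTables(annotations=annotations, n_queries=len(cfg.queries))
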