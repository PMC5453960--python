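"""Synthetic references, constructed peaks, and the brute-force oracle.

`make_annotation` emulates a small GTF reference: features with realistic
type (gene/transcript/exon) and biotype (protein_coding/pseudogene/
lincRNA) mixtures, both strands, and standard attribute keys. It stands
in for a real Gencode/Ensembl/RefSeq slice for testing; it does not model
gene nesting, overlapping isoform structure, or chromosome-scale feature
density.

`brute_force_annotate` re-derives the full annotation by direct O(peaks ×
features) iteration, re-stating every rule in plain arithmetic. It shares
only the data types with the production path — none of its filtering or
ranking code — so agreement between the two is a meaningful check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigSpec, QuerySpec
from .io_genomic import Feature, Peak, write_gtf
from .annotate import CandidateHit, PeakAnnotation, ResultTables

__all__ = [
    "SyntheticSpec",
    "make_annotation",
    "make_peaks",
    "make_peaks_at_offsets",
    "brute_force_annotate",
    "random_instance",
]

DEFAULT_FEATURE_TYPES = {"gene": 0.5, "transcript": 0.3, "exon": 0.2}
DEFAULT_BIOTYPES = {"protein_coding": 0.6, "pseudogene": 0.2, "lincRNA": 0.2}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic GTF reference.

    Defaults sketch a gene-dense genomic slice: 100 features on one 1-Mb
    chromosome (~1 feature / 10 kb), a 60/20/20 protein_coding/pseudogene/
    lincRNA biotype mixture under ``gene_biotype``, both strands equally,
    and feature lengths from 500 bp to 20 kb.
    """

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_features: int = 100
    feature_types: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEATURE_TYPES))
    biotypes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BIOTYPES))
    biotype_key: str = "gene_biotype"
    plus_fraction: float = 0.5
    min_length: int = 500
    max_length: int = 20_000
    seed: int = 0


def _draw(rng: np.random.Generator, dist: dict[str, float], size: int) -> list[str]:
    names = list(dist)
    probs = np.asarray([dist[n] for n in names], dtype=float)
    probs /= probs.sum()
    return [names[i] for i in rng.choice(len(names), size=size, p=probs)]


def make_annotation(spec: SyntheticSpec) -> tuple[str, list[Feature]]:
    """Generate a synthetic reference; returns (GTF text, feature list).

    Deterministic under ``spec.seed``. Raises when the requested feature
    length cannot fit the chromosome.
    """
    if spec.max_length >= spec.chrom_length:
        raise ValueError(
            f"features of length {spec.max_length} cannot fit a "
            f"{spec.chrom_length} bp chromosome"
        )
    if spec.min_length < 1 or spec.min_length > spec.max_length:
        raise ValueError("require 1 <= min_length <= max_length")
    rng = np.random.default_rng(spec.seed)
    types = _draw(rng, spec.feature_types, spec.n_features)
    biotypes = _draw(rng, spec.biotypes, spec.n_features)
    features: list[Feature] = []
    for i in range(spec.n_features):
        chrom = f"chr{int(rng.integers(1, spec.n_chroms + 1))}"
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        start = int(rng.integers(0, spec.chrom_length - length))
        strand = "+" if rng.random() < spec.plus_fraction else "-"
        features.append(
            Feature(
                chrom=chrom,
                source="synthetic",
                feature_type=types[i],
                start=start,
                end=start + length,
                score=".",
                strand=strand,
                frame=".",
                attributes={
                    "gene_id": f"g{i}",
                    "gene_name": f"GENE{i}",
                    spec.biotype_key: biotypes[i],
                },
            )
        )
    header = "## synthetic reference\n"
    return header + write_gtf(features), features


def make_peaks(features: list[Feature], n_peaks: int, chrom_length: int,
               seed: int = 0, width_range: tuple[int, int] = (100, 1000)) -> tuple[str, list[Peak]]:
    """Random peaks over the chromosomes the features occupy.

    Peaks are placed uniformly; roughly realistic for an unenriched
    control, and sufficient to exercise every relative-location category
    against a dense reference. Returns (BED text, peak list).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted({f.chrom for f in features}) or ["chr1"]
    peaks: list[Peak] = []
    for i in range(n_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        start = int(rng.integers(0, max(1, chrom_length - width)))
        strand = ["+", "-", "."][int(rng.integers(3))]
        peaks.append(Peak(id=f"peak_{i + 1}", chrom=chrom, start=start,
                          end=start + width, strand=strand))
    bed = "".join(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t0\t{p.strand}\n" for p in peaks)
    return bed, peaks


def make_peaks_at_offsets(features: list[Feature],
                          offset_spec: list[tuple[str, int]],
                          chrom_length: int,
                          width: int = 100,
                          window: tuple[int, int] | None = None) -> tuple[str, list[Peak], list[dict]]:
    """Construct peaks whose centers sit at exact anchor-relative offsets.

    For each feature and each ``(anchor, signed_offset)`` pair a peak of
    even ``width`` is placed so its center lands exactly ``offset`` bp
    from the anchor, measured in feature orientation (negative =
    upstream). Returns (BED text, peaks, truth table); each truth record
    gives the peak id, the source feature's gene_id, the offset, the
    implied distance, and — when a ``window = (up, down)`` is supplied —
    whether that window accepts the peak.
    """
    if width % 2:
        raise ValueError("peak width must be even so the center is exact")
    peaks: list[Peak] = []
    truth: list[dict] = []
    n = 0
    for f in features:
        first, last = f.start, f.end - 1
        anchor_pos = {
            "start": last if f.strand == "-" else first,
            "center": (f.start + f.end - 1) // 2,
            "end": first if f.strand == "-" else last,
        }
        sign = -1 if f.strand == "-" else 1
        for anchor, offset in offset_spec:
            center = anchor_pos[anchor] + sign * offset
            start = center - width // 2
            end = center + width // 2
            if start < 0 or end > chrom_length:
                raise ValueError(
                    f"offset {offset} from {anchor} of {f.attributes.get('gene_id')} "
                    f"places peak outside chromosome"
                )
            n += 1
            pid = f"peak_{n}"
            peaks.append(Peak(id=pid, chrom=f.chrom, start=start, end=end))
            record = {
                "peak_id": pid,
                "gene_id": f.attributes.get("gene_id"),
                "anchor": anchor,
                "offset": offset,
                "distance": abs(offset),
            }
            if window is not None:
                up, down = window
                record["annotated"] = -up <= offset <= down
            truth.append(record)
    bed = "".join(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n" for p in peaks)
    return bed, peaks, truth


def random_instance(seed: int,
                    max_features: int = 50,
                    max_peaks: int = 20,
                    max_queries: int = 4) -> tuple[list[Peak], list[Feature], ConfigSpec]:
    """A small random annotation problem exercising every query option.

    Feature and peak coordinates are drawn over a short chromosome so
    windows, overlaps, and containment cases all occur; each query draws
    its feature filter, window, anchors, strand mode, direction,
    attribute filter, and internals flag at random, and the global
    priority flag is a coin flip. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    chrom_len = 50_000
    spec = SyntheticSpec(
        n_chroms=int(rng.integers(1, 3)),
        chrom_length=chrom_len,
        n_features=int(rng.integers(1, max_features + 1)),
        min_length=50,
        max_length=5_000,
        seed=int(rng.integers(0, 2**31)),
    )
    _, features = make_annotation(spec)
    _, peaks = make_peaks(features, int(rng.integers(1, max_peaks + 1)), chrom_len,
                          seed=int(rng.integers(0, 2**31)), width_range=(50, 2_000))
    n_queries = int(rng.integers(1, max_queries + 1))
    queries = []
    all_types = ["gene", "transcript", "exon"]
    all_biotypes = ["protein_coding", "pseudogene", "lincRNA"]
    for qi in range(n_queries):
        anchors = tuple(
            a for a in ("start", "center", "end") if rng.random() < 0.5
        ) or ("start",)
        q = QuerySpec(
            index=qi,
            features=list(rng.choice(all_types, size=int(rng.integers(0, 3)), replace=False)),
            distance_upstream=int(rng.integers(0, 10_000)),
            distance_downstream=int(rng.integers(0, 10_000)),
            anchors=anchors,
            strand_mode=str(rng.choice(["ignore", "same", "opposite"], p=[0.6, 0.2, 0.2])),
            direction=str(rng.choice(["any", "upstream", "downstream"], p=[0.6, 0.2, 0.2])),
            internals=bool(rng.random() < 0.3),
        )
        if rng.random() < 0.3:
            q.filter_attribute = "gene_biotype"
            q.attribute_values = list(
                rng.choice(all_biotypes, size=int(rng.integers(1, 3)), replace=False)
            )
        queries.append(q)
    cfg = ConfigSpec(queries=queries, priority=bool(rng.random() < 0.5))
    return peaks, features, cfg


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_anchor_positions(f: Feature, anchors: tuple[str, ...]) -> list[tuple[str, int]]:
    out = []
    for name in ("start", "center", "end"):
        if name not in anchors:
            continue
        if name == "center":
            pos = (f.start + f.end - 1) // 2
        elif name == "start":
            pos = f.end - 1 if f.strand == "-" else f.start
        else:
            pos = f.start if f.strand == "-" else f.end - 1
        out.append((name, pos))
    return out


def _oracle_offset(center: int, pos: int, strand: str) -> int:
    return pos - center if strand == "-" else center - pos


def _oracle_passes(p: Peak, f: Feature, q: QuerySpec) -> bool:
    if q.features and f.feature_type not in q.features:
        return False
    if q.filter_attribute is not None and (
        q.filter_attribute not in f.attributes
        or f.attributes[q.filter_attribute] not in q.attribute_values
    ):
        return False
    if q.strand_mode == "same" and (p.strand == "." or p.strand != f.strand):
        return False
    if q.strand_mode == "opposite" and (
        p.strand == "." or f.strand == "." or p.strand == f.strand
    ):
        return False
    if q.direction == "upstream":
        five = f.end - 1 if f.strand == "-" else f.start
        if _oracle_offset(p.center, five, f.strand) >= 0:
            return False
    if q.direction == "downstream":
        three = f.start if f.strand == "-" else f.end - 1
        if _oracle_offset(p.center, three, f.strand) <= 0:
            return False
    return True


def _oracle_location(p: Peak, f: Feature) -> str:
    inter = min(p.end, f.end) - max(p.start, f.start)
    minus = f.strand == "-"
    if inter <= 0:
        left = p.end <= f.start
        if left:
            return "Downstream" if minus else "Upstream"
        return "Upstream" if minus else "Downstream"
    if f.start <= p.start and p.end <= f.end:
        return "PeakInsideFeature"
    if p.start <= f.start and f.end <= p.end:
        return "FeatureInsidePeak"
    if p.start <= f.start:
        return "OverlapEnd" if minus else "OverlapStart"
    return "OverlapStart" if minus else "OverlapEnd"


def _oracle_hit(p: Peak, f: Feature, q: QuerySpec) -> CandidateHit | None:
    offsets = [
        (name, pos, _oracle_offset(p.center, pos, f.strand))
        for name, pos in _oracle_anchor_positions(f, q.anchors)
    ]
    ok = [(n, pp, o) for n, pp, o in offsets
          if -q.distance_upstream <= o <= q.distance_downstream]
    via_internals = False
    if not ok:
        center_in = f.start <= p.center < f.end
        feat_in = p.start <= f.start and f.end <= p.end
        if q.internals and (center_in or feat_in):
            ok = offsets
            via_internals = True
        else:
            return None
    best = ok[0]
    for cand in ok[1:]:
        if abs(cand[2]) < abs(best[2]):
            best = cand
    name, pos, off = best
    inter = max(0, min(p.end, f.end) - max(p.start, f.start))
    return CandidateHit(
        peak=p,
        query_index=q.index,
        feature=f,
        best_anchor=name,
        anchor_pos=pos,
        distance=abs(off),
        signed_offset=off,
        relative_location=_oracle_location(p, f),
        feat_ovl_peak=inter / (p.end - p.start),
        peak_ovl_feat=inter / (f.end - f.start),
        via_internals=via_internals,
    )


def _oracle_sorted(hits: list[CandidateHit], show: list[str]) -> list[CandidateHit]:
    def key(h: CandidateHit):
        attr = h.feature.attributes.get(show[0], "") if show else ""
        return (h.distance, h.feature.start, h.feature.end, attr)

    out = list(hits)
    # insertion sort: simple, independent of the production path's sorted()
    for i in range(1, len(out)):
        j = i
        while j > 0 and key(out[j]) < key(out[j - 1]):
            out[j], out[j - 1] = out[j - 1], out[j]
            j -= 1
    return out


def brute_force_annotate(peaks: list[Peak], features: list[Feature], cfg: ConfigSpec,
                         show_attributes: list[str] | None = None) -> ResultTables:
    """Naive reference annotation: every rule by direct iteration.

    Matches chromosome names with the same leading-``chr`` normalization
    as the indexed path, but scans all features for every peak with no
    index and no chunking. Intended for small instances only.
    """
    show = show_attributes or []

    def chrom_key(name: str) -> str:
        return name[3:] if name.lower().startswith("chr") else name

    annotations: list[PeakAnnotation] = []
    for p in peaks:
        ann = PeakAnnotation(peak=p, best_per_query=[None] * len(cfg.queries))
        per_query: list[list[CandidateHit]] = [[] for _ in cfg.queries]
        for q in cfg.queries:
            hits = []
            for f in features:
                if chrom_key(f.chrom) != chrom_key(p.chrom):
                    continue
                if not _oracle_passes(p, f, q):
                    continue
                hit = _oracle_hit(p, f, q)
                if hit is not None:
                    hits.append(hit)
            per_query[q.index] = _oracle_sorted(hits, show)
            if cfg.priority and hits:
                break
        for qi, hits in enumerate(per_query):
            ann.all_hits.extend(hits)
            if hits:
                ann.best_per_query[qi] = hits[0]
        final = None
        for hit in ann.best_per_query:
            if hit is None:
                continue
            if final is None or (hit.distance, hit.query_index) < (final.distance, final.query_index):
                final = hit
        ann.final = final
        annotations.append(ann)
    return ResultTables(annotations=annotations, n_queries=len(cfg.queries))
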