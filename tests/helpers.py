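"""Shared construction and comparison helpers for the test suite."""

from peakanno.annotate import CandidateHit, ResultTables
from peakanno.io_genomic import Feature, Peak


def peak(start, end, chrom="chr1", strand=".", pid="p"):
    return Peak(id=pid, chrom=chrom, start=start, end=end, strand=strand)


def feature(start, end, chrom="chr1", strand="+", ftype="gene", **attrs):
    return Feature(
        chrom=chrom, source="t", feature_type=ftype, start=start, end=end,
        score=".", strand=strand, frame=".", attributes=attrs or {"gene_id": "g"},
    )


def hit_key(h: CandidateHit):
    """Canonical comparable representation of a hit."""
    return (
        h.peak.id,
        h.query_index,
        h.feature.chrom,
        h.feature.start,
        h.feature.end,
        h.feature.feature_type,
        h.feature.attributes.get("gene_id"),
        h.best_anchor,
        h.anchor_pos,
        h.distance,
        h.signed_offset,
        h.relative_location,
        round(h.feat_ovl_peak, 9),
        round(h.peak_ovl_feat, 9),
        h.via_internals,
    )


def tables_repr(rt: ResultTables):
    """Comparable representation of all three result tables."""
    out = []
    for ann in rt.annotations:
        out.append(
            (
                ann.peak.id,
                [hit_key(h) for h in ann.all_hits],
                [None if h is None else hit_key(h) for h in ann.best_per_query],
                None if ann.final is None else hit_key(ann.final),
            )
        )
    return out
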