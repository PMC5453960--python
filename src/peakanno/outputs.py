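"""Tab-separated result tables.

Three files share one fixed column order: ``<prefix>_allhits.txt`` (every
candidate from any query, plus one NA row per peak with no hit anywhere),
``<prefix>_besthits.txt`` (top candidate per peak and query; written only
for multi-query runs) and ``<prefix>_finalhits.txt`` (exactly one row per
peak). Feature coordinates are written back in GTF's 1-based inclusive
convention; missing values are the literal string ``NA``. An optional
*condensed* variant joins all candidate rows of a peak into one row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import CandidateHit, ResultTables
from .io_genomic import Peak

__all__ = ["OutputSchema", "FIXED_COLUMNS", "table_frames", "write_tables", "condense"]

FIXED_COLUMNS = [
    "peak_id",
    "peak_chr",
    "peak_start",
    "peak_center",
    "peak_end",
    "feature",
    "feat_start",
    "feat_end",
    "feat_strand",
    "feat_anchor",
    "distance",
    "relative_location",
    "feat_ovl_peak",
    "peak_ovl_feat",
    "query",
]

#: columns filled with "NA" when a peak/query has no hit
_FEATURE_COLUMNS = FIXED_COLUMNS[5:]


@dataclass
class OutputSchema:
    """Column layout of the result tables: fixed columns + show-attributes."""

    show_attributes: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return FIXED_COLUMNS + self.show_attributes


def _peak_fields(p: Peak) -> dict[str, object]:
    return {
        "peak_id": p.id,
        "peak_chr": p.chrom,
        "peak_start": p.start,
        "peak_center": p.center,
        "peak_end": p.end,
    }


def _hit_row(hit: CandidateHit, schema: OutputSchema) -> dict[str, object]:
    f = hit.feature
    row = _peak_fields(hit.peak)
    row.update(
        feature=f.feature_type,
        feat_start=f.start + 1,  # back to GTF convention
        feat_end=f.end,
        feat_strand=f.strand,
        feat_anchor=hit.best_anchor,
        distance=str(hit.distance),
        relative_location=hit.relative_location,
        feat_ovl_peak=f"{hit.feat_ovl_peak:.2f}",
        peak_ovl_feat=f"{hit.peak_ovl_feat:.2f}",
        query=str(hit.query_index),
    )
    for key in schema.show_attributes:
        row[key] = f.attributes.get(key, "NA")
    return row


def _na_row(p: Peak, schema: OutputSchema, query: str = "NA") -> dict[str, object]:
    row = _peak_fields(p)
    for col in _FEATURE_COLUMNS + schema.show_attributes:
        row[col] = "NA"
    row["query"] = query
    return row


def table_frames(rt: ResultTables, schema: OutputSchema) -> dict[str, pd.DataFrame]:
    """Build the allhits/besthits/finalhits tables as DataFrames."""
    all_rows: list[dict] = []
    best_rows: list[dict] = []
    final_rows: list[dict] = []
    for ann in rt.annotations:
        if ann.all_hits:
            all_rows.extend(_hit_row(h, schema) for h in ann.all_hits)
        else:
            all_rows.append(_na_row(ann.peak, schema))
        for qi in range(rt.n_queries):
            hit = ann.best_per_query[qi]
            if hit is not None:
                best_rows.append(_hit_row(hit, schema))
            else:
                best_rows.append(_na_row(ann.peak, schema, query=str(qi)))
        if ann.final is not None:
            final_rows.append(_hit_row(ann.final, schema))
        else:
            final_rows.append(_na_row(ann.peak, schema))
    cols = schema.columns
    return {
        "allhits": pd.DataFrame(all_rows, columns=cols),
        "besthits": pd.DataFrame(best_rows, columns=cols),
        "finalhits": pd.DataFrame(final_rows, columns=cols),
    }


def condense(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple hit rows per peak into one row per peak.

    Feature-derived fields of the peak's hits are joined by ``;`` in their
    existing (rank) order; peak fields appear once. Single-hit and NA rows
    pass through unchanged.
    """
    join_cols = [c for c in df.columns if c not in FIXED_COLUMNS[:5]]
    out_rows = []
    for _, group in df.groupby("peak_id", sort=False):
        row = group.iloc[0].to_dict()
        if len(group) > 1:
            for col in join_cols:
                row[col] = ";".join(str(v) for v in group[col])
        out_rows.append(row)
    return pd.DataFrame(out_rows, columns=df.columns)


def write_tables(rt: ResultTables, schema: OutputSchema, prefix: str | Path,
                 condensed: bool = False) -> list[Path]:
    """Write the result tables next to ``prefix``; returns the paths written.

    ``besthits`` is emitted only for multi-query runs (with a single query
    it would duplicate ``finalhits``). With ``condensed=True`` an
    additional ``*_allhits_condensed.txt`` summarizes each peak's
    candidates in one row.
    """
    prefix = Path(prefix)
    frames = table_frames(rt, schema)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = prefix.parent / f"{prefix.name}_{name}.txt"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    emit("allhits", frames["allhits"])
    if rt.n_queries > 1:
        emit("besthits", frames["besthits"])
    emit("finalhits", frames["finalhits"])
    if condensed:
        emit("allhits_condensed", condense(frames["allhits"]))
    return written
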