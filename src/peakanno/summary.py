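"""Annotation statistics and the graphical summary report.

Statistics derive from the *best-per-query* results: per query the number
of annotated peaks, feature-type occurrence counts, the distances (signed
offsets are plotted, so upstream/downstream asymmetry stays visible) and
relative-location counts; across queries the pairwise overlap of
annotated peak-id sets. The report renders one panel per page into a
single PDF: distance density per query, relative-location pies per
feature, feature-occurrence bars, the pairwise-overlap heatmap, distance
histograms per query and feature, and a set diagram of the per-query
annotated peak sets (exact counts; up to three queries as a circle
diagram, four or five as a membership-bar plot).
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.patches import Circle

from .annotate import ResultTables

__all__ = ["QueryStats", "SummaryStats", "compute_stats", "render_report", "write_stats_json"]


@dataclass
class QueryStats:
    """Counts and distributions for one query (from best-per-query rows)."""

    annotated: int = 0
    feature_counts: Counter = field(default_factory=Counter)
    distances: list[int] = field(default_factory=list)
    signed_offsets: list[int] = field(default_factory=list)
    location_counts: dict[str, Counter] = field(default_factory=dict)  # feature type -> counter
    distance_by_feature: dict[str, list[int]] = field(default_factory=dict)
    peak_ids: set[str] = field(default_factory=set)


@dataclass
class SummaryStats:
    n_peaks: int
    per_query: list[QueryStats]
    overlap: np.ndarray  # pairwise annotated-peak-set overlap counts


def compute_stats(rt: ResultTables) -> SummaryStats:
    """Aggregate best-per-query results into :class:`SummaryStats`.

    NA entries (peak/query pairs without a hit) are excluded from every
    distribution. The overlap matrix is symmetric with the per-query
    annotated counts on its diagonal.
    """
    per_query = [QueryStats() for _ in range(rt.n_queries)]
    for ann in rt.annotations:
        for qi in range(rt.n_queries):
            hit = ann.best_per_query[qi]
            if hit is None:
                continue
            qs = per_query[qi]
            ftype = hit.feature.feature_type
            qs.annotated += 1
            qs.feature_counts[ftype] += 1
            qs.distances.append(hit.distance)
            qs.signed_offsets.append(hit.signed_offset)
            qs.location_counts.setdefault(ftype, Counter())[hit.relative_location] += 1
            qs.distance_by_feature.setdefault(ftype, []).append(hit.distance)
            qs.peak_ids.add(ann.peak.id)
    n = rt.n_queries
    overlap = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            overlap[i, j] = len(per_query[i].peak_ids & per_query[j].peak_ids)
    return SummaryStats(n_peaks=len(rt.annotations), per_query=per_query, overlap=overlap)


def write_stats_json(stats: SummaryStats, path: str | Path) -> None:
    """Machine-readable companion to the PDF report."""
    payload = {
        "n_peaks": stats.n_peaks,
        "queries": [
            {
                "annotated_peaks": qs.annotated,
                "feature_counts": dict(qs.feature_counts),
                "relative_locations": {ft: dict(c) for ft, c in qs.location_counts.items()},
                "median_distance": float(np.median(qs.distances)) if qs.distances else None,
            }
            for qs in stats.per_query
        ],
        "pairwise_overlap": stats.overlap.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _placeholder(pdf: PdfPages, text: str) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.axis("off")
    ax.text(0.5, 0.5, text, ha="center", va="center", fontsize=14)
    pdf.savefig(fig)
    plt.close(fig)


def _distance_density(pdf: PdfPages, stats: SummaryStats) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    plotted = False
    for qi, qs in enumerate(stats.per_query):
        if not qs.signed_offsets:
            continue
        offs = np.asarray(qs.signed_offsets, dtype=float)
        lo, hi = offs.min(), offs.max()
        if lo == hi:  # degenerate: all offsets identical
            ax.axvline(lo, label=f"query {qi} (n={len(offs)})")
        else:
            grid = np.linspace(lo, hi, 200)
            bw = max((hi - lo) / 20.0, 1.0)
            dens = np.exp(-0.5 * ((grid[:, None] - offs[None, :]) / bw) ** 2).sum(axis=1)
            dens /= dens.sum() * (grid[1] - grid[0])
            ax.plot(grid, dens, label=f"query {qi} (n={len(offs)})")
        plotted = True
    ax.set_xlabel("signed offset of peak center from feature anchor (bp)")
    ax.set_ylabel("density")
    ax.set_title("Distance to feature anchor (signed; negative = upstream)")
    if plotted:
        ax.legend()
    pdf.savefig(fig)
    plt.close(fig)


def _location_pies(pdf: PdfPages, stats: SummaryStats) -> None:
    for qi, qs in enumerate(stats.per_query):
        for ftype, counter in sorted(qs.location_counts.items()):
            fig, ax = plt.subplots(figsize=(6, 6))
            labels, sizes = zip(*sorted(counter.items()))
            ax.pie(sizes, labels=labels, autopct="%1.0f%%")
            ax.set_title(f"Relative peak location — query {qi}, feature '{ftype}'")
            pdf.savefig(fig)
            plt.close(fig)


def _feature_bars(pdf: PdfPages, stats: SummaryStats) -> None:
    for qi, qs in enumerate(stats.per_query):
        if not qs.feature_counts:
            continue
        fig, ax = plt.subplots(figsize=(7, 5))
        items = sorted(qs.feature_counts.items())
        ax.bar([k for k, _ in items], [v for _, v in items])
        ax.set_ylabel("annotated peaks")
        ax.set_title(f"Feature occurrences — query {qi}")
        pdf.savefig(fig)
        plt.close(fig)


def _overlap_heatmap(pdf: PdfPages, stats: SummaryStats) -> None:
    n = len(stats.per_query)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(stats.overlap, cmap="viridis")
    ax.set_xticks(range(n), [f"q{i}" for i in range(n)])
    ax.set_yticks(range(n), [f"q{i}" for i in range(n)])
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(stats.overlap[i, j]), ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="shared annotated peaks")
    ax.set_title("Pairwise overlap of annotated peak sets")
    pdf.savefig(fig)
    plt.close(fig)


def _distance_histograms(pdf: PdfPages, stats: SummaryStats) -> None:
    for qi, qs in enumerate(stats.per_query):
        for ftype, dists in sorted(qs.distance_by_feature.items()):
            fig, ax = plt.subplots(figsize=(7, 5))
            ax.hist(dists, bins=min(30, max(5, len(dists))))
            ax.set_xlabel("distance (bp)")
            ax.set_ylabel("peaks")
            ax.set_title(f"Distance histogram — query {qi}, feature '{ftype}'")
            pdf.savefig(fig)
            plt.close(fig)


def _region_counts(sets: list[set[str]]) -> dict[tuple[int, ...], int]:
    """Exclusive region sizes of a small set family, by membership pattern."""
    n = len(sets)
    universe = set().union(*sets) if sets else set()
    counts: dict[tuple[int, ...], int] = {}
    for pattern in itertools.product((0, 1), repeat=n):
        if not any(pattern):
            continue
        region = universe.copy()
        for i, bit in enumerate(pattern):
            region = region & sets[i] if bit else region - sets[i]
        counts[pattern] = len(region)
    return counts


def _set_diagram(pdf: PdfPages, stats: SummaryStats) -> None:
    sets = [qs.peak_ids for qs in stats.per_query]
    n = len(sets)
    counts = _region_counts(sets)
    if n <= 3:
        # fixed-layout circle diagram with exact counts per region
        centers = {2: [(-0.5, 0), (0.5, 0)], 3: [(-0.5, -0.3), (0.5, -0.3), (0, 0.57)]}[n]
        label_pos = {
            2: {(1, 0): (-0.9, 0), (0, 1): (0.9, 0), (1, 1): (0, 0)},
            3: {
                (1, 0, 0): (-0.9, -0.5),
                (0, 1, 0): (0.9, -0.5),
                (0, 0, 1): (0, 1.0),
                (1, 1, 0): (0, -0.45),
                (1, 0, 1): (-0.5, 0.25),
                (0, 1, 1): (0.5, 0.25),
                (1, 1, 1): (0, 0),
            },
        }[n]
        fig, ax = plt.subplots(figsize=(6, 6))
        for i, (x, y) in enumerate(centers):
            ax.add_patch(Circle((x, y), 1.0, alpha=0.3, label=f"query {i}"))
            ax.annotate(f"q{i}", (x * 1.8, y * 1.8 if y else -1.3), ha="center")
        for pattern, (x, y) in label_pos.items():
            ax.text(x, y, str(counts.get(pattern, 0)), ha="center", va="center", fontsize=12)
        ax.set_xlim(-2.2, 2.2)
        ax.set_ylim(-2.2, 2.2)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title("Annotated peaks per query (region counts exact, areas schematic)")
    else:
        # membership-bar fallback (UpSet-style) for 4-5 queries
        nonzero = sorted(
            ((p, c) for p, c in counts.items() if c > 0), key=lambda pc: -pc[1]
        )
        fig, (ax_bar, ax_dot) = plt.subplots(
            2, 1, figsize=(max(7, len(nonzero)), 6), sharex=True,
            gridspec_kw={"height_ratios": [3, 1]},
        )
        xs = range(len(nonzero))
        ax_bar.bar(xs, [c for _, c in nonzero])
        ax_bar.set_ylabel("peaks")
        for x, (pattern, _) in zip(xs, nonzero):
            for qi, bit in enumerate(pattern):
                ax_dot.plot(x, qi, "o", color="k" if bit else "0.85")
        ax_dot.set_yticks(range(n), [f"q{i}" for i in range(n)])
        ax_dot.set_xticks([])
        ax_bar.set_title("Exclusive membership of annotated peaks across queries")
    pdf.savefig(fig)
    plt.close(fig)


def render_report(stats: SummaryStats, path: str | Path) -> Path:
    """Render the multi-page PDF report; returns the written path.

    Single-query runs omit the cross-query panels; a run with no
    annotated peak at all yields a placeholder page instead of a crash.
    """
    path = Path(path)
    any_annotated = any(qs.annotated for qs in stats.per_query)
    with PdfPages(path) as pdf:
        if not any_annotated:
            _placeholder(pdf, "No annotations — nothing to summarize")
            return path
        _distance_density(pdf, stats)
        _location_pies(pdf, stats)
        _feature_bars(pdf, stats)
        if len(stats.per_query) > 1:
            _overlap_heatmap(pdf, stats)
        _distance_histograms(pdf, stats)
        if 1 < len(stats.per_query) <= 5:
            _set_diagram(pdf, stats)
    return path
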