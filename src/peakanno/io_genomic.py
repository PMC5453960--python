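"""BED/GTF input, interval indexing, and the tab-to-GTF converter.

All internal coordinates are 0-based half-open. GTF records (1-based,
inclusive) are converted on read and re-converted on write; BED is taken
as-is. Chromosome names are normalized for matching only (a leading
``chr`` is stripped), so a BED using ``1`` still matches a GTF using
``chr1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "Feature",
    "FeatureIndex",
    "ParseError",
    "read_bed",
    "read_gtf",
    "write_gtf",
    "build_index",
    "query_window",
    "tab_to_gtf",
]


class ParseError(ValueError):
    """Malformed BED/GTF/table input; the message names the offending line."""


@dataclass
class Peak:
    """One input genomic range (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    score: str = "."

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Feature:
    """One GTF record with coordinates converted to 0-based half-open."""

    chrom: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str
    strand: str
    frame: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_chrom(name: str) -> str:
    """Matching key for a chromosome name: leading 'chr' stripped."""
    return name[3:] if name.lower().startswith("chr") else name


def _lines(stream) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        stream = stream.splitlines()
    for lineno, line in enumerate(stream, start=1):
        yield lineno, line.rstrip("\n").rstrip("\r")


def read_bed(stream) -> list[Peak]:
    """Read BED (≥3 columns) into peaks, preserving file order.

    A missing name column yields synthesized ids ``peak_1``, ``peak_2``, …
    (numbered over data lines); missing strand becomes ``.``. ``track``,
    ``browser`` and ``#`` comment lines are skipped.
    """
    peaks: list[Peak] = []
    n = 0
    for lineno, line in _lines(stream):
        if not line.strip():
            continue
        if line.startswith(("track", "browser", "#")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"BED line {lineno}: fewer than 3 columns: {line!r}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"BED line {lineno}: non-integer coordinate: {line!r}") from None
        if start >= end:
            raise ParseError(f"BED line {lineno}: start >= end ({start} >= {end})")
        n += 1
        name = cols[3] if len(cols) > 3 and cols[3] != "" else f"peak_{n}"
        score = cols[4] if len(cols) > 4 else "."
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
        peaks.append(Peak(id=name, chrom=cols[0], start=start, end=end, strand=strand, score=score))
    return peaks


_GTF_ATTR = re.compile(r'\s*(\S+)\s+"([^"]*)"\s*')
_GFF_ATTR = re.compile(r"\s*([^=;\s]+)\s*=\s*([^;]*?)\s*$")


def _parse_attributes(col9: str, lineno: int) -> tuple[dict[str, str], str]:
    """Parse GTF column 9; returns (attributes, dialect).

    Tries the GTF dialect ``key "value";`` first, then falls back to the
    GFF-style ``key=value``. Duplicate keys keep the first value.
    """
    attrs: dict[str, str] = {}
    dialect = None
    for token in col9.strip().split(";"):
        if not token.strip():
            continue
        m = _GTF_ATTR.fullmatch(token)
        if m:
            token_dialect = "gtf"
        else:
            m = _GFF_ATTR.fullmatch(token)
            if m:
                token_dialect = "gff"
            else:
                raise ParseError(f"GTF line {lineno}: unparseable attribute token {token!r}")
        if dialect is None:
            dialect = token_dialect
        elif dialect != token_dialect:
            raise ParseError(f"GTF line {lineno}: mixed attribute dialects in {col9!r}")
        key, value = m.group(1), m.group(2)
        attrs.setdefault(key, value)
    return attrs, dialect or "gtf"


def read_gtf(stream) -> list[Feature]:
    """Read GTF into features, converting to 0-based half-open coordinates.

    ``#`` comment lines are skipped; attribute values are unquoted;
    duplicate attribute keys keep the first value. A file mixing the GTF
    and GFF attribute dialects across lines is rejected.
    """
    features: list[Feature] = []
    file_dialect: str | None = None
    for lineno, line in _lines(stream):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ParseError(f"GTF line {lineno}: expected 9 columns, got {len(cols)}: {line!r}")
        try:
            start1, end1 = int(cols[3]), int(cols[4])
        except ValueError:
            raise ParseError(f"GTF line {lineno}: non-integer coordinates: {line!r}") from None
        attrs, dialect = _parse_attributes(cols[8], lineno)
        if attrs:
            if file_dialect is None:
                file_dialect = dialect
            elif file_dialect != dialect:
                raise ParseError(
                    f"GTF line {lineno}: attribute dialect '{dialect}' differs from "
                    f"earlier lines ('{file_dialect}')"
                )
        features.append(
            Feature(
                chrom=cols[0],
                source=cols[1],
                feature_type=cols[2],
                start=start1 - 1,
                end=end1,
                score=cols[5],
                strand=cols[6] if cols[6] in ("+", "-") else ".",
                frame=cols[7],
                attributes=attrs,
            )
        )
    return features


def write_gtf(features: Iterable[Feature]) -> str:
    """Serialize features back to GTF text (1-based inclusive coordinates)."""
    lines = []
    for f in features:
        attrs = " ".join(f'{k} "{v}";' for k, v in f.attributes.items())
        lines.append(
            "\t".join(
                (
                    f.chrom,
                    f.source,
                    f.feature_type,
                    str(f.start + 1),
                    str(f.end),
                    f.score,
                    f.strand,
                    f.frame,
                    attrs,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


class FeatureIndex:
    """Chromosome-partitioned interval index over features.

    Chromosome names are normalized symmetrically (leading ``chr``
    stripped) so BED and GTF naming conventions interoperate.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.n_features = 0

    def add(self, feature: Feature) -> None:
        key = normalize_chrom(feature.chrom)
        tree = self._trees.setdefault(key, IntervalTree())
        tree.addi(feature.start, feature.end, (self.n_features, feature))
        self.n_features += 1

    def query(self, chrom: str, wstart: int, wend: int) -> list[Feature]:
        """Features intersecting [wstart, wend), ascending by start.

        Ties on start break by end then by input order, giving a stable,
        deterministic ordering. Unknown chromosomes yield an empty list.
        """
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = tree.overlap(wstart, wend)
        ordered = sorted(hits, key=lambda iv: (iv.begin, iv.end, iv.data[0]))
        return [iv.data[1] for iv in ordered]

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)


def build_index(features: Iterable[Feature]) -> FeatureIndex:
    """Build a :class:`FeatureIndex` from parsed features."""
    index = FeatureIndex()
    for f in features:
        index.add(f)
    return index


def query_window(index: FeatureIndex, chrom: str, wstart: int, wend: int) -> list[Feature]:
    """Features whose span intersects [wstart, wend) on ``chrom``."""
    if wstart >= wend:
        raise ValueError(f"empty window: [{wstart}, {wend})")
    return index.query(chrom, wstart, wend)


_CHROM_NAMES = ("chr", "chrom", "chromosome")
_STANDARD_COLS = ("source", "feature", "score", "strand", "frame")


def tab_to_gtf(table: Iterable[str], source: str = ".", feature: str = ".") -> list[str]:
    """Convert a tab-delimited table with header into GTF lines.

    The header must contain columns identifiable as chromosome
    (``chr``/``chrom``/``chromosome``), ``start`` and ``end``
    (case-insensitive). Standard GTF columns present in the input
    (source, feature, score, strand, frame) pass through; absent ones are
    filled with dots, except source/feature which take the supplied
    parameters. Every remaining column becomes a ``key "value";`` pair in
    the attribute column. Coordinates are emitted as given — the input is
    assumed to already use GTF's 1-based inclusive convention.
    """
    it = iter(_lines(table))
    try:
        _, header_line = next(it)
    except StopIteration:
        raise ParseError("empty table: no header line") from None
    header = header_line.split("\t")
    lower = [h.strip().lower() for h in header]

    def find(names: tuple[str, ...]) -> int | None:
        for i, h in enumerate(lower):
            if h in names:
                return i
        return None

    ichrom = find(_CHROM_NAMES)
    istart = find(("start",))
    iend = find(("end",))
    if ichrom is None or istart is None or iend is None:
        raise ParseError(
            f"table header must contain chromosome/start/end columns; got {header}"
        )
    std_idx = {name: find((name,)) for name in _STANDARD_COLS}
    known = {ichrom, istart, iend} | {i for i in std_idx.values() if i is not None}
    extra = [i for i in range(len(header)) if i not in known]

    out: list[str] = []
    for lineno, line in it:
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < len(header):
            raise ParseError(f"table line {lineno}: expected {len(header)} columns, got {len(cols)}")

        def std(name: str, default: str) -> str:
            i = std_idx[name]
            return cols[i] if i is not None and cols[i] != "" else default

        attrs = " ".join(f'{header[i].strip()} "{cols[i]}";' for i in extra)
        out.append(
            "\t".join(
                (
                    cols[ichrom],
                    std("source", source),
                    std("feature", feature),
                    cols[istart],
                    cols[iend],
                    std("score", "."),
                    std("strand", "."),
                    std("frame", "."),
                    attrs,
                )
            )
        )
    return out
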