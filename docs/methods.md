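# Methods

## Coordinates and conventions

All internal coordinates are 0-based half-open. GTF input (1-based
inclusive) is converted on read and re-emitted in GTF convention in the
result tables, so `feat_start`/`feat_end` match the user's reference
file; BED is used as-is. The invariant `internal length = GTF(end − start
+ 1)` is tested for every parsed record. Chromosome names are normalized
only for matching (a leading `chr` is stripped case-insensitively), so a
BED naming chromosomes `1` matches a GTF naming them `chr1`; output
preserves the input spelling.

The peak **center** is `floor((start + end) / 2)`. Feature anchors are
interpreted in feature orientation: `start` is the 5′-most base, `end`
the 3′-most base (for minus-strand features these are the genomic right
and left edges respectively), and `center` is
`floor((start + end − 1) / 2)` — the middle base, identical for both
strands. Unstranded features (`.`) are oriented as `+`. The signed offset
of a peak center from an anchor is positive downstream and negative
upstream in feature orientation; the reported distance is its absolute
value.

## Query semantics

A query accepts a feature for a peak when all of the following hold:

1. the feature type is in the query's `feature` list (empty = any);
2. if `filter.attribute` is set, the feature carries that attribute with
   one of the accepted values (a feature lacking the key fails);
3. the strand mode passes — `ignore` always; `same` requires a stranded
   peak equal to the feature strand; `opposite` requires both stranded
   and unequal;
4. the direction passes — `upstream` requires the peak center strictly
   5′ of the feature's start anchor, `downstream` strictly 3′ of its end
   anchor, both regardless of which anchors the query requests; a peak
   centered inside the feature fails both;
5. the distance test passes at some requested anchor: signed offset in
   `[−d_up, +d_down]`, both boundaries inclusive — or the internals rule
   applies.

The **internals** rule is symmetric: the peak center lies within the
feature span, or the feature lies wholly within the peak span. Such hits
are flagged `via_internals` and may report distances exceeding the
window. Candidate retrieval scans the index over
`[center − W, center + W + 1)` with `W = max(d_up, d_down)`; when
internals is active the peak's own span is scanned too, so a feature
contained in a wide peak is found even when all of its anchors are far
from the peak center.

Among anchors that pass the window, the hit records the one minimizing
the absolute offset (ties resolve in start/center/end order); only when
acceptance came solely from the internals rule is the minimum taken over
all requested anchors. This keeps the invariant that a non-internals
hit's signed offset always lies within the query window.

## Ranking and merging

Per query, candidates sort by ascending distance, then feature start,
then feature end, then the value of the first show-attribute — a total,
deterministic order (the tie-break is a design choice; any stable rule
would do, but it must be fixed for reproducible output). The final hit of
a peak is the minimum-distance per-query best with ties to the lower
query index. With `priority = true`, queries are evaluated in order and
the first with any candidate terminates the search; later queries
contribute nothing for that peak, not even to the all-hits table — the
search genuinely aborts, which is what makes priority classifications
exclusive. Peaks with no hit in any query produce one `NA` row in each
table (the literal string `NA` in every feature-derived column).

Relative location is categorized from the interval geometry: disjoint
spans are Upstream/Downstream in feature orientation; containment gives
PeakInsideFeature or FeatureInsidePeak (identical spans count as
PeakInsideFeature); a partial overlap covering the feature's 5′ end is
OverlapStart, covering its 3′ end OverlapEnd. An exhaustive sweep test
verifies these categories partition all placements with no gaps.

## Defaults

Where a query omits a key: any feature type; window `[100000, 100000]`
(permissive enough to emulate plain closest-feature annotation on
mammalian gene densities, and always configurable); all three anchors
with closest-anchor-wins; strand ignored; no direction constraint;
internals off; priority off. Query keys accept both `.` and `_`
spellings; unknown keys are fatal rather than ignored so that typos
cannot silently change an analysis.

## Parallelism

Peaks are independent — queries interact only through the priority flag,
never across peaks — so parallel runs split the peak list into contiguous
balanced chunks, annotate each in a worker process, and concatenate in
chunk order. Output files are byte-identical for any thread count; the
test suite asserts this for 1/2/4/8 workers on a 10,000-peak run.
Near-linear scaling is hardware-dependent and not asserted.

## Summary statistics

Statistics derive from the best-per-query table: annotated-peak counts,
feature-type occurrences, distance distributions, relative-location
counts, and the pairwise overlap matrix of annotated peak-id sets. The
distance density panel plots *signed* offsets (noted in the axis label)
so asymmetric windows remain visible; distances elsewhere are absolute.
The query-set diagram shows exact region counts; for two or three queries
it is drawn as a fixed-layout circle diagram whose areas are schematic,
not proportional — area-proportional rendering is a cosmetic concern and
out of scope — and for four or five queries a membership-bar plot is used.
Runs with no annotated peaks render a placeholder page rather than
failing.

## Synthetic data and the oracle

`fixtures.make_annotation` emulates a compact reference slice: features
with a gene/transcript/exon type mixture (50/30/20 by default), a
protein_coding/pseudogene/lincRNA biotype mixture (60/20/20) under
`gene_biotype`, both strands equally, lengths 500 bp–20 kb on a 1 Mb
chromosome — about one feature per 10 kb, i.e. gene-dense but not
pathological. It does not model nested gene structure, overlapping
isoforms, or chromatin signal, so passing tests demonstrate the interval
logic, not robustness to every real-annotation quirk (overlapping
transcripts are nevertheless exercised, since random features freely
overlap). `make_peaks_at_offsets` places peak centers at exact signed
offsets from chosen anchors, giving ground truth by construction for
window-boundary tests.

`fixtures.brute_force_annotate` is an independent reference
implementation: it restates every filter, the distance test, ranking
(insertion sort) and merging in plain arithmetic over all peak × feature
pairs, sharing only the data classes with the production path. The
acceptance suite asserts exact equality of all three tables on 200
randomized instances (≤50 features, ≤20 peaks, 1–4 queries with random
windows, anchors, strand modes, directions, attribute filters, internals
and priority); problem sizes were chosen to cover every code path many
times over while keeping the whole suite fast.

## Known limitations

- Distances are always measured from the peak center, never the edges.
- Gene-model awareness (exon/intron resolution) is achieved by querying
  those feature types, not by a built-in gene model.
- The GTF parser accepts the `key "value";` dialect with a per-file
  fallback to `key=value`; files mixing both dialects are rejected.
- The tab-to-GTF converter copies coordinates verbatim and assumes its
  input is already 1-based inclusive; it is a formatter, not a
  coordinate interpreter.
- On-disk index caching is not implemented; the in-memory interval index
  is rebuilt per run (building 10⁵ features takes on the order of a
  second).
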