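# peakanno

Configurable, multi-query annotation of genomic ranges against any GTF
reference.

Peak callers, methylation pipelines, and motif scanners all emit genomic
ranges — "peaks" — that must be attributed to genes or other reference
features before any downstream biology (pathway enrichment, expression
correlation, regulatory interpretation) can happen. Simple nearest-TSS
assignment is often wrong for the data at hand: histone marks such as
H3K36me3 sit over gene bodies, H3K9me3 near gene ends, enhancers far
upstream, and large genes can swallow a peak whole while every annotated
anchor is tens of kilobases away. `peakanno` is for the bioinformatician
or biologist who wants those cases handled declaratively: a JSON file of
*queries* describes which features count and where they may lie, and the
engine produces candidate, per-query-best, and final one-per-peak
annotation tables plus a graphical summary.

## The annotation model

Inputs are a BED file of ranges (0-based half-open), a GTF reference
(Gencode/Ensembl/RefSeq or any custom GTF — a converter from tab-delimited
tables is included), and a JSON configuration. Each query is a conjunction
of filters evaluated per peak:

- **feature types** (GTF column 3: `gene`, `exon`, …) and an **attribute
  filter** on column 9 (e.g. `gene_biotype = protein_coding`);
- an **asymmetric distance window** `[d_up, d_down]`: a candidate is valid
  when the signed offset *s* of the peak center from a requested **feature
  anchor** (start = 5′ end, center, or end = 3′ end, in feature
  orientation) satisfies −d_up ≤ s ≤ d_down;
- **strand mode** (ignore / same / opposite) and a **direction**
  constraint (peak strictly upstream or downstream of the feature);
- an **internals** override: a peak centered inside a feature (or a
  feature contained in the peak) is accepted regardless of anchor
  distance — the reported distance may then exceed the window.

Candidates of each query are ranked by |*s*| at the closest requested
anchor. Queries combine by OR: the *final* annotation of a peak is its
minimum-distance per-query best. With the global `priority` flag the
queries instead form a hierarchy — the first query producing any
candidate for a peak ends the search for that peak, enabling exclusive
classifications such as promoter / gene-internal / distal.

Three tables are written: `*_allhits.txt` (every candidate of every
query), `*_besthits.txt` (best candidate per peak and query; multi-query
runs only) and `*_finalhits.txt` (exactly one row per peak). Each row
carries the anchor used, signed-distance-derived fields, the peak's
relative location (Upstream, Downstream, PeakInsideFeature,
FeatureInsidePeak, OverlapStart, OverlapEnd), and mutual peak/feature
overlap fractions.

## Worked example

A synthetic 40-gene reference and 8 peaks (generated by the bundled
`peakanno.fixtures` module), annotated with a strict promoter query
(5 kb upstream / 1 kb downstream of protein-coding TSS) backed by a
permissive 20 kb any-anchor query:

```json
{"queries": [
  {"feature": "gene", "distance": [5000, 1000], "feature.anchor": "start",
   "filter.attribute": "gene_biotype", "attribute.value": "protein_coding",
   "show.attributes": ["gene_name"]},
  {"feature": "gene", "distance": 20000}],
 "gtf": "ref.gtf", "bed": "peaks.bed"}
```

```sh
peakanno -i config.json -p demo -s
```

The log reports `query 0 annotated 1/8 peaks` and `query 1 annotated 8/8
peaks`; `demo_finalhits.txt` begins:

```
peak_id  peak_chr  peak_start  peak_center  peak_end  feature  feat_start  feat_end  feat_strand  feat_anchor  distance  relative_location  feat_ovl_peak  peak_ovl_feat  query  gene_name
peak_1   chr1      376511      376888       377265    gene     378230      378891    -            end          1341      Downstream         0.00           0.00           1      GENE20
peak_2   chr1      375648      375928       376208    gene     374917      386495    -            end          1012      PeakInsideFeature  1.00           0.05           1      GENE2
peak_3   chr1      32255       32742        33229     gene     7576        21083     -            start        11660     Upstream           0.00           0.00           1      GENE12
```

`peak_1` sits 1341 bp beyond the 3′ end of GENE20 (a minus-strand gene, so
"Downstream" is to genomic left); `peak_2` lies wholly inside GENE2
(`feat_ovl_peak = 1.00`) with its center 1012 bp from the nearest anchor.
Only one peak fell inside a strict promoter, so the fallback query
provides the final annotation for the rest (`query` column = 1).
`demo_summary.pdf` adds distance densities, relative-location pies,
feature bars, the per-query overlap heatmap, and the query-set diagram;
`demo_summary.json` holds the same statistics machine-readably.

The converter turns any headered table into GTF:

```sh
peakanno-gtf sites.txt --source UCSC --feature TFBS
```

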