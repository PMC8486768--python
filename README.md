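# seqsketch

Visualization-stage analysis of mapped high-throughput sequencing reads
(ChIP-seq, RNA-seq, ATAC-seq): genome-browser custom tracks, averaged
occupancy (meta-)plots, density heatmaps, per-region signal quantification,
peak classification into genomic features, peak-to-gene association, and
conservation scoring.

It is written for the step *after* quality control, mapping and peak
calling: you have a SAM/BAM file, a chromosome-size file, RefSeq-style
transcript annotations and perhaps a BED file of peaks, and you want the
standard panel of figures and tables — reproducibly, from a library you can
script or a one-line shell command.

## The model

The genome is divided into consecutive fixed-size **bins** (the *window
resolution*, `-w`, default 100 bp). All coordinates are 0-based, half-open.
The signal unit is the **pile-up**: bin *b* gets one count for every
retained alignment whose reference span (the CIGAR M/D/N/=/X extent)
overlaps *b*. Counts are scaled by a normalization factor

> depth: 10⁶ / (total retained reads) — reads-per-million (RPM)
> spike-in: 10⁶ / (reads mapped to the exogenous genome)
> none: 1 (raw integer counts)

Every downstream quantity is linear in this track: meta-profiles are means
of anchor-relative windows (TSS, TES, peak center, or a length-rescaled
gene body), density heatmaps are the same windows kept as rows and ranked
by signal, and region summaries are (mean, max, total) over the bins a
region overlaps. Peak classification follows the multi-counting rule — a
peak overlapping *k* distinct feature categories is counted once in each —
and spie charts compare the resulting distribution to the genome's bp
composition, drawing each category at angle ∝ p_ref and radius
√(p_obs/p_ref). Conservation scoring consumes per-bp fixedStep WIG
(PhastCons) tracks directly.

## Worked example

`examples/tss_metaprofile.py` builds a promoter-enriched synthetic
experiment (5 genes, 2000 reads clustered within ±300 bp of each TSS),
aggregates the RPM track around every TSS and ranks genes by total signal:

```
$ python examples/tss_metaprofile.py
5 TSS anchors; signal at TSS 29600 RPM, at -1 kb 0 RPM
gene ranking by total TSS signal:
row_id    total  rank
  NM_1 360000.0     1
  NM_3 356500.0     2
  NM_2 343500.0     3
  NM_4 342500.0     4
  NM_0 310500.0     5
```

The 29600-vs-0 center-to-flank contrast is the signature of a TSS-bound
factor; the rank table is the heatmap row order. The other examples cover
track building (`build_track.py`), peak annotation and spie charts
(`annotate_peaks.py`), and conservation scoring
(`conservation_scores.py`); each prints what it computes and says what the
numbers mean.

The same operations are exposed as subcommands of the `seqsketch` CLI
(`build-profile`, `combine-profiles`, `tss-plot`/`tes-plot`/`gene-plot`/
`peak-plot`, `tss-map` and friends, `chip-levels`, `phastcons`,
`genome-distribution`, `match-peaks`, `match-peaks-genes`,
`make-fixtures`), each writing a job-named directory with the figure, the
data TSV, an R script that redraws the figure from the TSV, and a run
summary.

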