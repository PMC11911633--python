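# File formats

All coordinates in TSV/BED outputs are 0-based half-open unless a format's
own convention dictates otherwise (GTF: 1-based inclusive).

## Inputs

* **FASTA** — multi-record genome; sequences are uppercased on read and
  restricted to A, C, G, T, N.
* **GTF** (`reference.gtf`, `assembled.gtf`) — Ensembl attribute dialect
  (`gene_id "X"; transcript_id "Y";`); `exon` and optional `CDS` features
  are consumed, transcripts are assembled from exon lines.  CDS length must
  be divisible by 3.
* **bedGraph** (`coverage_*.bedgraph`) — `seq  start  end  depth`,
  disjoint intervals (overlaps are a format error), unlisted positions are
  depth 0.
* **Junction TSV** (`junctions.tsv`) — header
  `seq  intron_start  intron_end  strand  sample  count`; the intron is
  0-based half-open, `intron_start` the first intronic base and
  `intron_end` one past the last.  Retained-intron boundary coverage is
  encoded as two 1-nt pseudo-junctions at the intron's first and last base.
* **Counts TSV** (`counts.tsv`) — genes × samples integer matrix with a
  `gene_id` index column; **groups TSV** (`groups.tsv`) — columns
  `sample  group`.
* **GMT** — `set_name  description  gene1  gene2 …` (tab-separated).

## Outputs

* `de_{early,late}.tsv` — `gene_id  base_mean  log2fc  p  padj
  significant  direction`.
* `events_{early,late}.tsv` — `event_id  gene_id  event_type  delta_psi
  p  fdr  significant  testable`, per-role coordinate columns
  (`cassette_coords`, …) and per-sample `psi_<sample>` columns.
* `candidates.tsv` — one row per new-boundary exon with coordinates, host
  gene, boundary status, `mean_coverage`, `background_coverage`,
  `background_ratio`, donor/acceptor dinucleotides, `canonical`,
  `flanking_ratio`, per-filter `filter_*` columns, `verdict`, and (for
  CDS-intron candidates) `frame_preserving  premature_stop
  novel_aa_before_stop`.
* `novel_exons.bed` — BED6 of candidates passing all filters.
* `panel_comparison.tsv` — per characteristic: panel/background medians,
  U statistic, two-sided p, direction.
* `report.json` — per-stage counts (DE up/down, significant events by
  type, candidate funnel), package version, seed and config hash.
* `truth_*.tsv` (simulation) — planted DE genes, planted events with
  per-group PSI, planted novel exons with expected verdicts and expected
  failing filters.
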