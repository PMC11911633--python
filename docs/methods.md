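# Methods

This note documents the models, defaults and design decisions behind
`neoexon`, and what the synthetic-data generator does and does not emulate.

## Coordinate and annotation model

All internal coordinates are 0-based half-open; GTF I/O converts to/from
1-based inclusive at the file boundary, bedGraph and BED are native
0-based half-open.  Minus-strand transcripts store exons in genomic order;
transcription order is derived on demand.  A gene's *boundary index* is the
union of exon start/end coordinates over all of its transcripts and is the
reference against which "new" boundaries are called.  Junction keys are
`(seq, donor_pos, acceptor_pos, strand)` delimiting the half-open intron.

## Differential expression

The DE stage is a deliberately plain stand-in for shrinkage-based NB
frameworks; it provides thresholded calls on synthetic data, not a
reimplementation of any published estimator.

* **Normalization** — median-of-ratios against a geometric-mean reference
  over zero-free genes; if none exists, the reference falls back to genes
  with ≤ 50 % zeros (positive counts only) with a logged warning.  Inside
  the test, size factors are divided by the first sample's factor.  This is
  a pure unit convention (all normalized counts share one scale factor);
  it makes normalization absorb a rescaling of any non-anchor sample
  *exactly*, which a fully symmetric reference cannot do once the
  pseudocount below enters the fold change.
* **Dispersion** — gene-wise method of moments pooled within groups,
  `α̂ = (v̂ − m̂)/m̂²`, floored at 10⁻⁸.  No shrinkage or trend fitting.
* **Effect and test** — `log2FC = log2((m̄_B + 0.5)/(m̄_A + 0.5))`; the
  pseudocount 0.5 stabilizes zero means.  The Wald statistic uses the NB
  model variance `(m + αm²)/n` delta-methodized to the log2 scale and is
  referred to a t distribution with `n_A + n_B − 2` df — at four replicates
  per group the normal reference is visibly anti-conservative, the t
  reference keeps the null false-positive rate at ≈ 0.04–0.05.
* **Multiplicity and calls** — Benjamini–Hochberg over all genes with at
  least one nonzero count (all-zero genes are excluded from testing and
  from the BH denominator); significance is strict: `padj < 0.05` **and**
  `|log2FC| > 1`.

## Splicing

Events are defined from annotated transcript structure by pairwise isoform
comparison and deduplicated by type and defining coordinates:

* **CE** — internal exon private to one isoform whose two neighbours are
  shared and directly spliced together in the other isoform;
* **MXE** — two private, non-overlapping internal exons between the same
  shared flanks;
* **A5SS / A3SS** — two exons sharing exactly one boundary and spliced to
  the same neighbour across the variable junction; labels follow the
  transcribed strand (a variable genomic-right boundary is a 5′ event on
  `+` and a 3′ event on `−`);
* **RI** — one isoform's exon spanning an exon–intron–exon block of the
  other with matching outer boundaries.

PSI uses junction counts only, normalized by the number of distinct
junctions per side — not read-length-dependent effective lengths — because
the simulator provides junctions directly.  Retained-intron "inclusion" is
carried as two 1-nt pseudo-junction keys at the intron's first and last
base, standing in for exon–intron boundary coverage; the spliced intron is
the single skipping junction (2:1 normalization).

Differential inclusion is a Welch t-test on logit-PSI with PSI clamped to
[0.01, 0.99] to avoid infinite logits; events with fewer than two defined
replicate PSIs in either group are marked untestable and excluded from the
BH denominator.  Significance is strict: `FDR < 0.01` and `|ΔPSI| > 0.05`,
with ΔPSI = later − earlier group so that positive values mean increased
inclusion during maturation.  A gene counts as alternatively spliced if it
has ≥ 1 significant event.

## Novel-exon discovery

Internal exons of assembled transcripts are compared with the same-strand
overlapping reference gene of maximal overlap; terminal assembled exons
are excluded because assembly end boundaries are unreliable.  An exon is a
candidate if ≥ 1 boundary is absent from the host's boundary index;
candidates fully inside a reference intron with both boundaries new are
flagged `fully_novel`.  Filters run in a fixed order with a complete audit
trail:

1. **coverage** — mean per-base depth strictly `> 5` reads ("greater than
   five" is read as a strict inequality on the per-base mean);
2. **background ratio** — `mean / max(background, ε) ≥ 10`, with
   ε = 0.1.  "Surrounding intronic background" is implemented as the
   pooled base-wise mean over up to 200-nt windows on each side of the
   candidate, clipped to the host intron (gene span for boundary-modifying
   candidates) and masked of every reference or assembled exon; empty
   windows fall back to ε with a warning.  Window size and ε are exposed
   in `ThresholdConfig`;
3. **canonical splice sites** — donor = first two intronic nucleotides 3′
   of the exon, acceptor = last two intronic nucleotides 5′ of it, both on
   the transcribed strand; the default canonical set is {GT–AG} only, with
   GC–AG and AT–AC available via configuration.

The candidate/flanking-exon expression ratio is a reported score, never a
filter — it mirrors a manual review step, not an automated cut.  For a
candidate inside a CDS intron, the exon sequence is spliced into the mature
CDS at its genomic position and translated from the annotated start;
`premature_stop` marks a stop upstream of the original terminator and
`novel_aa_before_stop` counts residues from the first codon altered by the
insertion up to (excluding) the new stop.  Cross-species identity is a
global Needleman–Wunsch alignment (match +1, mismatch −1, gap open −2,
extend −1); percent identity is matches over alignment columns.

## Panel statistics

Panel-vs-background characteristic comparisons (transcript count, gene
length, maximal exon count, mean CDS length, expression) use a two-sided
Mann–Whitney U — exact when both groups have ≤ 12 untied values, normal
approximation with tie correction otherwise; the choice of test is this
package's (the comparison itself does not prescribe one).  Expression is
the mean count in the adult (last) group.  Over-representation analysis is
an upper-tail hypergeometric test per GMT set, BH-adjusted; paralog counts,
when used, are consumed as a pre-tabulated column.

## Synthetic data

The generator emulates a three-timepoint postnatal-maturation design
(E18.5, 2 weeks, 7 weeks; four replicates; 100-bp reads implied by the
coverage scale) on a single synthetic chromosome:

* **Genes** — one two-isoform gene per AS event type plus a PSI-constant
  control, 13 four-exon host genes for planted novel exons, and ~30 filler
  genes of 2–6 exons (half coding) for panel statistics.  All annotated
  introns carry GT–AG (strand-aware).
* **Counts** — NB with mean `baseline × 2^{log2FC·1[stage reached]} ×
  size factor`, dispersion 0.05, baselines log-normal(log 200, 1), size
  factors log-uniform [0.7, 1.4].  Planted fold changes default to ±2
  (baseline 400) at the early or late transition and persist afterwards.
* **Junctions** — each inclusion junction draws Poisson(depth·ψ), each
  skipping junction Poisson(depth·(1−ψ)), depth 100 informative reads per
  event, so replicate-level PSI has usable precision at n = 4 and the PSI
  estimator converges to ψ at high depth.
* **Coverage** — exonic depth Poisson(30)/base, intronic Poisson(0.5),
  *except* planted novel exons and their host introns, which are written
  at constant depth equal to their specified means.  The planting grid
  tiles both sides of every filter: mean coverage {4, 5, 6, 20},
  background ratio {8, 10, 12}, GT–AG, GC–AG and AT–AC sites, on both
  strands.  Constant depth in planted regions is deliberate: an exon
  planted exactly at a threshold (coverage 5, ratio 10) has a well-defined
  expected verdict only if its realized mean equals its nominal mean;
  Poisson noise everywhere else keeps the remaining stages realistic.
* **ORF host** — one host gene carries a full-length stop-free CDS across
  its exons and a 62-nt intronic exon designed so that, spliced in at a
  codon boundary, translation reads 14 novel residues and terminates —
  the frame-disrupting topology the discovery stage must characterize.

What the generator does **not** emulate: read-level errors and biases (GC,
positional), fragment-length effects, overdispersion of junction counts
beyond Poisson, overlapping genes, soft-clipped or mis-assembled exon
boundaries, and library-size outliers.  Passing tests therefore demonstrate
correctness of the analysis logic under the stated statistical model, not
robustness to alignment or assembly artifacts in real data.

## Determinism and numerical choices

All randomness flows through seeded `numpy` generators with fixed
sub-stream keys, so every artifact is byte-identical under a fixed seed
(asserted in tests by hashing rerun outputs).  Degenerate cases are
defined explicitly: PSI is missing when no informative reads exist; a
Welch test with zero variance in both groups returns p = 1 for equal means
and p = 0 otherwise; an empty DE overlap reports a missing consistency
fraction; all-identical pooled values give a Mann–Whitney p of 1.
Problem sizes in the test suite and acceptance script (≈ 50-gene genomes,
1000-gene count matrices, 500 null events) were chosen as the smallest
sizes at which the calibration checks have meaningful resolution.

## Known limitations

* The DE stand-in has no dispersion shrinkage; at n = 4 its power is below
  that of shrinkage estimators, and log2FC estimates are unshrunken.
* The splicing test ignores the hierarchical (within-sample binomial)
  structure of PSI; the logit-Welch approximation is calibrated at depth
  ≈ 100 but will be anti-conservative at very low junction depth.
* Discovery assumes pre-tabulated coverage and junctions (no BAM access)
  and a single assembled annotation; it does not attempt transcript-level
  quantification of the novel exon.
* The gene-collapse rule (gene is AS if ≥ 1 significant event) and the
  exact background-window definition are package decisions where the
  underlying procedure is commonly left unstated.
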