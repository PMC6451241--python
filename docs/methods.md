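# Methods

This note documents the models, procedures and design choices behind
`crmscan`, in the order data flows through the package.

## Coordinates and interval semantics

All coordinates are 0-based half-open (BED convention); GFF input is
converted on read and nothing downstream sees 1-based data. `sort_merge`
merges overlapping *and book-ended* intervals. `intersect_fraction(A, B, f)`
marks an A interval as hit when some B interval overlaps it by at least
`f` of A's own length; the comparison is `overlap/len(A) >= f` in division
form, matching the float semantics of the classic BED toolkit, so the
boundary cases (50 bp of a 500-bp interval at f = 0.10; 100 bp of 1000)
qualify exactly. The fraction never applies to B: the convention is fixed
by how known/novel predictions are counted — the numerator of database
recovery counts *predictions*, classified by whether they hit a known CRM.

`shuffle_intervals` places each interval uniformly over every valid start
position on every chromosome, excluding a merged exclusion set (exons).
Intervals may change chromosome (probability proportional to available
space) and outputs may overlap one another; only the exclusion constraint
is enforced. This mirrors the default behaviour of the standard shuffling
tool, and the uniformity is verified by a chi-square test in the suite.

## Evaluation engine

Reference preparation drops database CRMs of length ≥ 2 kb (the curated
database's own inclusion rule is strictly "< 2 kb") and removes any
database CRM sharing ≥ 50% of its own length with a training CRM —
exact-match filtering alone is too brittle against merged or re-curated
records. Survivors are sorted and merged for the recovery/recall track and
kept un-merged, with their expression terms, for the expression measures.

Choices the measure definitions leave open, decided here:

- **Distinct counting.** Training-set sensitivity counts *distinct*
  training CRMs hit (not qualifying predictions), capping the measure at
  100% when several predictions tile one training CRM. Recall measures
  likewise count distinct reference records.
- **Per-prediction classification for precision.** A prediction with
  several annotated hits enters the precision denominator once and is
  correct if *any* of its hits carries the target term — the most
  generous per-prediction reading.
- **Permutation null.** 100 shuffles by default; the z score uses the
  population standard deviation (at 100 replicates the sample/population
  difference is negligible). Replicates whose measure is NA (an empty
  denominator under shuffling, e.g. no annotated hit at all) count as 0 —
  a shuffled draw that hits nothing annotated gives no evidence of
  expression-pattern agreement. z is NA when the null is degenerate
  (sd = 0).
- Expression-pattern recall shares the training-filtered reference with
  the other measures, so training CRMs never inflate recall.

Semi-continuous evaluation computes every measure on the top-n
predictions for n = step, 2·step, … (default step 250 up to 7000), with a
final partial bucket when the list does not divide evenly.

## Window scorer

The scorer is a fixed-order Markov log-likelihood ratio: two
add-pseudocount Markov models (CRM and background) trained on k-mer
counts, a window scored by the mean per-base log ratio. It is a
deliberately simple stand-in carrying the same scanning interface as the
interpolated/partition-based scorers used by production CRM-discovery
tools; the aggregation and evaluation layers are scorer-agnostic.

- **Model order.** `train_markov` accepts any order; the pipeline default
  is 3. A fixed-order model has 4^k·4 free conditionals and no
  interpolation to fall back on, so the order must match training-set
  size: a typical set of ~30 sub-kilobase CRMs (~30 kb of sequence)
  supports 4^3 contexts comfortably, while hexamer-level contexts (order
  5, 16 k parameters) memorize the training sequences — their windows
  then outrank everything else, and since training CRMs are filtered out
  of the reference, database recovery collapses below random. Order 3
  keeps planted-CRM discrimination above 0.9 AUROC on the default fixture
  while letting held-out CRMs rank among the top predictions.
- **Strand symmetry.** The pipeline trains with k-mer counts pooled with
  reverse complements; `train_markov` defaults to forward-only counts so
  its closed-form arithmetic is transparent.
- **N handling.** (k+1)-mers containing N are excluded from counting and
  from scoring; windows with more than 10% N, or with no scoreable
  position, are dropped from scans. k-mer statistics over ambiguous bases
  are undefined, and windows inside assembly gaps should not be ranked.
- **Scanning.** Windows are generated inside maximal non-exonic segments;
  within a segment, starts are `segment_start + offset + i·shift` while
  the window fits. The offset — the number of leading bases ignored — is
  applied per segment, generalizing the original per-scaffold trim to
  exon-masked scanning. Windows never straddle a segment boundary, and a
  window's first `k` bases serve only as context.
- **Ranking.** Descending score, ties broken by (chrom, start) — scores
  are data-derived doubles, but determinism across platforms is worth the
  rule.

### Elbow cutoff

Ranked-curve cutoffs use the knee rule: the point furthest from the chord
joining the first and last points. Both axes are min-max normalized first
— rank and score carry different units, so the geometric rule is only
scale-invariant after normalization. Ties (within float tolerance) break
to the smallest index; a flat curve returns the first point, so the
default-protocol cutoff "score ≥ elbow score" then keeps everything
rather than silently truncating.

## High-density aggregation

25 instances at offsets 0, 10, …, 240 bp jointly place a window start at
every 10-bp position of each segment. Aggregation:

1. pool all instances; keep windows scoring ≥ theta, the score of the
   5000th-ranked *pooled* window (the pooled reading is the only one that
   makes "the 5000th-ranked score" a single number; ties at theta are
   kept). With fewer than 5000 pooled windows theta is the smallest
   score — on small genomes theta can then be negative, since the scores
   are signed log ratios; bin values inherit that sign.
2. split each kept window into 10-bp segments retaining the window score,
   and sum per bin. Window starts must sit on the bin grid — guaranteed
   when offsets are multiples of 10 and segment boundaries are
   grid-aligned; off-grid input is an error, not a silent shift.
3. call peaks on the summed track: maximal runs of bins strictly above
   theta, runs separated by ≤ 30 bp of sub-threshold signal merged,
   merged runs shorter than 200 bp discarded — the peak caller's
   documented defaults. Only present (scored) bins are examined, so peaks
   always lie within kept-window territory.
4. two-stage cutoff: the descending amplitude curve (amplitude = max bin
   value in the peak) and the descending max-window-score curve are each
   cut at their elbow. Both curves are built over *all* called peaks —
   the low-amplitude noise tail is what anchors the elbow — and the two
   cutoffs are applied in sequence to the surviving peaks. A peak's
   max-window score is the best score of any kept window overlapping it
   by ≥ 1 bp. With fewer than 3 peaks an elbow is undefined; all peaks
   are kept, with a warning.

## Fragmentation simulator

A fragment plan tiles each chromosome exactly, cutting from the start:
draw one of the four quartiles of an empirical scaffold-length sample
(uniformly), then a length uniformly from the sample values in that
quartile; the final fragment is truncated at the chromosome end. The
"halves" mode splits each chromosome into two equal parts — the
best-assembled condition. A packaged table of scaffold N50 values for ten
arthropod assemblies, from excellent to poor, parameterizes realistic
length models: sample lengths are drawn from an exponential distribution
whose mean is set so the length-weighted median matches the preset N50
(for an exponential, N50 ≈ 1.678 × mean).

Fragment sequences are copied verbatim; features spanning cuts are split
into per-fragment pieces rather than dropped, preserving exon-masking
mass so that scoring differs only by window-boundary effects. Liftover
back to native coordinates is the exact inverse for unsplit intervals.
Cut positions can be snapped to the 10-bp analysis grid (`align=10`, used
by all high-density experiments) so fragment-local segment boundaries
stay grid-aligned; the shift is ≤ 9 bp against multi-kilobase scaffolds.

Robustness is assessed by treating the native run's top predictions as
true positives and sub-threshold scored territory as true negatives:
TP% is the fraction of lifted simulated predictions hitting a native top
prediction at ≥ 50% of their own length; FP% the fraction hitting only
sub-threshold windows; and Pearson r correlates the scores of windows
present in both runs, matched by exact lifted coordinates. Windows
truncated or lost on short scaffolds simply do not match and are visible
through `n_common_windows`. Because the scorer is a deterministic
function of window sequence, matched windows score identically and r
measures exactly the grid/coverage agreement between runs.

## Synthetic fixture

The generator emulates the inputs of a supervised CRM-discovery study on
a compact insect-like genome (default 2 Mb over 4 chromosomes):

- background from an order-2 Markov chain with mildly non-uniform,
  seeded transition probabilities;
- 3 expression classes × 60 planted CRMs (300–1500 bp, ≥ 200 bp apart),
  each class enriched for its own 8 hexamers: during CRM emission, a
  class hexamer is emitted at each position with probability
  `(strength − 1) × n_kmers/4^k × 4.0`. The mapping is linear in the
  odds multiplier, so `strength = 1` plants nothing — the exact null
  used by the calibration test. The constant 4.0 was frozen once, after
  verifying that the default strength (4.0) gives AUROC > 0.9 for the
  order-3 scorer and a realistic measure regime (sensitivity 60–87%,
  recovery 26–31% against a ~20% random expectation across seeds); it is
  not a tuning knob.
- exons covering 25% of the genome, placed away from planted CRMs; all
  placements (CRMs, exons, decoys, and fragmentation cuts in the
  experiments) sit on the 10-bp analysis grid, mirroring whole-scaffold
  scanning where the grid anchors at position 0;
- a database holding 70% of planted CRMs with coordinates jittered
  ±50 bp (modelling reporter-construct imprecision, and exercising the
  fractional-overlap logic), terms kept at 80%, plus 40 unannotated
  decoys overlapping nothing planted;
- per-class training sets of 30 CRMs, leaving 30 held out so recovery
  and recall are earned, not guaranteed;
- random training sets: GC-matched (±0.02) non-coding intervals with a
  log-normal length profile (median 745 bp, quartiles ≈ 360/1200 bp).

What the fixture does *not* model: repeats, chromatin, conservation,
motif grammar (enrichment is raw k-mer odds, not motif instances),
assembly gaps or sequencing error. Passing tests therefore demonstrate
the pipeline's mechanics and statistical calibration on sequence-level
signal, not performance on real genomes.

## Problem sizes and determinism

The experiments run on the 2-Mb default fixture: a full 25-instance
high-density run takes a few seconds, the six-run fragmentation
experiment a couple of minutes, and the power check (100-permutation
null plus three random-training contrasts) under a minute — sizes chosen
so the whole suite exercises every pipeline end to end at desk scale.
Every random draw flows from an explicit seed through `numpy`
generators; rerunning any command or experiment with the same seed
reproduces its outputs byte-identically.

## Known limitations

- The fixed-order scorer is a stand-in; absolute measure values depend
  on it and should not be compared against tools using interpolated
  models, only relative contrasts (true vs random training, native vs
  fragmented) should.
- The elbow rule is a heuristic; on small peak populations the cutoff
  is sensitive to curve shape even with full-curve anchoring.
- The expression table dialect (5-column TSV with semicolon-separated
  terms) is this package's canonical exchange format; real database
  exports need a one-line conversion.
- High-density binning requires grid-aligned segment boundaries; genomes
  annotated with off-grid exons must be scanned with the default
  protocol or re-gridded.
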