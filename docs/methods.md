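# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and
the known limitations.

## Coordinates, alphabet and formats

All motif positions are transcript-local, 0-based, half-open.  A
transcript is partitioned contiguously into 5'UTR, CDS and 3'UTR spans
(UTRs may be empty); a CDS whose length is not a positive multiple of 3
is loaded but flagged, and frame analysis is unavailable for it.  Only
the sense strand is ever scanned.  T and U are interchangeable on
input; internally sequences are A/C/G/U/N.  Missing ratio-matrix cells
are empty TSV fields and are never imputed.

Tables written by the package carry a `# n_records=N` first line and
must end with a newline.  Together with the FASTA/region-table pairing
(every region row must have a sequence), this lets every reader detect
a file truncated at an arbitrary byte instead of silently loading a
prefix — important because the pipeline's inputs are routinely copied
between systems.

## Two-class SAM

The statistic is the moderated relative difference
`d_i = (x̄_1 − x̄_2)/(s_i + s0)` with `s_i` the pooled two-sample
standard error computed over present values (a feature needs at least
two present values per class; others are excluded with a warning, since
flagged spots are routine on two-color arrays).

* **s0**: candidates are the 0th, 5th, …, 100th percentiles of
  `{s_i}`.  For each candidate, features are split into 100 s-quantile
  windows; the candidate minimizing the coefficient of variation of the
  window-wise median absolute deviations of `d` is chosen.  A fixed-s0
  mode exists for oracle comparisons.
* **Permutations**: all `C(n, n1)` distinct class-label assignments are
  enumerated when their number does not exceed the configured count
  (always the case for the 3-vs-5 design, 56 assignments); otherwise
  assignments are drawn uniformly from a seeded generator.
* **π0** is `min(1, #{d_i in the central 50% range of permuted d} /
  (0.5·m))`; a π0=1 mode exists so tests can compare against a
  brute-force oracle with no estimator in the loop.
* **FDR/q**: thresholds are the observed scores themselves (ties share
  a threshold), processed in decreasing order; at a threshold,
  `FDR = π0 × (mean permuted call count)/(observed call count)` capped
  at 1, and `q_i` is the minimum FDR over the thresholds at which
  feature i is called (its own and all weaker ones).  This makes q
  monotone non-increasing in the score by construction.
* **Side**: affinity-isolation data are called on the positive side by
  default (enriched transcripts only); negative and two-sided modes
  exist.  The choice of side for the original tool run is not
  documented anywhere we could verify, so it is an explicit config
  field rather than a constant.

QC filtering precedes the statistic: RIP mode keeps cells with
signal/background strictly above 1.8 in the total-RNA (input) channel;
expression mode requires signal/background above 1.5 in both channels
and a per-spot regression correlation below 0.5.  The regression
correlation is treated as an opaque per-cell quality number; its
internal computation in array-scanner software is not reproduced.
Median centering subtracts each array's median over present values.

The one-sample expression rule calls a gene up (down) only when both
|mean log2| ≥ log2(1.5) ≈ 0.585 and the two-sided one-sample t-test
gives p < 0.05.  Zero-variance replicate sets have no defined p; such
genes are flagged degenerate and never called, avoiding p = 0 artifacts
on constant replicates.

## Repeat scanning

A pattern is a 3-letter IUPAC consensus (e.g. GWW, GAN, GSS).  Pattern
N matches any base; sequence N matches nothing.  A *run* is a set of
consecutive matching triplets in one phase; runs are maximal within
their phase, and overlapping runs in different phases are reported
separately (phase-agnostic matching without double counting within a
phase).  Regions are scanned independently, so a repeat spanning a
region junction is split and each side assigned to its own region —
every occurrence belongs to exactly one region in the count tables.
CDS hits carry frame = start mod 3, with 0 meaning the run starts at
the first codon position.

In the count table, one maximal run of L triplets counts once in every
row k ≤ L, for both the occurrence count and the transcript count.
This reconciles the two counting units seen in region tallies
(occurrences ≥ transcripts, both monotone non-increasing in k).

Motif discovery scores every triplet over a candidate IUPAC alphabet
(default {A,C,G,U,W,S,R,Y,N}³ minus NNN, 728 candidates) by the
hypergeometric enrichment of motif-bearing transcripts among targets
versus the full transcript background, ranking by p with ties broken
toward more specific patterns (fewer concrete triplets matched), then
lexicographically.  It is a deliberately transparent stand-in for
EM-style motif discovery: adequate for tandem-repeat consensi, not for
position-weight-matrix motifs.

## Set statistics

Hypergeometric tails are computed in log space via log-gamma and
reported without flooring, so overlaps with p ~ 1e-150 remain exact and
comparable.  The enrichment universe is always an explicit argument —
annotation-version-dependent backgrounds make an inferred universe a
silent source of irreproducibility.  The overlap matrix uses Bonferroni
across retained queries (queries below 8 members are dropped with a log
line), matching the multiple-RBP comparison convention; BH is available
but off by default.

The ranked-list statistic is the minimum hypergeometric (mHG) tail over
all proper prefixes.  Its exact p-value is computed by the standard
path-counting dynamic program on the B×(N−B) grid: walk the ranked list
with hypergeometric step probabilities, removing mass that enters any
cell whose tail is at most the observed statistic; the removed mass is
the p-value.  The DP is O(N·B) and is used for N ≤ 2,000; beyond that a
seeded permutation estimate (≥ 10,000 shuffles) takes over.  The
analytic sandwich `mHG ≤ p ≤ min(1, N·mHG)` is asserted on every exact
evaluation.

## Regulon expression analysis

The subset test compares targets-in-term against (a) all measured
features and (b) non-targets in the same term, with a two-sided
Mann-Whitney U — exact enumeration when both groups have ≤ 8 values and
no ties (essential: biologically interesting subsets can have 3
members), otherwise the tie-corrected normal approximation with 0.5
continuity correction — plus Welch's t as a companion.  The "vs all"
background includes the subset's own members by default, mirroring the
convention of plotting a subset against the global distribution; an
exclusive mode exists because the inclusive choice is a convention, not
a law.  Summary statistics use linear interpolation between order
statistics (10th/90th percentile whiskers are convention-sensitive on
small n, so the convention is fixed and tested).  Significance stars
map p < 0.001/0.01/0.05 to ***/**/*, with boundary values assigned to
the weaker category.

Percentages round half-away-from-zero; this convention reproduces every
printed summary ratio the package reports (13.6, 93, 21, 26, 38, 17.8,
65, 98, 27).

## Synthetic data: what it emulates, and what it does not

* `simulate_transcriptome`: i.i.d. uniform background over A,C,G,U with
  Poisson-distributed region lengths (defaults 60/1200/120 nt,
  CDS forced to a multiple of 3).  Planted runs get run-breaking
  flanking bases so their maximal length is exact, and a cleanup pass
  mutates any chance background run reaching the plant's minimum length
  (touching only bases outside planted runs), so a scan at that minimum
  recovers exactly the planted hits — sharp ground truth for scanner
  tests.  Defaults plant GWW runs of 4–8 triplets in 25% of
  transcripts, 85% in CDS, first-codon-position probability 0.93,
  mirroring the CDS dominance and frame bias of the studied RBP's
  element.  The model deliberately omits codon-usage and GC-content
  structure; chance-run rates are therefore analytically checkable but
  real transcriptomes will show different background run statistics.
* `simulate_ripchip`: 3 IP vs 5 mock arrays by default; non-targets
  draw i.i.d. Normal(0, noise_sd = 0.5) log2 ratios, targets add a
  +2.0 log2 shift on IP arrays, target fraction 0.136.  Signal/
  background values come from a lognormal so the >1.8 filter removes a
  controllable minority of cells.  The noise law of real two-color
  ratios is not documented; Normal is an assumption of the generator,
  not a claim about the arrays.  Dye bias and spatial artifacts are out
  of scope.
* `simulate_expression`: baseline Normal(0, 0.3) for both columns;
  shifts apply to genes carrying a GO term intersected with the target
  set (target-specific regulation), with a whole-term mode for
  contrast; protein values observed for a Bernoulli 0.27 fraction of
  genes, except that genes given a nonzero protein shift are always
  observed (the planted signal must be measurable to be testable).
* `simulate_geneset_overlap` realizes requested overlap counts exactly.

All generators draw from one seeded `numpy` Generator per call; equal
seeds give byte-identical output files.  Passing tests on these data
shows the *machinery* is correct and calibrated under the stated noise
conditions; it does not certify behaviour under correlated array noise,
composition-biased sequence, or annotation errors in real data.

## Pipeline and problem sizes

Per-stage seeds derive from the global seed by CRC hashing of the stage
name, so adding a stage never perturbs earlier stages' streams.  All
outputs are plain text; a manifest records the package version, stage
seeds and a config hash (paths by basename), and reruns are
byte-identical.

Problem sizes were chosen as desk-scale study conditions: the demo uses
1,000 transcripts and the 3-vs-5 design (56 permutations enumerated
exactly); FDR calibration uses 200 null datasets of 300 features;
subset-shift calibration uses 500 simulated tables; the mHG exact/
permutation cross-check uses N = 30 with 100,000 shuffles.

## Known limitations

* The SAM s0 percentile search and π0 estimator follow the standard
  published procedure but micro-choices (window count, percentile grid)
  are conventions; the oracle tests therefore pin the *implemented*
  definitions, and the fixed-s0/π0=1 modes expose the core statistic.
* The mHG exact DP accumulates float probabilities; beyond N ~ 2,000
  the permutation path is used rather than extending the DP.
* GO annotation sets are taken as given (no true-path propagation).
* The discovery stand-in ranks triplet consensi only; it cannot find
  motifs that are not tandem triplet repeats.
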