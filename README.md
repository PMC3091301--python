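# regulonscan

Tools for dissecting the RNA regulon of a zinc-finger RNA-binding
protein from two-color RIP-chip arrays, sequence, and matched
transcriptome/proteome profiling — exercisable end to end on synthetic
data with exact ground truth.

## The scientific problem

An RNA-binding protein (RBP) built from tandem CCHC zinc knuckles, such
as yeast Gis2p or its human homolog ZNF9/CNBP, binds functionally
related mRNAs through short degenerate trinucleotide repeats — runs of
GWW (W = A/U) or GAN triplets — located mainly in coding sequence and
preferentially aligned with the reading frame.  Linking such a protein
to its regulon takes four computational steps, each of which this
package implements as a tested, seedable library module:

1. **Target calling** (`regulonscan.sam`).  Transcripts enriched in
   affinity isolations versus mock controls are called from log2 ratio
   matrices by two-class SAM: the moderated relative difference
   `d_i = (x̄_IP − x̄_mock) / (s_i + s0)` with `s_i` the pooled
   two-sample standard error and `s0` a variance-stabilizing fudge
   factor chosen by percentile search; per-feature q-values (FDR) come
   from enumerating or sampling class-label permutations, scaled by a
   π0 estimate.  A companion one-sample t-test implements the
   "≥1.5-fold (|mean log2| ≥ 0.585) and p < 0.05" rule for expression
   profiling, and QC filters (signal/background, regression
   correlation) plus per-array median centering run upstream.
2. **Repeat scanning** (`regulonscan.motifs`).  Maximal runs of
   consecutive IUPAC-triplet matches are found at every phase offset,
   split at 5'UTR/CDS/3'UTR boundaries, frame-annotated within the CDS
   (frame 0 = first codon position), tallied into region-by-run-length
   count tables with hypergeometric target enrichment, and a discovery
   mode ranks all candidate triplet consensi by target enrichment.
3. **Set statistics** (`regulonscan.enrichment`).  Log-space
   hypergeometric tails, 2×2 chi-square with Fisher companion,
   Bonferroni correction, GO-term enrichment over an explicit universe,
   the exact minimum-hypergeometric (mHG) statistic for ranked lists
   with `enrichment = (b/n)/(B/N)`, and the multi-RBP overlap matrix.
4. **Regulon expression analysis** (`regulonscan.regulon`).  For a GO
   term, the target subset's mRNA or protein log2 changes are compared
   with all measured features and with non-targets in the same term
   (Mann-Whitney U, exact for small groups, plus Welch t), with
   10–90% whisker summaries, mRNA–protein Pearson correlation, and
   chi-square overrepresentation of targets among changed genes.

`regulonscan.synthetic_data` generates every input with planted ground
truth (enrichment effects, repeat runs with known region/length/frame,
GO-linked expression shifts, exact set overlaps), and
`regulonscan.pipeline` orchestrates a deterministic end-to-end run.

## Worked example

`analysis/` contains the study as numbered scripts.  With the default
seed 42:

```sh
python analysis/01_simulate_study.py     # writes results/study/data
python analysis/02_call_rip_targets.py
python analysis/03_scan_repeats.py
python analysis/04_enrichment_overlap.py
python analysis/05_expression_shifts.py
```

Script 02 prints

```
SAM called 243 of 988 analyzed features (24.6%) at FDR<0.05 with 56 permutations
against planted truth: recall 0.968, precision 0.996
```

meaning that of the 250 transcripts simulated with a +2.0 log2 IP
enrichment, 242 are recovered at FDR < 5% with a single false call.
Script 03 then finds the planted repeat from sequence alone:

```
(GWW)4 in CDS: 212 transcripts, 206 targets, enrichment p=2.75e-165
frame distribution of 206 target CDS runs: frame 0: 187 (91%), ...
top discovered consensi: GWW (p=1.3e-222), WWG (p=6.66e-151), ...
```

and script 05 reproduces the signature regulon behaviour — a GO subset
whose *protein* levels shift while mRNA does not, against a background
with essentially no mRNA–protein correlation:

```
mRNA vs protein changes: Pearson r=0.081 over 324 complete pairs
GO:7000000 [mrna]:    n=29, mean log2=-0.09, MW p vs all=0.25 ns
GO:7000000 [protein]: n=29, mean log2=+0.75, MW p vs all=5.2e-14 ***
```

The same flow is available as a single command:
`regulonscan demo --config-out demo.yaml && regulonscan run --config demo.yaml`.

## Layout

```
src/regulonscan/    io_formats, synthetic_data, sam, motifs,
                    enrichment, regulon, pipeline, cli
analysis/           numbered study drivers (write results/study)
scripts/            acceptance.py
tests/              pytest suite with independent brute-force oracles
docs/methods.md     models, conventions, parameter choices, limitations
```
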