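# Methods

## The analysis

`tzsig` identifies mRNAs and lincRNAs associated with acquired resistance
to trastuzumab (Tz) by integrating three expression contrasts and an
enhancer-level chromatin readout:

1. **Tumor (in vivo) differential expression.** FPKM values from a cohort
   of HER2+ tumors, 11 responders (TzS) vs 2 non-responders (TzR). After
   the expression gate (below), the fold change of condition means,
   TzR/TzS, is computed per gene; a gene is differential when
   FC ≥ 2.0 or FC ≤ 0.5. With only two non-responders no per-gene test is
   meaningful, so tumor mode is fold-change-only by design.
2. **Cell-line (in vitro) differential expression.** Paired TzS/TzR
   isogenic replicates. Same gate and fold-change rule, plus a two-sided
   paired t-test on log2(FPKM + pseudocount) with p < 0.05. The test is
   paired because replicates share culture batches; pairing is declared in
   the sample sheet and must match 1:1 across conditions.
3. **Short-term subtraction.** Genes responding to a 48-h Tz exposure of
   sensitive cells (mock vs treated, same cell-line rule) are removed from
   the in-vitro list *by gene id regardless of direction*, so the
   signature reflects stable resistance rather than acute drug response.
   Subtraction precedes intersection.
4. **Concordant intersection + Fisher.** The in-vivo list is intersected
   with the post-subtraction in-vitro list requiring the same direction of
   change (sign of log2 FC; magnitudes are not compared). Overlap
   enrichment is tested with a two-tailed Fisher's exact test.
5. **Enhancer signal ratios.** High-confidence H3K4me1/H3K27ac peaks
   (−log10 p strictly greater than 9, i.e. p < 1e-9) within 150 kb of a
   signature gene's TSS are scored as log2 of the ratio of mean normalized
   ChIP signal, resistant over sensitive; the per-gene median summarizes
   the local chromatin shift.

## Rules and their boundaries

* **Expression gate.** A gene is "expressed" iff EVERY sample of at least
  one condition is at or above its biotype threshold: 1.0 FPKM for mRNA,
  0.25 FPKM for lincRNA. All threshold comparisons are inclusive (≥).
  The lower lincRNA threshold reflects the genuinely lower abundance of
  that biotype. Unknown biotypes are rejected outright so a threshold is
  never mis-applied.
* **Fold change.** FC = (mean_num + c)/(mean_den + c) with pseudocount
  c = 0.01 by default. The gate makes both-zero means impossible, but
  one-sided zeros occur; the pseudocount keeps the ratio finite and is
  also used inside every log2 transform. FC boundaries are inclusive
  (≥ 2.0, ≤ 0.5); the p criterion is strict (p < 0.05).
* **Paired t-test.** Computed explicitly from per-pair log2 differences:
  t = mean(d) / (sd(d)/√n), two-sided p from the t distribution with
  n − 1 df. Degenerate genes are resolved deterministically: all-zero
  differences → t = 0, p = 1; zero variance with nonzero mean → p = 0.
  No multiple-testing correction is applied by default (the per-gene
  p < 0.05 rule); a Benjamini–Hochberg option exists (`fdr_bh`) but is
  off by default.
* **Fisher's exact test.** `fisher_overlap` builds the 2×2 table
  (in-both / A-only / B-only / neither) and computes the exact two-tailed
  p in integer/`Fraction` arithmetic: the sum of hypergeometric point
  probabilities not exceeding the observed one, with 1e-7 relative slack
  for ties — the convention of standard exact-test implementations. No
  normal approximation is involved at any universe size. The universe is
  the analysis' one genuinely open parameter; the default policy
  (`gated_both`) uses the genes passing the expression gate in both the
  tumor and cell-line datasets, reported pooled and per biotype.
* **Heatmap matrix.** Differential genes only; each row is
  log2(FPKM + c) z-scored across samples with the sample (n−1) standard
  deviation; constant rows map to zeros, never NaN.
* **ΔΔCt.** Relative qPCR expression is 2^−ΔΔCt with
  ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control.
* **Coordinates.** Everything genomic is 0-based half-open (BED). A TSS
  is a single base: gene start on +, gene end − 1 on −. Peak-to-gene
  distance is TSS to peak midpoint (floor of (start+end)/2), inclusive at
  exactly 150 kb; midpoint was chosen over any-overlap for symmetry with
  the per-peak dot plots.
* **Track normalization.** Each bedGraph is divided by its
  length-weighted mean over all covered bases, so a common scaling of
  both conditions cancels exactly. Per-peak signal is the length-weighted
  mean of the normalized track over the peak interval (uncovered bases
  count as zero signal with full weight); a pseudocount of 0.5 guards
  log ratios against zero-coverage peaks. Peaks present in only one
  condition's peak file are handled by taking the union of both files'
  intervals before filtering.

## The synthetic study

`tzsig.synth` generates the complete input bundle with planted truth so
every stage is testable without external data. Defaults define the study
conditions:

* 2,000 genes (15% lincRNA) on one synthetic chromosome, TSSs evenly
  spaced 400 kb apart so neighbouring 150-kb windows never overlap.
* log2 FPKM = baseline + planted effect · condition + N(0, σ) with
  σ = 0.2 — i.e. lognormal FPKM noise, the standard approximation.
  Baselines are N(5, 2) for mRNA and shifted −2 for lincRNA, so ≥ 95% of
  genes pass the gate (the gate, not the simulator, is what the gate
  tests exercise) while the 0.25 lincRNA threshold still sees traffic.
* Planted, mutually disjoint sets: 30 concordant, 20 in-vivo-only,
  20 in-vitro-only, 15 short-term genes, each with |log2FC| = 2 and a
  random sign; concordant genes share their sign between tumor and
  cell-line datasets; short-term genes are perturbed only in the
  48-h-treated samples.
* Cohorts: 11 TzS vs 2 TzR tumors; 3 cell-line pairs and 3 short-term
  pairs, each pair carrying a shared N(0, 0.3) batch offset so pairing
  genuinely helps the paired test.
* Chromatin: for each planted concordant gene and for 30 unplanted
  background genes, 8 high-confidence peaks (−log10 p ~ U(10, 50), width
  1 kb) are placed in non-overlapping slots within ±120 kb of the TSS,
  plus one sub-threshold peak per gene and 40 background peaks in
  intergenic gaps. Peak heights are lognormal around 2^6 ≈ 64× the track
  baseline; the resistant condition multiplies planted-gene peaks by 2.0,
  and both conditions carry independent multiplicative noise with
  σ = 0.1 on the log2 scale. With 8 peaks per gene the sampling noise of
  a per-gene median is ≈ 0.06 sd, so the planted 2× shift (log2 ≈ 1) and
  background (≈ 0) separate cleanly; the 0.5 signal pseudocount and track
  normalization together bias the planted medians down by only ~0.04.
* All randomness flows from one `numpy` Generator seeded by `seed`;
  the same seed reproduces the bundle byte-for-byte on disk.

What the simulator does **not** emulate: fragment-level FPKM estimation
noise, gene-length and GC effects, correlated gene modules, copy-number
structure around the HER2 amplicon, read-level ChIP background, or peaks
with condition-specific presence. Passing the planted-truth tests
therefore shows the pipeline's rules and plumbing are correct under a
clean lognormal model — not that the thresholds are optimal for any real
cohort.

## Problem sizes and reproducibility

The test suite and the acceptance script run the full default study
(2,000 genes, 13 + 6 + 6 samples, ~540 peaks per mark); a reduced design
(300 genes) backs the I/O and CLI round trips. These sizes were chosen so
the whole suite runs in seconds while keeping every statistical check
well-powered. Pipeline output is a pure function of (inputs, config,
seed); the run manifest records a hash of the analytic config and of
every output file, so bit-identical re-runs are checkable.

## Known limitations

* FPKM is assumed pre-normalized; no library-size or batch correction is
  applied (count-based DE models are out of scope by design).
* The tumor mode's fold-change-only rule has no error control; it is the
  stated procedure for a 2-sample non-responder arm, not a recommendation.
* The Fisher universe is a modelling choice; results should be reported
  together with the chosen policy.
* Annotation is opaque user input; no gene catalog is bundled.
* The enhancer analysis is descriptive (no per-peak differential-binding
  statistics), matching its role as a qualitative chromatin readout.
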