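# Methods notes

This note records the models, conventions and numerical choices behind
cascade-pbm, in the order the pipeline runs.

## Probe design

A design is a manifest: one row per spotted probe, carrying the target
sequence, probe class (seed / sv / ref / nonref / background /
tfbs_consensus), orientation and replicate index. Conventions:

* **Tiling.** Tiles of 26 bases at a 5-base step, offsets 0, 5, 10, …
  When `(L − 26) mod 5 ≠ 0` a terminal tile anchored at `L − 26` is
  appended so the union of tiles covers every base. Overlapping tiles
  produce duplicate SV sequences; these are kept as distinct records (a
  166-bp region therefore counts 29·79 = 2,291 targets).
* **Probe layout.** `GCCTAG` + 26-base target (or its reverse complement
  for the − orientation) + `CTAG` + the 24-base primer-binding site
  `GTCTTGATTCGCTTGACGCTGCTG` (the reverse complement of the
  double-stranding primer), 60 bases total. TF-consensus probes instead use
  a `GC` cap + 34-base target + primer, the target being a 2-base pad +
  consensus + 2-base pad written over the 5′ end of a random backbone in
  which no two adjacent bases repeat; pads are drawn with the same
  no-adjacent-repeat constraint against their neighbours.
* **SNPs.** Targets are built on the + strand as 13 bases + allele + 12
  bases; the strand of the source annotation is ignored since both probe
  orientations are spotted anyway. SNP positions are accepted 1-based in
  TSV input and converted on ingest; BED input is standard 0-based
  half-open.
* **Background probes** are sampled uniformly from a genome FASTA when one
  is supplied, else i.i.d. uniform ACGT — the package never requires a
  genome download. Windows containing non-ACGT characters are resampled.
* **Capacities** (how many tiles or pairs fit on a slide) are treated as
  user-supplied budgets, not constants derived by the package; the helper
  `tiled_span(n)` = `26 + 5(n − 1)` reports the bases covered by `n`
  contiguous tiles.
* The manifest TSV carries two columns beyond the core set — `target_id`
  (groups the 10 spots of one target) and `tile_offset` (the tile's anchor,
  which the terminal-tile rule makes non-derivable from `tile_index`).

## Fluorescence simulator

The simulator exists so that every downstream stage can be tested without
array data. One planted TF–COF complex is parameterized by an `m × 4` score
matrix `w`, amplitude `A`, baseline `B`, occupancy scale `K`, log-normal
noise σ and an orientation bias. A probe's best window score on either
strand, `s`, sets its expected fluorescence

    mu = B + A · exp(s) / (K + exp(s)),

and each spot draws `mu · exp(N(0, σ²))`, times the bias for − orientation
spots. The logistic-occupancy × multiplicative-noise form was chosen because
PBM intensities are non-negative, saturating and dominated by multiplicative
noise; it is a simulator convention, not a claim about any particular
experiment.

Defaults (chosen once as a realistic operating point and used everywhere):
`A = 500`, `B = 100`, `σ = 0.2`, bias 1.0; the stock ETS-like complex
scores its 8-base consensus at 3 per matching base with
`ln K = 22.5` (1.5 score units — half a mismatch — below the consensus
score). At these settings a perfect site sits ≈ 20 background standard
deviations above background, matching the z-score range the screen is meant
to operate in, and a single-base mismatch traverses most of the occupancy
range, which is what makes single-variant motifs readable.

What the simulator does **not** model: spatial artifacts, scanner
saturation, inter-array normalization, probe-position effects along the
slide, or sequence-composition biases of real genomic background. Passing
tests therefore demonstrate the correctness and calibration of the
analysis under the stated generative model, not performance on any real
array.

Null screens use a motif-free (zero-matrix) complex so REF and non-REF
alleles share their expected signal exactly. Planted screens embed the
consensus with one mismatch at the SNP position in the REF allele; the
non-REF allele restores the consensus base. Because non-gain pairs carry
uniform-random flanks, a small number of them can contain fortuitous sites
overlapping the SNP and show *genuine* differential recruitment; they are
not false positives of the statistics.

## Z-scoring

Probe means (arithmetic mean of the ≥ 2 surviving replicate spots; median
available) are standardized against the background-probe distribution with
the sample (n−1) standard deviation. The background is summarized per
orientation by default — orientation-specific scanner/strand effects exist
and the screen tests orientations separately — with a pooled option.
Z-scores are computed on the natural (already-normalized) intensity scale so
that Δz values remain interpretable; a log-scale switch exists. Spot-level
vectors are retained because the screen's t-tests operate on fluorescence,
not on z-scores. Rows with missing or negative fluorescence are dropped with
a logged count; no other outlier handling is applied (inter-array
normalization is upstream of this package).

## Differential screen

Per pair and orientation, a two-sided Welch t-test on the replicate
fluorescences (Student's pooled test behind a flag; zero-variance inputs
fall back to p = 1 for equal means, p = 0 with a warning otherwise).
Orientation p-values are combined by Fisher's method against χ² with 4 df;
p = 0 inputs are clamped at 1e-300 with a warning. BH adjustment runs over
all testable pairs of one experiment (factor × condition × replicate) — the
only family definition that makes q-values comparable across loci. Δz is
the plain mean over the two orientation z-scores, non-REF minus REF.
Reproducible calls require q < 0.05 in both technical replicates and
concordant Δz signs; a locus with both gain and loss calls (across factors)
is tallied as "both", so gains + losses + both = total called loci.

## Motif construction

* **Reset rule:** variant z > 1.645 with seed z ≤ 1.645 → variant reset to
  the seed value. 1.645 is the one-sided standard-normal 0.95 quantile,
  i.e. the point above ~95% of background probes under normality.
* **Seed threshold:** stand-alone locus motifs are reported only when the
  seed z reaches 1.5. Region-wide integration does **not** gate tiles on
  this threshold — all tiles contribute — because weakly bound tiles are
  informative in the weighted average and the threshold's role is to keep
  unreliable stand-alone motifs out of reports.
* **Integration:** at each position/base, the mean over covering tiles
  weighted by each tile's seed z. Weights are floored at 0.01 so a
  non-positive seed cannot flip the sign of the average; a single strongly
  bound tile then dominates, which is the intended behaviour.
* **Δz logos:** rows centred on their median across the four bases (for 4
  values, the mean of the two middle order statistics), computed after
  integration. Axis limits for display are the global min/max Δz across
  experiments of one factor. Replicate experiments are kept separate
  rather than averaged.
* Orientation handling: z-scores are averaged across the two orientations
  per target before matrix assembly; per-orientation matrices remain
  available through the z-score table for QC.

## PWM conversion and matching

`β = 30 / max(z)` with the maximum taken over **all probes of the
experiment** (the most literal reading of an experiment-wide scale), so
factors probed with weaker antibodies get proportionally sharper
transforms. Negative z values enter the exponential unchanged. The softmax
is computed with per-row max subtraction, so arbitrarily large βz cannot
overflow.

Matching slides the query over each library motif on both strands (minus
strand = reverse-complemented library matrix), requires ≥ 4 overlapping
columns, and scores the **mean** per-column Euclidean distance — mean, not
sum, so scores are comparable across overlap lengths. No match
significance is computed; q-value-based reporting belongs to external
motif-comparison tools operating on the exported MEME files.

## Degenerate inputs and tie-breaks

Zero background standard deviation raises "degenerate background"; fewer
than 30 background probes is an error (configurable for testing); probes
with < 2 surviving spots are excluded from t-tests and reported NA; matches
at equal distance are ordered + strand first, then by motif id; screen
output is ordered by rsid and is invariant to input row order.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
null and planted screens use 1,000 SNP pairs × 2 replicates with 500
background probes, motif recovery uses one 166-bp region (2,291 targets,
200 background probes), and the background-calibration check uses 10,000
background probes. These sizes were chosen so the binomial/KS tolerances
asserted in the tests are meaningful while the whole suite stays fast.

## Known limitations

* The simulator's single-complex signal model cannot produce condition- or
  factor-correlated structure; multi-complex mixtures must be composed by
  summing expected signals across runs.
* GPR ingestion reads a minimal GenePix column subset (Block/Column/Row/
  Name/ID/F635 Median); full GenePix headers with per-channel statistics
  are not parsed.
* Motif-library matching reports distances only; use the MEME export with
  external tools when calibrated significance is needed.
* Array feature-count packing (slide formats, physical layout) is out of
  scope; capacity figures are user-supplied budgets.
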