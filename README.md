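# cascade-pbm

Design and analysis of **cofactor-recruitment protein-binding microarrays**
(PBMs): customizable double-stranded DNA probe arrays incubated with nuclear
extract and read out by fluorescent antibody against a cofactor (COF) or
transcription factor (TF) of interest. The readout at each probe measures
recruitment of a TF–COF complex to that DNA sequence, which makes it possible
to (i) map, base by base, how every possible single-nucleotide variant of a
regulatory element changes cofactor recruitment, and (ii) screen large panels
of non-coding SNPs for alleles that gain or lose TF–COF binding.

The package is aimed at regulatory-genomics groups who design such arrays and
analyze the scanned, normalized fluorescence — and at anyone who wants to
study the statistical behaviour of this screen, since it ships a full
fluorescence simulator with a planted recruitment complex.

## What it computes

**Probe design.** A regulatory region is tiled with 26-base targets at a
5-base step (a terminal tile anchored at the 3′ end covers any remainder).
Every tile is accompanied by all `3 × 26` single-variant (SV) probes, so a
*T*-tile design has `T·(1 + 78)` targets (a 166-bp region needs 29 tiles =
2,291 targets). SNP screens use one 26-mer pair per variant (13 bases + SNP
+ 12 bases), one probe per allele. Each target is embedded in a 60-base
probe — `GCCTAG` + target + `CTAG` + 24-base primer site — and spotted in
both orientations with 5 replicate spots, alongside ~500 random background
probes.

**Z-scores.** Probe means are standardized against the background-probe
distribution, per orientation:
`z = (x − mean(bg)) / sd(bg)`.

**Differential screen.** Per SNP pair, REF vs non-REF replicate
fluorescences are compared with a two-sided Welch *t*-test per orientation;
the two p-values are combined with Fisher's method
(`X = −2(ln p₊ + ln p₋) ~ χ²₄`), BH-adjusted across all pairs, and the
effect size is `Δz = z̄_nonREF − z̄_REF` (positive = gain of recruitment).
A hit must reach `q < 0.05` in both technical replicates with concordant
direction.

**Recruitment motifs.** Per locus, an `L × 4` matrix holds the seed z at the
reference base and SV z elsewhere, with a reset rule: an SV z above 1.645
(the ~95% normal point of the background) whose seed z is ≤ 1.645 is reset
to the seed value, suppressing sites created de novo by a variant. Tiled
regions are integrated by a seed-z-weighted mean over overlapping tiles.
Logos display `Δz_ik = z_ik − median_k z_ik`.

**PWM conversion and matching.** A z-matrix becomes a probability matrix via
the Boltzmann transform `P_ik = exp(β z_ik) / Σ_k exp(β z_ik)` with
`β = 30 / max(z)` over the experiment; PWMs are exported in MEME minimal
format and ranked against motif libraries by mean per-column Euclidean
distance over the best overlap on either strand.

## Worked example

The `demo` subcommand runs the whole pipeline on a synthetic 166-bp
promoter-like region with an ETS-like site planted at offset 40 and an
ISRE-like site at offset 110, simulated with the default planted complex
(amplitude 500, baseline 100, log-normal noise σ = 0.2):

```sh
$ cascade demo --seed 7 -o demo/
demo complete: 2791 targets, max z = 22.51, beta = 1.3327, delta-z range [-2.78, 13.69] -> demo/
```

Reading the numbers: the design holds 2,291 non-background targets (29 tiles
× 79) plus 500 background probes; the strongest probe sits 22.5 background
standard deviations above the background mean; the Boltzmann β for this
experiment is 30/22.51 = 1.33; and the region-wide Δz matrix spans −2.8 to
+13.7 — the large positive values are confined to the planted site, where
mutating a consensus base wipes out recruitment. `demo/` contains the
manifest, intensity table, z-scores (`zscores.tsv`), the long-form motif
matrix (`motif.tsv`) and the planted site's PWM in MEME format
(`motif.meme`).

The same stages are available separately as
`cascade design cre|snp|tfbs`, `cascade simulate`, `cascade zscore`,
`cascade screen`, `cascade motif`, `cascade pwm` and `cascade match`, and as
library functions (see module docstrings).

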