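# Methods

This note documents the statistical models implemented in screenkit, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices
that matter when reproducing results.

## Binding-screen statistic

**Model.**  One two-channel array per replicate measures, per protein spot,
fluorescence of a query RNA and of a total-mRNA reference.  The quantity of
interest is the centered log ratio `R_p = log2(query_p / reference_p) − c`,
where `c` is the median (default) or mean over proteins passing the
background filter.  Under the null of no specific binding, `R_p` is modeled
as Gaussian; each replicate's values are standardized to z-scores and
mapped to upper-tail p-values `p = P(Z ≥ z)` — upper-tail because the
screen seeks proteins with *elevated* query affinity.

**Background filter.**  A protein is detectable on an array when its
foreground exceeds `k` times its background (default `k = 1.5`) in **both**
channels; undetectable proteins are excluded from that array's statistics.
A protein must be detectable in all three replicates of a dye set to be
scored for that set, and scorable in both sets to be classifiable.

**Dye-swap combination.**  Half the replicates swap which dye labels the
query.  Orientation is role-based (query over reference regardless of dye),
so a dye-swapped array yields identically signed ratios; any residual
intensity-independent dye bias appears as a per-array constant and is
removed by centering.  Per dye set, the three replicate p-values are
combined by their product.  The product is a score, not a calibrated
p-value: for three independent uniforms its CDF is
`F(x) = x·(1 + (−ln x) + (−ln x)²/2)`, so the per-set pass probability at
`x = 10⁻⁴` is `F(10⁻⁴) ≈ 5.26×10⁻³` and the dual-set null call rate is
`F(α)² ≈ 2.77×10⁻⁵` — about 0.055 expected false calls among 2,000
proteins.  A Fisher χ²₆ calibration of the same product is reported for
reference but plays no role in classification.

**Numerical conventions.**  z-scores use the population SD (divide by n);
over thousands of spots the difference from the sample SD is far below any
threshold of interest.  Median and mean centering differ by a constant that
z-scoring absorbs, so the choice does not affect classification; both are
exposed.  Ranking is by the worse (larger) of the two combined products,
ascending, with lexicographic protein-id tie-breaks for determinism.
Whether ratios should be formed from background-subtracted foregrounds is
genuinely open; the default uses raw foregrounds (background enters only
the detectability filter), with subtraction available as an option, since
subtraction destabilizes log-ratios for dim spots.

## RIP-ChIP enrichment

Each array hybridizes an IP (or mock-IP) against its depleted supernatant.
Per array, log2(IP/reference) ratios are median-centered; mock correction
subtracts, gene-wise, the **mean** over mock replicates (no IP↔mock pairing
is assumed; the mean is the stable default and batch pairing can be imposed
upstream by subsetting).  Genes must be detectable — foreground > 1.5×
background in **either** channel here, since a transcript absent from the
IP can still be present in the reference — in at least 9 of 12 arrays for
the full design, or a strict majority otherwise.  Genes are ranked by mean
corrected enrichment; per-gene significance uses a one-tailed one-sample t
against zero (n ≥ 3 replicates required; Welch for two-sample variants).

**Simplified SAM.**  Cross-condition comparisons use a moderated statistic
`d_g = (x̄_A − x̄_B)/(s_g + s₀)` with `s_g` the pooled standard error and
the fudge factor `s₀` fixed at the median of the `s_g` — deliberately not
the original percentile-search calibration, which adds complexity without
changing the toy-scale behaviour this package targets.  The null comes from
group-label permutations: all distinct assignments when there are at most
`n_perm`, otherwise a seeded sample.  The q-value at a gene's |d| cutoff is
the median permuted exceedance count over the observed count, clipped to
[0, 1] and made monotone (a larger |d| never carries a larger q, enforced
by a cumulative minimum from the least significant gene upward).  Under a
global null the estimated FDR in the extreme tail sits near 1 by
construction; this is verified, not assumed, in the test suite.

Enrichment matrices are keyed by probe (feature id) with the gene as
annotation: *HAC1* is tiled by five probes — two unspliced exon–intron
junctions, the intron, the ORF, and the spliced exon–exon junction — and
the unspliced-isoform summary averages the unspliced-junction and intron
probes while the spliced summary is the spliced-junction probe alone.

## Knockdown expression profiling

Per replicate, median-centered log2(knockdown/WT) ratios; the reported
profile is the replicate average.  The target-set shift test is an unpaired
(Welch) t-test of set members against **non-members** — disjoint groups
keep the test well-defined; an inclusive "set vs all genes" variant is
available since either reading of "relative to all genes" is defensible and
the two differ negligibly when the set is small.  The shift estimate
(difference of group means) is invariant to adding a constant to all genes.
Per-gene changes report the mean log2 ratio, its fold-change `2^mean`, and
a t-test across replicates; *HAC1* probe classes can be pooled.  A small
illustrative UPR target set (KAR2, ERO1, PDI1, HAC1) ships as a constant;
real analyses should pass the full annotated list as a `GeneSet`.

## Decay estimation

Abundances are qPCR values normalized to a reference gene measured in the
same reaction (GAPDH for decay assays; ACT1 for UPR induction/attenuation
time courses — the reference is configurable).  Assuming first-order decay
`X(t) = X(0)·2^(−t/T)`, the two-point estimator is
`T = (t₁ − t₀)/log2(X(t₀)/X(t₁))`.  Written with the remaining fraction in
the denominator the same expression is negative for decaying RNA; it is
read as a magnitude so decaying series yield positive half-lives.  A
remaining fraction at or above 1 means induction, an expected regime since
transcription inhibitors themselves stress the ER; such series return a
flagged non-decaying estimate (infinite half-life), never a negative one.
Series with three or more timepoints are fitted by least squares of
`log2 X(t)` on `t` with `T = −1/slope` and a delta-method standard error
`se(T) = se(slope)/slope²`.  Replicate fractions are averaged **before**
applying the formula (the estimator is applied to the replicate-mean
fraction); per-replicate estimates are also kept, since the alternative
order of operations is equally defensible and the difference is second-
order at these noise levels.  The steady-state relation `X* = k/δ`,
`δ = ln2/T`, predicts an abundance ratio `(k₁/k₂)(T₁/T₂)`: a two-fold
stability change alone accounts for a two-fold steady-state difference.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume, with
ground truth carried in a sidecar object, never in the analyzed columns.

- **Noise model.**  Gaussian on the log2-ratio scale for arrays
  (screen default SD 1.0; RIP-ChIP 0.5; expression 0.2), multiplicative
  log-normal for qPCR (default CV 5%).  Designs default to the study
  layout: six dye-swap screen replicates (three per set), 6 IP + 6 mock
  arrays, two expression replicates, three qPCR replicates over a 0/30-min
  shut-off.
- **Intensity back-transform.**  Log-ratios are encoded as foreground
  intensities around a log-normal reference baseline (median 2^13 ≈ 8,200
  arbitrary units, log2-SD 1) plus an additive background (100 units),
  so the detectability filter is exercisable and dropouts can be injected.
  The baseline sits well above background deliberately: raw-foreground
  ratios are compressed by a factor `≈ S/(S+B)` that varies with spot
  brightness, and at dim baselines this protein-dependent compression
  fattens the z-score tails enough to break the product-null calibration
  the screen statistic assumes.  At the default scale the compression is
  ≤ 2% and the global-null classifier rate matches the closed form within
  Monte-Carlo error (verified over 10⁶ protein-trials).  Zero-noise
  identity tests set the background to zero, where the encoding is exactly
  ratio-faithful.
- **Dye bias** is a per-array constant whose sign follows the dye carrying
  the query, plus a small random per-array offset (SD 0.1 log2); both are
  removed by centering, which is the point — they make dye-swap handling
  non-trivial without changing any statistic.
- **Seeding.**  A single root seed spawns fixed per-stream child
  generators (screen/ripchip/expression/decay), so identical (seed,
  parameters) give byte-identical outputs and modules are independently
  reproducible.

**What the generators do not emulate:** spot morphology, scanner
saturation, spatial or print-tip artifacts, intensity-dependent (loess-
type) dye bias, cross-hybridization, or correlated gene–gene structure.
Passing the recovery and calibration suites therefore demonstrates the
statistics are implemented and calibrated as described above — not that the
pipeline is robust to every artifact of real arrays.

## Problem sizes in the test and acceptance suites

Calibration and recovery checks run at the study's design sizes (2,000
features; six screen replicates; 6 IP/6 mock; 3 qPCR replicates at 5%
noise).  Monte-Carlo repetition counts are the package's own choices:
40 pooled runs for the screen null rate (120,000 protein-trials against an
expected 2.77×10⁻⁵, a ±3-SD band), 20 seeds for spike-in recovery and SAM
null calibration (500 permutations), 30–40 seeds for decay recovery and
the RIP-ChIP power property.  Stochastic ≥95%-of-runs properties are
asserted through a 1%-level binomial bound at the nominal rate rather than
exact counts, so a passing implementation does not fail on Monte-Carlo
error.  The mutant stabilization ratios are recovered as the median over
30 simulated three-replicate shut-off assays per strain.

## Known limitations

- The combined product score is reported uncalibrated, mirroring the
  analysis it reimplements; use the Fisher column when a calibrated
  combined p-value is needed.
- The simplified SAM's fixed `s₀` makes q-values slightly conservative for
  genes with very small standard errors compared to the percentile-search
  original.
- The two-point half-life estimator is exact under first-order decay but
  has no goodness-of-fit information; multi-point series with the
  log-linear method are preferred when available.
- GPR support covers the median foreground/background columns of the
  standard two-color layout only.
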