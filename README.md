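# screenkit

Statistical pipeline for finding and characterizing RNA-binding proteins of
the yeast unfolded protein response (UPR), built around the post-
transcriptional regulation of *HAC1* — the mRNA encoding the UPR
transcription factor, whose unspliced isoform (*HAC1*u) is held inactive
until the ER-stress sensor Ire1 splices it.  The package is for
computational biologists who work with two-color microarray and qPCR data
and want the analysis chain of an RNA-binding screen reproducible end to
end, including over fully synthetic data.

Four analysis stages, each a model/results pair, plus a seeded generator
for every input class:

1. **Binding screen** (`BindingScreenModel`).  A labeled query RNA competes
   against labeled total mRNA on a proteome array, six replicates with the
   dyes swapped in half.  Per array, proteins with foreground ≤ 1.5×
   background in either channel are filtered; the remaining
   log₂(query/reference) ratios are median-centered, z-scored, and mapped
   to one-sided Gaussian tail p-values, `p = P(Z ≥ z)`.  Each dye set's
   three replicate p-values are combined by their product
   `P = p₁p₂p₃`, whose null CDF is `F(x) = x Σ_{j<3} (−ln x)^j / j!`; a
   protein is a high-confidence interactor when `P < α` (default 10⁻⁴) in
   **both** dye sets.
2. **RIP-ChIP enrichment** (`RipChipModel`).  IP vs mock-IP two-channel
   arrays; after per-array median centering, mock-corrected IP enrichment
   is `E_g,r = IP_g,r − mean_mocks(Mock_g,·)`, with a presence filter
   (detectable in ≥ 9 of 12 arrays, or a strict majority for smaller
   designs), ranking by mean enrichment, one-tailed t-tests, and a
   simplified SAM comparison across conditions:
   `d_g = (x̄_A − x̄_B)/(s_g + s₀)` with permutation-based q-values.
3. **Knockdown profiling** (`KnockdownModel`).  Median-centered
   log₂(knockdown/WT) ratios per replicate, per-gene fold-changes, and an
   unpaired t-test asking whether an annotated target set (e.g. UPR
   targets) shifts relative to the rest of the transcriptome.
4. **Decay estimation** (`DecayModel`).  After transcription shut-off,
   reference-normalized qPCR abundances give remaining fractions
   `f = X(t₁)/X(t₀)` and the two-point half-life
   `T = (t₁ − t₀)/log₂(X(t₀)/X(t₁))`, generalized to a log-linear fit for
   longer time courses; at steady state of first-order synthesis–decay the
   predicted abundance ratio between strains is `(k₁/k₂)(T₁/T₂)`.

## Worked example

```python
import screenkit as sk

# a six-replicate dye-swap screen with two spiked binders
es, truth = sk.simulate_screen(n_proteins=2000, truth_set=("P0007", "P0042"),
                               effect=4.0, noise_sd=1.0, seed=17)
results = sk.BindingScreenModel(es).fit()
print(results.summary())

# shut-off decay arithmetic from measured 30-min remaining fractions
wt = sk.half_life_two_point(0.0, 30.0, 0.3347)
kd = sk.half_life_two_point(0.0, 30.0, 0.5700)
print(f"wild-type HAC1u half-life : {wt.half_life:.1f} min")
print(f"ypt1-DAmP HAC1u half-life : {kd.half_life:.1f} min")
print(f"stabilization             : {sk.half_life_ratio(kd, wt):.2f}-fold")
```

prints

```
Dye-swap RNA-binding screen
===========================
proteins on array:      2000
scorable in both sets:  2000
alpha (per dye set):    0.0001
classified interactors: 2
expected under null:    0.0554

rank  protein          combined_A   combined_B
   1  P0042            3.269e-11  1.757e-18
   2  P0007            3.851e-09  2.745e-14

wild-type HAC1u half-life : 19.0 min
ypt1-DAmP HAC1u half-life : 37.0 min
stabilization             : 1.95-fold
```

Both spiked proteins — and nothing else — clear the dual dye-set product
threshold (under the global null the closed form predicts 0.055 false
calls among 2,000 proteins), and a 30-minute remaining fraction of 0.3347
corresponds to a 19-minute half-life.  Slowing decay from 19 to 37 minutes
doubles the transcript's steady-state abundance at unchanged synthesis.

The same stages run from the shell: `screenkit simulate screen --seed 17
--out runs/`, then `screenkit screen --arrays runs/screen_arrays.tsv
--meta runs/screen_metadata.tsv --out runs/`; see `screenkit --help`.
`screenkit reproduce --seed 17 --out runs/` regenerates every synthetic
input class, runs all stages and reports pass/fail target checks.

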