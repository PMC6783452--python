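# Methods

This note documents the measurement model behind `mprasplice`, the defaults
and the reasoning for the choices that were genuinely open.

## Library layout and coordinate convention

Every library member is exactly 210 nt:

```
fwd primer (18) + barcode (12) [+ SpeI-NNN-AatII cassette (15)] + variable region + rev primer (18)
```

The internal cloning cassette is present only for the cassette-exon and
tandem-3′ layouts (which need a second cloning step), leaving 147 nt for
the variable region instead of 162 nt. Barcodes are 12-mers sampled by
seeded rejection so that every pair differs in at least 3 nt — one
sequencing error cannot convert one barcode into another. Recognition
sites for the cloning enzymes (RsrII, AscI, SpeI, AatII, XbaI) are excluded
from variable regions; assembling a region that contains one raises an
error naming the enzyme and position.

All edit windows are half-open `[start, end)` intervals in a signed
coordinate system anchored at a splice site: for donors position 0 is the
first intronic base (so the consensus window −3:+6 covers 3 exonic + 6
intronic bases = `CAGGTAAGT`), for acceptors position 0 is the first exonic
base (so −15:+3 covers the 18-nt acceptor consensus and −26:−21 the 5-nt
branch-point element). This is the only convention under which every
shipped replacement string matches its window length, which is why it was
adopted package-wide.

Open layout choices: contexts shorter than the budget are padded 3′ with a
neutral `CAT` repeat (no splice motifs, no restriction sites, no
homopolymer); hexamer regulatory elements are written into 9-nt windows
with the three splice-site-proximal positions retained; synonymous-recoding
GC ties are broken by lexicographic codon order so recoding is
deterministic.

## Synthetic data generator

The generator emulates the assay's three measurement channels from a
planted truth per variant:

* **RNA log ratio** `r`: a linear combination of standardized feature
  columns plus Gaussian noise. Isoform reads are
  `total ~ Poisson(depth)`, `N_iso1 ~ Binomial(total, 2^r/(1+2^r))`, so the
  estimator `log2(N1/N2)` is consistent for `r`. Default depth: 10,000
  reads/variant.
* **Protein splicing value**: `a + b·tanh(r/c)` with `a = b = 2.5`,
  `c = 2` — a monotone saturating link producing values in [0, 5] with a
  plateau near 5, mimicking the saturation of fluorescence-based splicing
  readouts at consensus-site efficiency.
* **Cell-to-cell SD** `σ` of `log2(GFP/mCherry)`:
  `LogNormal(log 0.4, 0.5)` clipped to [0.1, 1.0] — between a tenth of a
  bin width and roughly two bin widths, the regime in which a 16-bin sort
  is informative. When noise is flagged as sequence-encoded, variants with
  identical variable regions share one σ draw.
* **Sorting**: each variant contributes `cells_per_variant` (default
  5,000) cell values from `Normal(protein value, σ²)`. Bin boundaries are
  population quantiles giving 16 equal-occupancy bins (6.25% each, inside
  the 1–10% occupancy rule); quantile placement concentrates bins where the
  population is dense, which keeps the discretization error of the weighted
  moments small even near the saturation plateaus. Per-bin sequencing depth
  is proportional to the bin's cell share (samples mixed at population
  ratios) and reads within a bin are multinomial across variants.

All draws flow from a single seed; reruns are bit-identical.

What the generator does **not** emulate: PCR and synthesis errors, cryptic
splice sites, barcode cross-talk, FACS gating artifacts, bin-boundary
drift, or transcript degradation coupling RNA and protein readouts. Passing
the recovery tests therefore shows the estimators are correct under the
stated sampling model, not that real libraries are free of these effects.

## RNA quantification

Variants need ≥ 100 mapped isoform reads. If all reads support one isoform,
one read is added to **both** counts before the ratio — the symmetric
reading of the one-read pseudo-count rule, chosen because it preserves the
exact antisymmetry `ratio(a,b) = −ratio(b,a)` (implemented as
`log2(N1) − log2(N2)`, which keeps the negation exact in floating point).
Expression is `log2((RNA+0.5)/(DNA+0.5))`; the half-read offset guards
zero counts. Wild-type normalization subtracts the per-context mean of
wild-type replicate ratios; contexts without a passing wild type yield
missing values, never zeros. Confidence intervals are percentile bootstrap
with 1,000 iterations.

## Protein quantification

Filter cascade, in this order (the order matters and is pinned by a
regression test): (1) drop variants with < 200 reads across bins; (2) zero
bins with < 5 reads or < 2% of the variant's reads; (3) zero bins
surrounded by zeros (isolated bins — singleton read pileups in a distant
bin are more plausibly contamination than signal); (4) drop the variant if
the retained normalized mass is < 30% of the pre-filter mass. Bin weights
are depth-corrected first (variant reads ÷ bin total × bin population
share) so unequal per-bin sequencing depth cancels; the raw per-variant
fraction is available as a config alternative.

Smoothing uses a Savitzky–Golay filter with window 5 and polynomial
order 2 — the smallest symmetric window that does meaningful smoothing on
16 points — and feeds **only** peak QC. A position is a peak when it holds
the running maximum and was preceded, since the last peak, by a value at
least δ = 0.05 lower; the candidate is finalized when the profile falls δ
below it or at the end of the scan (so a distribution pressed against the
first or last bin still counts as unimodal). Variants without exactly one
peak are disregarded.

The splicing value and variance are weighted moments of the per-bin median
`log2(GFP/mCherry)` under the **unsmoothed** normalized weights; noise
strength is variance/mean. Variants with a non-positive mean get a QC flag
and no noise strength — a ratio with a vanishing denominator is not a
usable noise measure — and are excluded from the noise model by default.

## Noise model and encoding test

Noise strength is regressed on the splicing value (20 B-spline basis
functions, second-order difference penalty, penalty weight by generalized
cross-validation) and linearly on expression, using a Gaussian generalized
additive model (statsmodels `GLMGam`). The residual from this fit is the
per-variant noise residual; its mean is ~0 by construction because the
intercept is unpenalized.

The sequence-encoding test asks, for each group of ≥ 8 variants with
identical variable regions, whether the group's residual variance is
smaller than chance: it is compared against 10,000 random same-size sets
drawn from non-member variants whose splicing value lies within ±0.5 log2
units of the group mean (nearest-N fallback when that window is thin). The
±0.5 window is a compromise between matching fidelity and pool size; the
reported null fraction is calibrated — uniform under the null — which the
acceptance suite verifies by simulation.

## Features and prediction

Hexamer counts are overlapping, per region (the three-region scheme per
splicing type: e.g. upstream exon / intron / downstream exon for retained
introns). PWM scores are cumulative log-odds over all alignment positions,
the standard occupancy proxy for RBP binding. Splice-site strength uses a
consensus-weighted first-order PWM over the MaxEntScan-convention windows
(9-mer donors, 23-mer acceptors) by default; the scorer is pluggable and a
k-mer score table (e.g. precomputed maximum-entropy scores) can be dropped
in, but scores from different scorers are never mixed in one feature
matrix. Secondary structure uses ViennaRNA's `fold` (MFE and binary
pairedness from the MFE structure); a Nussinov-style base-pair-maximization
fallback exists for environments without the bindings and is explicitly
approximate (its "energies" are pair counts).

The prediction protocol collapses duplicate sequences to one random
representative before any split (otherwise barcode-control replicates leak
between train and test), holds out 10% for final scoring only, tunes
learning rate / tree count / depth by 10-fold cross-validated R², selects
features with importance above the mean, re-tunes on the reduced set and
refits. The default grid (3 learning rates × 2 tree counts × 2 depths) is
desk-scale and fully configurable.

## Problem sizes used in validation

The test suite validates the estimators at these scales, chosen as the
package's reference conditions: end-to-end recovery on 2,000 variants with
5,000 cells/variant and 10,000 reads/variant; encoding-test calibration on
100 null groups with 1,000 random sets each; signal recovery for the
prediction protocol on 3,000 variants with 5 planted signals among 500
decoy features (single-point grid at this scale; the grid search itself is
exercised at smaller scale).

## Known limitations

* Noise strength divides by the mean splicing value, so for variants with
  means near zero it is dominated by the denominator; across a library
  whose protein values span [0, 5] its rank agreement with the underlying
  cell-to-cell variance σ² is capped around 0.79 *even for the exactly
  known planted quantity* — the variance estimate itself tracks σ² at
  Spearman ≈ 0.96. Comparisons of noise levels should therefore rely on
  the GAM residual (which conditions on the mean), not raw noise strength.
* The weighted-moment splicing value is biased toward the interior for
  variants whose cell distribution extends beyond the outermost bin
  boundaries; quantile binning mitigates but does not remove this.
* The Nussinov fallback maximizes pair counts and is not thermodynamic;
  MFE-based features from the two engines are not comparable.
* `assign_reads` expects reads pre-classified by junction (aligned
  upstream); it performs demultiplexing and filtering, not alignment.
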