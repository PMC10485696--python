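# Methods

## Model and estimands

`mrkit` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics. For each genetic variant *j* used as an instrument, let
β<sub>Xj</sub> ± σ<sub>Xj</sub> be its estimated association with the
exposure and β<sub>Yj</sub> ± σ<sub>Yj</sub> with the outcome, from two
separate samples. Under the instrumental-variable assumptions (relevance,
no association with confounders, no direct path to the outcome), each
variant gives a Wald-ratio causal estimate

  β̂<sub>j</sub> = β<sub>Yj</sub> / β<sub>Xj</sub>,
  se(β̂<sub>j</sub>) = σ<sub>Yj</sub> / |β<sub>Xj</sub>|  (first order),

with inverse-variance weight w<sub>j</sub> = β<sub>Xj</sub>² / σ<sub>Yj</sub>².
Three combiners with different robustness profiles are provided:

* **IVW**: β̂ = Σ w<sub>j</sub> β̂<sub>j</sub> / Σ w<sub>j</sub>,
  algebraically identical to a zero-intercept weighted regression of
  β<sub>Y</sub> on β<sub>X</sub> with weights 1/σ<sub>Y</sub>².
  Fixed-effect SE (Σ w<sub>j</sub>)<sup>−1/2</sup>; the default
  multiplicative-random-effects model scales it by
  φ̂ = √(Q/(L−1)), with underdispersion (φ̂ < 1) permitted. Unbiased only
  when every instrument is valid.
* **MR-Egger**: the same weighted regression with a free intercept. The
  slope is a consistent causal estimate under InSIDE (pleiotropic effects
  independent of instrument strength); the intercept estimates mean
  directional pleiotropy. Because the slope is not invariant to the
  arbitrary choice of effect allele, instruments are canonicalized first
  (pairs with β<sub>X</sub> < 0 are sign-flipped); this makes the output
  invariant to the input orientation and is recorded in the fit metadata.
  Residual scale φ̂² = RSS<sub>w</sub>/(L−2), underdispersion permitted;
  p-values from Student t with L−2 df.
* **Weighted median**: order the β̂<sub>j</sub> ascending and place the
  *j*-th at standardized cumulative weight
  p<sub>j</sub> = (S<sub>j</sub> − w<sub>j</sub>/2)/S<sub>L</sub>; the
  estimate linearly interpolates at p = 0.5. Consistent while valid
  instruments carry ≥ 50% of the total weight. Its SE is the standard
  deviation of the estimate over a parametric bootstrap that redraws every
  β<sub>Xj</sub> and β<sub>Yj</sub> from normals centered at the observed
  values with the reported SEs (default 1000 replicates, seeded).

Estimates are reported on the log-odds scale and as odds ratios
exp(β ± z·se); z defaults to the exact 97.5% normal quantile. The packaged
reproduction uses z = 1.96 because the published intervals round-trip with
that value.

## Harmonization and instrument selection

Exposure and outcome records are aligned to a shared effect allele:
identical orientation passes through; swapped alleles negate the outcome
beta and complement its EAF; strand-complemented records are complemented
first. Palindromic variants (A/T, C/G) are resolved by effect-allele-
frequency agreement when both EAFs fall outside the ambiguous band
0.5 ± 0.08, and dropped otherwise (both the window and the drop policy are
arguments). When a table omits the other allele — as the packaged extract
does — harmonization falls back to effect-allele equality with a warning
and leaves the palindromic flag undetermined. Unresolvable allele pairs
are dropped with a logged reason, never silently kept.

Selection keeps variants with exposure p < 5×10⁻⁸ and instrument-strength
F = (β<sub>X</sub>/σ<sub>X</sub>)² > 10, then greedily clumps on a
user-supplied pairwise r² matrix (threshold 0.1), retaining the most
significant variant of each correlated group; ties break lexicographically
for reproducibility. The package never computes LD from genotypes — r² is
an input. Pairs absent from the matrix are treated as independent with a
warning.

## Heterogeneity and influence diagnostics

Cochran's Q is Σ w<sub>j</sub>(β̂<sub>j</sub> − β̂)² for IVW (df = L−1) and
the weighted residual sum of squares of the intercept regression for Egger
(df = L−2, both slope and intercept estimated). I² = (Q − df)/Q is stored
signed — it is negative whenever Q < df — with a display-magnitude accessor
because published tables sometimes print magnitudes. Q = 0 leaves I²
undefined and sets the heterogeneity p to 1. Leave-one-out repeats IVW
with each instrument removed; the funnel diagnostic plots β̂<sub>j</sub>
against precision 1/se(β̂<sub>j</sub>) (precision rather than weight, the
conventional funnel axis). All figures are rendered from the diagnostic
tables alone, so plot and table content cannot diverge.

## Packaged dataset and the reproduction report

The package ships the seven-variant instrument extract for the Neale-lab
UK Biobank GWAS pair "aspirin use" (MR-Base ukb-a-132, n = 337,159,
exposure) and "doctor-diagnosed hayfever or allergic rhinitis" (ukb-a-254,
n = 83,529, outcome). `reproduce_published()` re-runs the full pipeline on
it and flags each quantity REPRODUCED or DOCUMENTED-DISCREPANCY against
the values reported in the originating analysis (0.5% relative tolerance,
absolute 5×10⁻⁴ for near-zero intercepts — printed values carry about four
significant figures).

Recomputation reproduces: four of the seven published F statistics, the
weighted-median estimate (−0.4162 vs −0.4155), and all exp-scale
identities of the published (β, SE) rows. It does **not** reproduce:

* three published F statistics, which appear permuted across rows —
  (β/σ)² gives ≈33.39 for rs583104 (printed 40.22), ≈40.22 for rs73015016
  (printed 32.78) and ≈32.78 for rs7412 (printed 38.51);
* the published IVW β (−0.349; recomputed −0.3030) and Egger
  slope/intercept (−0.3742/0.00021; recomputed −0.712/+0.0032) under
  either orientation convention;
* the published Q statistics (2.148/2.143; recomputed 5.65/4.17), and two
  published upper CI bounds that are inconsistent with exp(β + 1.96·se) of
  their own rows.

These are properties of the published per-SNP table itself — independent
weighted-least-squares oracles on the printed numbers give the same
recomputed values — so the package documents them as discrepancies rather
than forcing agreement. The published I² magnitudes (1.793, 1.333) *are*
internally consistent with (Q − df)/Q applied to the published Q values.

## Synthetic data

The generator draws true exposure effects γ<sub>j</sub> ~ N(0.01, 0.0025)
(the magnitude of the packaged extract), sets true outcome effects
Γ<sub>j</sub> = β·γ<sub>j</sub> + α<sub>j</sub>, and adds independent
Gaussian estimation noise with SE scales 10⁻³ (exposure) and 2.5×10⁻³
(outcome), again matching the extract's order of magnitude; with those
defaults F ≈ 100. Pleiotropy α<sub>j</sub> ~ N(mean, sd) hits exactly
round(invalid_fraction·L) variants; an InSIDE-violation toggle correlates
α<sub>j</sub> with γ<sub>j</sub> (ρ = 0.7). SEs may instead be derived
from sample sizes and allele frequency as 1/√(2·n·p(1−p)). Variants are
generated mutually independent (the post-clumping state) and never
palindromic, so synthetic data exercises estimation, not allele ambiguity
— tests passing on it say nothing about strand inference on real data,
which the harmonization unit tests cover separately. All randomness flows
from one master seed through spawned child streams, so any replicate is
independently reproducible.

Recovery experiments report bias, RMSE, empirical vs model SE, 95%
coverage and rejection rate per estimator. The test battery uses 50-SNP
configurations with 1000 replicates for the type-I-error check (binomial
tolerance [0.035, 0.065] around the nominal 0.05) and 200 replicates for
the pleiotropy-robustness comparisons; these sizes keep Monte-Carlo error
well below the effect sizes being compared.

## Numerical choices and limitations

* Weighted regressions are solved by weighted normal equations; the test
  suite cross-checks them against statsmodels WLS as an independent oracle.
* The Wald-ratio SE is first-order (exposure uncertainty ignored), the
  convention under which the published weighted median is reproduced; a
  second-order SE is deliberately out of scope for estimation because the
  weights w<sub>j</sub> = β<sub>Xj</sub>²/σ<sub>Yj</sub>² define the
  estimators being mirrored.
* With exact data (zero residuals) the multiplicative-random-effects SE
  collapses; it is floored at the smallest positive float so the estimate
  remains well-defined.
* A bootstrap with `n_boot = 1` returns an undefined (NaN) SE rather than
  a misleading zero.
* Binary-trait effects are treated as log-odds throughout; no
  binary-exposure attenuation correction is applied.
* No proxy-variant lookup, no multivariable or bidirectional MR, no
  mode-based estimators, no outlier-removal (MR-PRESSO) — the scope is the
  three-estimator battery plus its sensitivity analyses.
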