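# Methods

## Setting and data model

The package implements a complete two-sample Mendelian randomization (MR)
workflow over GWAS summary statistics: per-SNP effect sizes with standard
errors from one GWAS of the exposure (metformin use, a 0/1 treatment
indicator analysed with a linear model in ~463k UK Biobank participants) and
one of the outcome (rheumatoid arthritis, log-odds scale, ~58k subjects).
No individual-level data are touched.  The bundled reference dataset is the
source study's 32-SNP harmonized instrument table (exposure and outcome
betas, SEs, p-values, effect-allele frequencies and per-SNP F statistics),
shipped as plain TSV package data.

## Instrument selection

Candidate instruments pass, in pipeline order: genome-wide significance
(p < 5e-8, strict), LD clumping, harmonization, Steiger directionality
filtering, and the weak-instrument filter — each drop recorded in the
instrument set's provenance with a machine-readable reason.

**Clumping** is the standard greedy scheme: scan SNPs by ascending p
(ties broken lexicographically by rsID for determinism) and keep a SNP only
if its r² with every kept SNP is below 0.001 within a 5000 kb window.  The
package computes no LD itself: callers plug in any pairwise r² source via
the `LdProvider` contract (e.g. a precomputed matrix), and pairs without LD
information fall back to a distance-only rule (reject within the window on
the same chromosome), which requires positions.

**F statistics.** The per-SNP instrument-strength F is taken as z², with z
recovered from the exposure p-value via the upper-tail normal quantile
(`from_p`, the default) or as (β/SE)² (`from_beta_se`).  On exact inputs the
two agree to six significant figures (property-tested); on published tables
rounded to four decimals they need not, and `from_p` is preferred because
printed p-values carry more relative precision than 1-significant-digit SEs.
The tail inversion is accurate to p ~ 1e-300 (scipy's `ndtri`, cross-checked
against R's `qnorm` and a 60-digit computation).  A caveat discovered while
validating: the bundled table's printed F column was evidently derived from
*unrounded* p-values upstream — the printed p-values reproduce it only to
~0.05 (e.g. z²(6.100e-9) = 33.8025 vs the printed 33.8179), which is the
expected effect of 4-significant-figure p rounding, not an implementation
discrepancy.  Summary statements (mean F = 64, range 31–578) are unaffected.

**Steiger filtering** compares variance explained using the z-and-n
approximation r² = z²/(z² + n − 2), keeping a SNP iff r²_exposure >
r²_outcome (strict).  When sample sizes are unavailable — as in the bundled
table — the filter is skipped with a warning rather than guessed.

## Harmonization

The outcome record is re-expressed per copy of the exposure's effect allele:
identical alleles copy through; swapped alleles negate β_out and complement
the outcome EAF; strand-complemented alleles (A↔T, C↔G) are complemented
first and then the same rules applied.  Harmonization never changes |β_out|
or its SE (property-tested), and the full 12×12 ordered-allele-configuration
space is checked against a hand truth table.  Palindromic SNPs (A/T, C/G)
are indistinguishable from their own strand complement; orientation is
recovered from allele frequency when informative (both EAFs on the same side
of 0.5 after alignment; flipped otherwise), and the SNP is dropped when the
exposure EAF lies inside the intermediate window or is missing
(conservative: strand cannot be inferred).  The window defaults to
[0.42, 0.58], symmetric about 0.5 — the source analysis states only
"intermediate allele frequencies", so the bound follows common two-sample MR
practice and is exposed as configuration.

## Estimators

All estimation is on the log-odds scale; odds ratios and Wald 95% CIs
(multiplier 1.959964) are derived by exponentiation, never by averaging ORs.

* **Wald ratio**: r_j = β_Yj/β_Xj with first-order SE σ_Yj/|β_Xj|.  The
  first-order form (ignoring exposure-side noise) is the default because it
  is what standard two-sample MR tooling uses and what reproduces the
  reference results; a second-order option adding β_Y²σ_X²/β_X⁴ sits behind
  a flag.
* **IVW**: inverse-variance-weighted mean of the ratios (algebraically the
  zero-intercept weighted regression of β_Y on β_X with weights 1/σ_Y²,
  verified against an independent WLS solve).  `fixed` uses SE = (Σw)^(−1/2);
  `random_multiplicative` multiplies it by max(1, sqrt(Q/(J−1))) — no
  underdispersion credit.  Both are reported by the analysis driver; the
  reference study's printed CI and p correspond to the multiplicative
  random-effects variant, its OR to either.
* **MR-Egger**: instruments oriented so β_X > 0, then weighted least squares
  of β_Y on β_X *with* intercept, weights 1/σ_Y².  Coefficient SEs are
  divided by min(weighted residual SD, 1) and p-values use t(J−2) — the
  conventions of standard MR software, needed to reproduce the reference
  intercept SE.  The intercept estimates average directional pleiotropy.
* **Weighted median**: interpolated 50th percentile of the ordered ratios
  under cumulative normalized inverse-variance weights
  p_j = (Σ_{k≤j} w_k − w_j/2)/Σw.
* **Mode-based estimators**: Gaussian-kernel density over the ratios with
  the modified Silverman bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5)
  (φ = 1 by default), weights normalized inverse ratio variances (weighted)
  or uniform (simple).  The argmax is taken on a 512-point grid spanning the
  ratio range padded by 3h — grid and padding are implementation choices
  (the reference names no KDE settings) and are configurable; mode results
  should be read to about one significant figure.  A degenerate bandwidth
  (all ratios identical) returns the common ratio with the IVW SE.

Median and mode SEs use a parametric bootstrap (default 1000 draws, seeded):
both betas are redrawn from N(observed, SE), the estimator recomputed, and
the SD over draws taken.  Bootstrap output is bit-reproducible under a fixed
seed; two 1000-draw runs with different seeds agree to a few percent.

## Sensitivity battery

* **Cochran's Q** about the fixed-effect IVW centre, p from χ²(J−1).  The
  same Q feeds the random-effects scale — single source of truth.
* **Egger intercept test**: the intercept triple from the Egger fit.
* **MR-PRESSO**: observed statistic is the leave-one-out weighted residual
  sum of squares RSS = Σ_j d_j²/σ_Yj², d_j = β_Yj − θ̂₋j β_Xj.  Null
  replicates redraw β_X* ~ N(β_X, σ_X) and β_Y* ~ N(θ̂₋j β_Xj, σ_Y) and
  recompute RSS identically.  Monte-Carlo p-values use (1+k)/(1+n_sim), so
  they are never zero; per-SNP outlier tests are Bonferroni-corrected at
  0.05/J (the reference reports only the global test); when outliers are
  flagged, a distortion test compares the estimate shift against random
  same-size removals.  Randomness uses one root seed with per-SNP substreams
  keyed by a stable hash of the rsID, making results invariant to instrument
  order.
* **Leave-one-out**: fixed-effect IVW re-fit J times, plus an all-SNP row.

## Synthetic data generator

The generator emulates the study design, not generic GWAS data: a huge
linear-model binary-exposure GWAS paired with a smaller case-control outcome
GWAS.  Defaults are the study conditions: J = 32 instruments, n_exp =
462,933 (case fraction 11,552/462,933), n_out = 58,284 (14,361/58,284),
MAF ~ U(0.05, 0.5), mean per-SNP exposure variance explained 1.4e-4 (so
per-SNP F averages ~64 at the exposure sample size, matching the bundled
table), and θ = −3.76.  Standard errors follow the survey formulas
σ_X = sqrt(μ_x(1−μ_x)) / sqrt(2f(1−f)·n_exp) (linear model on a 0/1 trait)
and σ_Y = 1/sqrt(2f(1−f)·n_out·μ_y(1−μ_y)) (logistic), which reproduce the
bundled table's SE scales (~3.5e-4 and ~0.02).  Pleiotropy laws: none,
balanced N(0, σ), directional N(μ, σ) — defined relative to the
exposure-increasing allele so the mean is estimable by the Egger intercept —
and correlated (α = k·β_X + noise, violating InSIDE).  Planted outliers add
a ±`outlier_scale`·σ_Y pleiotropic shift.  A configurable fraction of SNPs
get palindromic allele pairs and outcome records are emitted in randomly
swapped/strand-flipped orientations, so harmonization is exercised on every
dataset.  `simulate_significant_instruments` rejection-samples on the *true*
exposure z so selection introduces no winner's curse; infeasible scenarios
(acceptance probability < 1e-6, computed analytically) raise immediately.
One root seed with per-SNP counter substreams makes draws independent of
panel size and order.

What the generator does **not** emulate: LD between instruments (clumping is
tested through explicit r² matrices instead), allele-frequency differences
between cohorts beyond small noise, winner's curse, sample overlap between
the two GWAS, and population stratification.  Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under the
stated model, not robustness to those real-data complications.

## Numerical and design choices

* Strict inequalities at every threshold (p < 5e-8, F ≥ 10 keeps F = 10,
  Steiger keeps only r²_X > r²_Y), matching the stated selection rules.
* Clumping tie-break: lexicographic rsID at equal p (determinism).
* "Mean F" is the arithmetic mean of per-SNP F; the analysis driver also
  prints the median since the F distribution is heavily right-skewed.
* Monte-Carlo p floor 1/(1+n_sim), reported as an upper bound when no
  simulated statistic exceeds the observed one.
* Missing EAF/n serialize as `NA`; every downstream operation either
  declares behaviour on absent fields (palindromic drop, Steiger skip) or
  does not need them.
* Problem sizes in the test suite (e.g. 400 null replicates for type-I
  calibration, 100 replicates for outlier-detection rates, 1000 MR-PRESSO
  simulations) are chosen so the whole suite completes in a few minutes on
  one CPU while keeping Monte-Carlo bands comfortably narrower than the
  asserted tolerances.

## Known limitations

* No proxy-SNP lookup for instruments missing from the outcome GWAS, no
  multivariable MR, no MR-RAPS/contamination-mixture estimators, no
  reference-panel LD computation, and no VCF input.
* The bundled table lacks sample sizes, so the Steiger filter cannot run on
  it (skipped with a warning), mirroring the information actually printed.
* The first-order Wald SE understates uncertainty when instruments are
  weak; all bundled and default-synthetic instruments have F > 30, where
  the approximation is good.
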