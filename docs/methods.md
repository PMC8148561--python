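# Methods

## Trial model

The package targets balanced split-plot screening trials: irrigation regimes
(full vs. limited) on main plots, genotypes on subplots, repeated over
seasons with r replicates. The observation model per trait is additive:

    y_gsir = mu + season_s + regime_i + rep(s)_r + rep(s,i)_r
             + G_g + GE_(g,si) + eps_gsir

with genotypic effects G shared across regimes and seasons,
genotype-by-environment effects GE specific to each season × regime cell, and
plot residuals eps. Seasons are treated as a random environmental draw;
regimes and genotypes are fixed. "Environment" means a season × regime
combination by default (e = seasons × regimes), because the stress response
itself differs between regimes; e can be set to the season count instead —
both readings are defensible for the heritability denominator and the choice
is recorded in every output.

## Combined ANOVA and genetic parameters

For a balanced table the sums of squares of the sources S, rep(S), I, S×I,
rep(I×S), G, S×G, I×G, S×I×G are computed from cell-mean contrasts, and the
Error SS is the exact remainder of the total SS (conservation is asserted on
every run). Variance components are method-of-moments estimates:

    s2_re  = MS_Error
    s2_gxe = (MS_GxE - MS_Error) / r
    s2_g   = (MS_G - MS_GxE) / (r e)

Negative estimates are truncated to zero and logged, the standard practice
for ANOVA estimators. Which mean square plays the role of MS_GxE is
genuinely ambiguous in a two-factor environment: published reports variously
use S×G, I×G, S×I×G or a pooled value, and the packaged summary tables are
not mutually reconcilable under any single convention. The package therefore
defaults to the df-weighted pool of the three interaction mean squares and
records the convention in the output; all four conventions are selectable.

Genetic parameters follow the coefficient-of-variation convention:
GCV = 100·sqrt(s2_g)/X̄, PCV = 100·sqrt(s2_p)/X̄ with
s2_p = s2_g + s2_gxe/e + s2_re/(r·e), heritability h² = s2_g/s2_p (reported
in percent), genetic advance GA = k·h²·sqrt(s2_p) with k = 2.06 (the
standardized selection differential at 5% selection intensity), and genetic
gain GG = 100·GA/X̄. These definitions satisfy h² = (GCV/PCV)² exactly,
which the packaged genetic-parameter table reproduces to rounding (e.g.
grain yield: (10.80/14.24)² = 57.5% against a printed 57.60%) — the reason
this square-root reading was fixed. X̄ is the unweighted mean of all plot
observations, which in a balanced design equals the mean of the four
season × regime cell means.

## Trait screening

Collinearity is diagnosed on genotype-mean (or treatment-cell) matrices:
tolerance_j = 1 − R²_j of trait j regressed on all others, VIF_j = 1/tolerance_j,
computed through a standardized least-squares fit so perfectly collinear
traits are flagged infinite rather than failing. Iterative exclusion drops
the single worst trait (alphabetical tie-break, logged) and recomputes until
max VIF ≤ 10. PCA operates on the trait correlation matrix; components are
Kaiser-retained (eigenvalue > 1) and the sign of each component is fixed so
its largest-magnitude loading is positive, making outputs deterministic.
Trait selection takes |loading| > 0.27 on any of the first two components:
the absolute value matters because informative traits (canopy temperature,
water-use efficiencies) legitimately load negatively. The 0.27 cutoff is
applied to raw unit-length eigenvector loadings, not loadings scaled by
sqrt(eigenvalue).

## Yield modelling

Stepwise regression is classical forward selection with a backward removal
check: enter the candidate with the smallest partial-F p-value while it is
below alpha_enter (default 0.05), then drop any entered trait whose p-value
exceeds alpha_remove (default 0.10); the alphas are configurable because no
single pair is canonical. Selection stops at an exact fit and guards against
enter/remove cycles. Partial R² is reported as the R² increment in entry
order. Regression rows default to genotype × season × regime cell means.

Path analysis standardizes all variables and solves R_x·p = r_xy for the
direct effects p; indirect_i = r_iy − p_i, R² = Σ p_i·r_iy, residual effect
= sqrt(1 − R²). The identities r_iy = direct + indirect and R² = Σ p_i·r_iy
hold to machine precision on every decomposition the package computes. The
packaged published path table does not satisfy the second identity with its
own printed values (Σ p_i·r_iy ≈ 0.535 against a printed R² of 0.886 whose
direct/indirect split matches Σ p_i² plus a remainder); the package
implements the standard identity and does not attempt to reverse-engineer
that variant, so cross-checks against the printed table are limited to row
arithmetic (direct², direct + indirect, sqrt(1 − R²)).

## Tolerance index

Per trait, season and genotype, the stress ratio is limited/full of the
genotype means. Traits that increase under stress are inverted to
full/limited so that larger always means more tolerant: for canopy
temperature a tolerant line keeps the trait low under stress, and without
inversion the most tolerant lines would score lowest. By default the
direction is detected from the sign of the pooled regime contrast and
logged; it can be forced per trait. Ratios are min–max rescaled across
genotypes within each trait × season slice (a degenerate slice maps to 0.5
everywhere, logged). Fi is the mean score per season and over all slices
combined; classes are HT (Fi ≥ 0.8), T (≥ 0.6), I (≥ 0.4), S (≥ 0.2),
HS (< 0.2). The 0.8 boundary is assigned to HT so the partition is gapless.
Reported scores are rounded half-up to 3 decimals; classification always
uses unrounded values. The default four-trait panel (GLA, LAI, RWC, CT) is
fully configurable.

## Group validation

Validation consumes the genotype × (trait × season) membership-score matrix.
Clustering uses scipy's agglomerative linkage on Euclidean distances (Ward
default, UPGMA available). PCoA is classical scaling: double-center −D²/2,
eigendecompose, scale eigenvectors by sqrt(eigenvalue); for Euclidean inputs
it equals centered-data PCA, which the tests assert. The Mantel test
correlates upper off-diagonal triangles and permutes the labels of the
second matrix, p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1); the default pairing
compares score distances against cophenetic distances of the dendrogram.
Canonical discriminant functions are the eigenvectors of W⁻¹B (at most
min(groups − 1, traits) functions). Box's M uses the chi-squared
approximation — appropriate for the small group sizes here — and its p-value
below 0.05 switches the equal-prior Gaussian resubstitution classifier from
pooled (LDA) to per-group (QDA) covariances; groups too small for a stable
covariance fall back to the pooled estimate, flagged. With the default
8-column score matrix and 25 genotypes in five classes every group is
smaller than the trait count, so Box's M is undefined and the classifier
reports the pooled-covariance fallback; the 4-column (season-combined)
configuration avoids this when group sizes allow. MANOVA reports Wilks'
Λ = det(W)/det(W + B) with Rao's F approximation, per-trait group means and
unadjusted pairwise t contrasts at alpha = 0.05 (adjustment deliberately
left to the caller, matching how such trials are conventionally reported).

## Synthetic trial generator

The generator exists because no plot-level data accompany the published
trial the package mirrors; it defines the study conditions under which the
estimators are validated. Defaults: 25 genotypes, 2 seasons, 2 regimes, 3
replicates, 28 traits. Per trait, the full-irrigation mean and the
limited-regime offset are calibrated from the published season × regime cell
means; sigma2_g and sigma2_p derive from the published GCV/PCV (so the
implied heritability matches the published GCV/PCV ratio), and the
non-genetic gap sigma2_p − sigma2_g is split evenly between the G×E and
residual phenotypic contributions at r = 3, e = 4, since nothing published
determines that split. Genetic correlations across traits are completed from
trait-to-yield targets by the product rule rho_ij = rho_iy·rho_jy (always
positive semi-definite for |rho| ≤ 1); the five screened traits use
published trait–yield correlations and the rest use moderate values
consistent with the published ordination trend. Season, replicate and
main-plot effects are drawn once per level with standard deviations set as
fractions (0.5, 0.25, 0.25) of each trait's residual sd, so they vanish in
the degenerate zero-variance case. A single seed feeds one master stream;
per-trait substreams are spawned deterministically, making output
byte-identical for identical (design, seed).

Traits are Gaussian. Because the published dispersions give the leaf area
index a stressed-cell coefficient of variation near 45%, an unbounded
Gaussian would produce physically impossible negative values on most seeds;
plot values are therefore clipped at each trait's physical lower bound
(0 for every default trait, disabled by default for custom specs). The clip
affects only far-tail draws of the lowest-mean trait and introduces a small
upward bias in that trait's stressed-cell mean — acceptable for machinery
testing, and irrelevant to the recovery benchmarks, which use unbounded
specs.

What the generator does *not* emulate: skewed or bounded-support trait
distributions, genotype-specific stress-response dimensions beyond random
G×E (so synthetic tolerance classes concentrate near the middle ranks rather
than reproducing the published spread), spatial field trends, missing plots,
and measurement-instrument error structure. Passing tests therefore
demonstrate estimator correctness under the stated model, not robustness to
those departures.

## Problem sizes and numerics

Simulation benchmarks use 200 trials of the default single-trait design
(300 plots each) for variance-component and heritability recovery, 300–500
replicates for permutation/type-I-error calibration with 99 permutations per
test, and 999–9999 permutations for single Mantel runs. Matrix solves use
`numpy.linalg` with explicit condition checks (predictor correlation
matrices with condition number above 1e12 are treated as singular);
eigenvalues are clipped at zero where roundoff produces tiny negatives; the
ANOVA error SS is obtained by subtraction and floored at zero. Ties in
iterative exclusion break alphabetically; component and canonical-function
signs are fixed by the largest-magnitude loading. All stochastic tests are
seeded, and Monte-Carlo tolerances are set at roughly three standard errors
of the quantity under test.

## Known limitations

- ANOVA estimation only: no REML/mixed models, no unbalanced designs, no
  narrow-sense heritability.
- The published genetic-parameter table cannot be reproduced exactly from
  the published mean squares under any single G×E convention; the package
  exposes the conventions rather than resolving the discrepancy.
- The published membership-score table is treated as given (its scores are
  not min–max images of any per-season slice, so the upstream rescaling set
  used by its authors is not recoverable); recomputed tolerance indices
  agree with it to one unit in the third decimal, and all 75 class labels
  match.
- Mantel pairings other than scores-vs-cophenetic, cross-validated
  classification error, stepwise discriminant analysis and non-Euclidean
  dissimilarities are out of scope.
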