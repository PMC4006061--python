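# Methods notes

## Superimposition

Configurations are k × 3 matrices of named landmarks in mm. Centroid size
(CS) is the root summed squared landmark-to-centroid distance; it is the
size variable throughout. GPA centers each configuration, fixes scale at
unit CS (no secondary projection rescaling), and iterates optimal rotations
to the running consensus until the RMS consensus change falls below 1e-10
(maximum 100 iterations; the first specimen seeds the reference). Rotations
come from the SVD of the cross-covariance with the determinant forced to
+1 — reflections are never admitted, because a mirrored match between
anatomical configurations is an artifact. The sign of the smallest singular
direction is the deterministic tie-break for rank-deficient cross-
covariances.

After convergence the whole sample is rotated onto the consensus principal
axes with axis directions fixed by the third moments of the consensus along
its own axes (the two axes with the largest |skewness| point toward positive
skewness; the third sign preserves det = +1). This makes the aligned output
a pure function of the shapes: arbitrary similarity transforms applied to
the inputs change the aligned coordinates by < 1e-8 (observed: ~1e-15).

Tangent coordinates are the orthogonal projection of each flattened aligned
configuration x onto the tangent space at the unit-norm consensus c:
x − (x·c)c. The consensus maps to the origin; the projection annihilates the
scale direction exactly, centering removes the 3 translations, and at the
rotational optimum the 3 rotation directions carry no variance, so the
tangent covariance has rank ≤ 3k − 7 (= 47 for 18 landmarks). Euclidean
tangent distances track full Procrustes distances to well under 1% at the
shape variation magnitudes simulated here.

## Measurement-error ANOVA

The error study design is individuals × scan sessions × digitizations,
fully nested and balanced, s, d ≥ 2. For CS the decomposition is the
ordinary nested ANOVA. For shape, squared deviations of Procrustes
coordinates are pooled over all landmarks and dimensions (isotropic,
Goodall-style), and every design df is multiplied by 3k − 7 = 47. Each
effect's MS is tested against the next-lower stratum with a parametric F.
`percent_explained` is SS_effect / ΣSS × 100, and the total measurement
effect is the sum over the non-individual strata. `ProcrustesAnovaTable.
from_components` rebuilds MS/F/p/percents from an SS and df column alone,
which is how printed error tables can be checked as worked examples.
Individuals are identified by the specimen-id prefix before ":" (the
generator emits `ind007:s2:d1`), or by an explicit `individual_ids` array.

## Shape space

PCA is computed on the covariance (not correlation) of tangent
coordinates — shape coordinates share units, so correlation scaling would
distort the metric. Eigenvector signs follow the largest-|loading|-positive
convention. The dimensionality criterion correlates, for each m, the
Euclidean inter-specimen distances in the first m PCs with the *full
Procrustes* distances (each pair re-superimposed); the retained dimension is
the smallest m with r ≥ 0.98 (threshold-first), and a plateau diagnostic
reports the first m after which r gains less than 0.005 over the next 5
components. Because the reference axis is the full Procrustes distance
rather than the tangent distance, r at the full dimension is 1 only up to
the tangent approximation (≈ 1 − 2e-7 in our simulations); tests assert
1 ± 1e-5.

Thin-plate-spline warps use the 3D biharmonic kernel U(r) = r (the
dimensionally correct fundamental solution; r² log r is the 2D kernel). The
bordered system [[K, P], [Pᵀ, 0]] is solved directly; since ‖x‖ is a
conditionally negative definite kernel, bending energy is defined as
−tr(WᵀKW) ≥ 0, exactly zero when the target is an affine image of the
reference. Grids are three axis-aligned planes through the reference
centroid, 20 × 20 cells, bounding box + 10% margin — figure geometry is a
package convention, since section-plane placement is otherwise arbitrary.

## Group statistics

Size: two-way Type III ANOVA with sum-to-zero contrasts (equals Type I under
balance). Shape: MANOVA/MANCOVA on the retained PC scores. Wilks' Λ per
effect is det(E)/det(E + H) with H the Type III hypothesis cross-product
(L B)ᵀ(L G Lᵀ)⁻¹(L B); the same contrast machinery backs the univariate and
multivariate paths, and statsmodels (anova_lm, MANOVA) serves as an
independent oracle in the tests. Rao's F approximation converts Λ:
df₁ = pq, t = sqrt((p²q² − 4)/(p² + q² − 5)) (t = 1 when pq ≤ 3 or the
denominator is non-positive), df₂ = (ν_e − (p − q + 1)/2)·t − pq/2 + 1,
F = ((1 − Λ^{1/t})/Λ^{1/t})·df₂/df₁ — exact when min(p, q) ≤ 2. Eta squared
is reported as 1 − Λ (multivariate partial form). MANCOVA without
interaction fits per-group intercepts and a common CS slope
(ν_e = n − groups − 1); with interaction, per-group slopes
(ν_e = n − 2·groups).

Pairwise group contrasts are permutation tests: the statistic is the
Procrustes distance between the two group mean shapes (shape) or the
absolute mean difference (size); labels are permuted within the two-group
subsample; p = (b + 1)/(N + 1) with N = 10,000 by default. Percent explained
is the between-group share of total SS on the pair subsample. "Sequential
Bonferroni" is implemented as Holm's step-down, applied across the six
pairs. A Mahalanobis-distance permutation statistic is deliberately not
offered in v1; the Procrustes-distance statistic matches the mean-shape
testing tradition this workflow follows.

Allometry is the multivariate regression of tangent coordinates on CS
(not log CS; a log option exists but is off by default), summarized as
predicted SS / total SS × 100 with a CS-shuffling permutation p. Size
correction removes the pooled *within-group* common slope, evaluated at the
grand-mean CS: Y − b(CS − mean CS). Estimating b within groups keeps group
mean differences out of the slope; correcting to the grand mean preserves
group differences except the part attributable to mean-CS differences along
the allometric vector, and leaves zero CS-predictable pooled within-group
variance.

Discriminant analysis uses a pooled-covariance linear classifier
(scikit-learn) with equal priors by default (the design is nearly balanced;
proportional priors are available), resubstitution and leave-one-out
confusion matrices (each LOO fold refits without the held-out specimen),
and our own one-way Wilks/Rao test of group separation.

## Synthetic data generator

The generator's defaults are the study conditions: four groups × two sexes
with cells 20/20/20/19 (F) and 20/20/19/15 (M); group mean CS 18.58, 17.88,
17.84, 17.51 mm with +0.44 mm for males and SD 1.05 mm; group mean-shape
offsets with Procrustes norms 0 / 0.035 / 0.045 / 0.055 sharing 70% of
their energy along a common severity direction (so mean shapes order along
a severity gradient); an allometric vector of norm 0.016 per mm CS
(≈ 7% of within-group shape variance — weak allometry of the magnitude
typical for molar crowns, where 5–9% shares are the norm); and isotropic
landmark noise of 0.16 mm per coordinate. Offset norms were chosen from the
design algebra so that pairwise percent-explained lands in the 7–18% band
characteristic of group separation in such case-control studies — a
calibration of effect size, since Procrustes-unit effect sizes are not
something one can measure without the raw scans. Each specimen is the unit-CS template plus
offset + allometry + noise, rescaled to its drawn CS, then arbitrarily
rotated and translated; everything is a pure function of (spec, seed).

The error-study generator draws an individual configuration once, adds a
scan-level perturbation per scan session (sd 0.022 mm) and a
digitization-level perturbation per digitization (sd 0.083 mm), each
replicate arbitrarily rotated/translated. These sds were solved from the
expected-SS equations so the designed ANOVA shares are ≈ 83 / 6 / 11% —
the structure of a realistic error study where individual variation
dominates. `designed_error_shares` and `designed_allometric_share` expose
the analytic expectations that parameter-recovery tests compare against.

The template molar is a synthetic 18-landmark fixture (CS normalized to
18.2 mm) respecting crown topology — cusp tips occlusal to pits, pits
occlusal to the gingival margin, contacts at the mesial/distal extremes. It
is a geometric scaffold, not a measured tooth.

What the generator does *not* emulate: landmark-specific noise
heterogeneity, covariance between neighboring landmarks, non-normal size
distributions, outliers, or any biomechanical constraint on deformations.
Passing parameter-recovery tests therefore demonstrates correctness of the
estimators under the isotropic model they assume, not robustness to real
digitization pathologies.

## Problem sizes and numerical choices

Test simulations use the default design (N = 153) or smaller balanced
designs, with permutation counts of 99–299 in unit tests and 10,000 as the
analysis default; calibration checks use 1000 null replicates. Eigenvalues
are counted nonzero above 1e-8 × the leading eigenvalue; GPA tolerance is
1e-10 RMS; TPS landmark residuals are required below 1e-8. Degenerate
inputs (coincident landmarks, coplanar TPS references, constant covariates,
singular pooled covariances, unbalanced replicate designs) raise typed
errors rather than returning silently wrong numbers.

## Known limitations

- Procrustes ANOVA supports only the balanced, fully nested two-level
  replicate design; crossed designs and landmark-wise error attribution are
  out of scope.
- No sliding semilandmarks, missing-landmark estimation, or bilateral
  symmetry decomposition.
- The permutation engine recomputes mean-shape distances in a Python loop;
  at the default 10,000 permutations × 6 pairs this is seconds, not
  milliseconds.
- Tangent-space statistics assume small shape variation; at the simulated
  magnitudes (Procrustes distances ≲ 0.1) the linearization error is far
  below sampling noise, but the package does not check this for user data.
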