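# Methods

This note documents the statistical procedures implemented in
`trussmorph`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data tests do and do not establish about
real data.

## Data model

A specimen is a configuration of 9 ordered 2D landmarks in millimetres
(after per-image scale calibration), digitized with a consistent
left-facing orientation and y-up Cartesian coordinates. Landmarks follow
the whole-body scheme common in truss studies of knifefishes: snout tip
(1), nape (2), dorsal-fin origin (3), posterior end of the vertebral
column (4), ventral point perpendicular to the dorsal-fin origin (5),
anal-fin origin (6), pectoral-fin insertion (7), posterior end of the
maxilla (8), ventral point perpendicular to the maxilla end (9). Groups
are sampling locations (rivers); every group-level statistic requires at
least 2 specimens per group (3 for cross-validated pairwise tests).

## Truss network and size correction

The truss network is the complete set of C(9,2) = 36 pairwise Euclidean
distances, named `i_j` with 1-based i < j. Distance `1_4` is the standard
length (SL). Coincident landmarks produce a zero distance and a logged
warning rather than an error, since downstream transforms will surface
the problem with a precise message.

Size correction uses the Elliott adjustment
M_adj = M · (L_S/L_0)^b with per-variable growth exponent b estimated by
ordinary least squares of log10 M on log10 SL **pooled over all
specimens**. Pooling is the most common reading of the method and
matches the adjustment's own use of a single overall mean length L_S; a
`method="pooled_within"` option (groups centred before the regression)
is provided for sensitivity analysis, since a common within-group slope
is the other defensible choice. SL is removed after adjustment (it is
the covariate, so its adjusted value is the constant L_S), leaving 35
variables. Values are then log10-transformed. The log base is a free
choice: it rescales all variables uniformly and cannot affect
correlations, correlation-matrix PCA, or discriminant results.

Under exact isometry the adjustment is exact: every variable collapses
to its mean-size value with zero residual variance, which is the basis
of the generator-backed recovery tests.

The one-way ANOVA screen (default α = 0.01) and the
specimens-per-variable ratio N/P (recommended stability band 3.5–8) are
**reported, not enforced**: the full 35-variable matrix proceeds to
ordination unless the caller passes `drop_nonsignificant`. Analyses of
this design conventionally keep the full matrix (149 × 35 gives
N/P = 4.26, inside the band) even when quoting the screen.

## Ordination and discrimination

**PCA** is of the correlation matrix (variables standardized), so the
eigenvalues sum to the number of variables and a component's percent
variance is eigenvalue/p — this is fixed, not optional, because the
variance bookkeeping of the reported tables only balances on the
correlation scale. Components retain the Kaiser criterion count
(eigenvalue > 1). Loadings are variable–component correlations
(eigenvectors × √eigenvalue); |loading| > 0.13 is flagged as
significant, again as a report rather than a filter. Eigenvector signs
are fixed so each component's largest-magnitude loading is positive,
making tables reproducible.

**CDFA** solves the generalized symmetric eigenproblem of the
between-group SSCP matrix B against the pooled within-group SSCP matrix
W. With eigenvalues λ_k (at most min(p, g−1) of them):
percent of discriminant variance = λ_k/Σλ; canonical correlation
= √(λ_k/(1+λ_k)); Wilks' Λ for functions k..K = Π_{j≥k} 1/(1+λ_j),
tested by Bartlett's χ² = −(n−1−(p+g)/2)·ln Λ on (p−k+1)(g−k) degrees of
freedom. Coefficients are unstandardized, scaled to unit pooled
within-group variance of the canonical scores. A singular W raises an
instructive error pointing at PCA reduction (DAPC) or variable removal.

**Membership probabilities** are Gaussian posteriors in the canonical
space, where the pooled within-group covariance is the identity by
construction: p(g|x) ∝ π_g exp(−½‖s(x) − c_g‖²). Priors default to
group proportions (the convention of the major commercial packages);
uniform priors are available. Leave-one-out assignment refits the whole
canonical space without the held-out specimen.

**DAPC** feeds the first n_pcs correlation-PCA score columns (default 6,
the dimensionality used in the seven-river study design this package
follows) into the same canonical analysis. Function coefficients are
back-projected to the original standardized variables through the PCA
eigenvectors — the exact composition of the two linear maps, verified by
reconstructing the canonical scores from raw data. With n_pcs equal to
the full rank, DAPC reproduces CDFA exactly.

**ROC/AUC** is one-vs-rest per group, scored by that group's DAPC
membership probability (the score variable is a package choice, recorded
in the run log). The AUC is the Mann–Whitney pair-counting statistic
computed via midranks (ties count ½), tested against brute-force pair
enumeration. Bands: AUC ≥ 0.9 "outstanding", 0.8–0.9 "excellent",
otherwise "lower".

Score densities per group use a Gaussian KDE on a shared grid (25%
padding); a zero-variance group degrades gracefully to a narrow Gaussian
at its value (bandwidth 1% of the grid span).

## Procrustes shape analysis

GPA iterates translation to zero centroid, scaling to unit centroid
size, and least-squares rotation onto the running consensus (optimal
rotation from the SVD of the cross-covariance, determinant-corrected so
**reflections are disallowed** — specimens share one orientation), until
the consensus moves less than 1e-10 or 100 iterations. The reported
consensus is the plain coordinate-wise mean of the aligned shapes.

Shape comparisons use the **full Procrustes distance** between unit-size
preshapes, d = √(1 − cos²ρ) with cos ρ from the reflection-constrained
SVD; the partial (rotation-only) distance √(2 − 2cos ρ) is available via
`kind="partial"`. For the small shape differences typical of
conspecific populations the two agree to first order; the choice is
recorded in the run log.

Procrustes ANOVA: centroid size is tested by one-way ANOVA on log
centroid size; shape by a Goodall-style decomposition of squared
Procrustes residuals with the 2·9−4 = 14 shape dimensions pooled into
the degrees of freedom, F = (SSB/dfB)/(SSW/dfW). The p-value is obtained
by permuting group labels (default 999 permutations, seeded; p =
(1+hits)/(n_perm+1)), so it is exact at its resolution regardless of the
Gaussian assumptions behind the parametric Goodall p (also reported).

Shape PCA operates on residuals projected into the **tangent space** at
the consensus (the two translation, one scaling and one rotation
directions are removed by orthogonal projection), so exactly 14
components can carry variance. Per-group 95% confidence ellipses on any
component pair come from the group score covariance and the χ²(2)
quantile.

Pairwise group mean-shape tests report, per pair: the full Procrustes
distance between mean shapes; the Mahalanobis distance between means in
a discriminant space built on the pair's shape-PCA scores (components
covering ≥ 95% of variance, capped at n₁+n₂−3 so the pooled covariance
stays invertible — the exact internal convention of the standard
morphometrics GUIs is not published, so this choice is explicit and
configurable); a label-permutation p-value of the distance; leave-one-out
CV accuracy of two-group linear discriminant assignment; and the
per-landmark mean-difference ("lollipop") vectors. Because
superimposition re-centres every shape, roughly 1/9 of a single-landmark
offset leaks onto the other eight landmarks — the recovery test accounts
for this.

Signed per-group "distances" along a principal component axis sometimes
quoted in narrative summaries of such analyses are not metric distances;
this package reports true (nonnegative) Procrustes distances and,
separately, per-group mean PC scores.

## Thin-plate splines, relative warps, PSR/WDS, modularity

The 2D TPS uses kernel U(r) = r² log r² and the bordered system
[[K, P], [Pᵀ, 0]]; the bending-energy matrix is the upper-left block of
its inverse — positive semidefinite, annihilating affine targets. Total
bending energy is tr(YᵀBY) for target Y, cross-checked against the
kernel-weight identity tr(WᵀKW). Deformation grids are sampled on a
25×25 lattice over the 10%-padded reference bounding box (presentation
only).

Relative warps are principal components of the tangent residuals,
optionally re-weighted by the consensus bending-energy eigenstructure
with exponent α/2 on the non-affine subspace (|α| ≤ 1; the affine
subspace keeps unit weight). α = 0 reproduces shape PCA exactly; α > 0
emphasizes large-scale, α < 0 small-scale deformation.

The **principal score ratio** (PSR) divides a group's two extreme
warp-deformation magnitudes on a shape component, in the order given —
published summary tables print the pair as "first(second)" and their
ratio, which can fall below 1. When this package computes its own
extremes it uses (|max score|, |min score|) of the group's scores,
ordered largest first; the convention is documented in the output. A
zero minimum yields an infinite PSR with a warning.

The **warp density score** (WDS) has no published definition; the
default here is the per-group sum of bending-energy-weighted specimen
scores on a component (weights = specimen bending energies against the
consensus, normalized to unit mean). The aggregate is pluggable and the
formula in force is recorded in the output metadata; WDS is excluded
from the reference-value checks for exactly this reason.

**Modularity** uses Escoufier's RV between the aligned-coordinate blocks
of a landmark subset and its complement:
RV = tr(S₁₂S₂₁)/√(tr(S₁₁²)·tr(S₂₂²)) ∈ [0, 1]. Presets cover the hump
subset {1, 8, 9} and the fin subset {4, 5, 6}. The observed RV is placed
against all cyclic contiguous partitions of the same size plus seeded
random partitions; the reported proportion of alternatives with RV ≤
observed reads low when the hypothesized split covaries less than
typical splits (i.e., is more modular).

## Synthetic data generator

The generator draws, for each specimen of group g:
a scale factor s = L₀/SL_base with L₀ ~ Uniform(size_range);
coordinates s·(base_shape + offset_g) plus isotropic Gaussian noise per
coordinate. Defaults reproduce the seven-river sampling design: group
sizes 43/16/31/16/13/20/10 (149 specimens), sizes 250–450 mm on a
stylized 9-landmark knifefish outline with a 320 mm standard length,
digitization noise 0.5 mm (about the precision of graph-paper-calibrated
photographs), and group deformations of 1–3 mm concentrated on hump and
fin landmarks — the body regions where river populations of knifefish
actually differ. Allometry is isometric by default (b = 1); b ≠ 1 scales
one designated landmark's position by s^b to create non-isometric
growth. A degenerate size range (L, L) is allowed and produces equal
sizes.

`known_truth` returns the noiseless group mean shapes and their pairwise
full Procrustes distances, independent of the seed, for
parameter-recovery tests.

What the generator emulates: unequal group sizes, additive group mean
deformations, uniform size variation acting multiplicatively on all
distances, independent digitization noise. What it does not emulate:
measurement error correlated across landmarks (camera angle, specimen
bending), non-isometric multi-landmark allometry, within-group shape
heterogeneity beyond isotropic noise, and outliers. Passing recovery
tests therefore establish correctness of the estimators under the
model's assumptions, not robustness of the field protocol.

One deliberate calibration: the assignment-accuracy recovery test
specifies groups "separated by five within-group standard deviations".
Because truss-distance noise is correlated across variables (shared
landmarks) and inflated by the size adjustment, a 5σ displacement in
landmark space realizes only ~2.6–3.6 SD units in the canonical space
where assignment happens. The test therefore measures separation where
it matters: a pilot dataset is generated, the minimum pairwise
group-centroid distance in DAPC's canonical space (pooled within-group
SD units) is measured, and the offsets rescaled so that minimum equals
5 — a deterministic two-pass construction of the stated condition.

## Numerical choices and degenerate inputs

- GPA convergence: consensus change < 1e-10, max 100 iterations
  (typically 3 on study-scale data). Zero-centroid-size configurations
  raise an error naming the specimen.
- Eigen-decompositions use symmetric solvers; tiny negative eigenvalues
  are clipped to zero; component signs are fixed (largest-magnitude
  entry positive) for reproducible tables.
- Permutation tests use `numpy.random.default_rng` with explicit seeds;
  p = (1+hits)/(n_perm+1) never returns 0. The pipeline derives one
  sub-2³¹ seed per stochastic stage from the config seed via
  `SeedSequence.spawn`, recorded in the run log.
- All CSV output uses fixed 6-decimal formatting; a pipeline rerun with
  the same config is byte-identical. Stage caching was considered and
  dropped: the full run takes about a second, so a content hash in the
  run log (for change detection) gives the useful part of caching
  without its failure modes.
- Problem sizes in the test suite follow the study design (149
  specimens, 35 variables); simulation-based checks use 200 replicate
  datasets with 199 permutations each, which resolves a 5% type-I rate
  to ±2% while keeping the suite fast.

## Known limitations

- 2D landmarks only; no sliding semilandmarks, no 3D.
- Only the Elliott size correction and the raw-log mode are offered
  (no Burnaby back-projection or shearing).
- The Mahalanobis dimensionality rule and the ROC score variable are
  package conventions where published analyses leave the convention
  unstated; both are configurable and logged.
- The "mean-score-linked relative warp" summary printed in some
  published tables has no recoverable formula and is not implemented;
  WDS is implemented but behind an explicitly pluggable definition.
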