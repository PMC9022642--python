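# trussmorph

Truss-network and landmark-based geometric morphometrics for phenotypic
stock discrimination in fishes.

Fisheries biologists routinely ask whether fish sampled from different
rivers form distinct *phenotypic stocks* — population units separated by
body-shape differences, whether heritable or plastic. `trussmorph`
implements the full quantitative chain used to answer that question from
2D anatomical landmarks (here a 9-landmark scheme spanning the whole body
of a knifefish, from snout tip to the posterior end of the vertebral
column):

1. **Truss network** — all C(9,2) = 36 inter-landmark Euclidean distances
   `i_j`, an overlapping lattice that samples shape far more evenly than
   traditional length measurements.
2. **Allometric size correction** — each measurement *M* is rescaled to a
   common body size by Elliott's transformation
   *M*<sub>adj</sub> = *M* · (*L*<sub>S</sub>/*L*<sub>0</sub>)<sup>*b*</sup>,
   where *L*<sub>0</sub> is the specimen's standard length (truss variable
   `1_4`), *L*<sub>S</sub> the overall mean standard length, and *b* the
   pooled OLS slope of log₁₀ *M* on log₁₀ *L*<sub>0</sub>. Standard length
   itself is then dropped, leaving 35 analysis variables; values are
   log₁₀-transformed.
3. **Ordination and discrimination** — correlation-matrix PCA with Kaiser
   (eigenvalue > 1) retention; canonical discriminant function analysis
   (CDFA) with eigenvalues λ<sub>k</sub> of the between- vs pooled
   within-group SSCP problem, Wilks' Λ = Π 1/(1+λ<sub>j</sub>) with
   Bartlett χ² tests, and canonical correlations √(λ/(1+λ)); discriminant
   analysis of principal components (DAPC, default 6 PCs) with Gaussian
   membership posteriors; one-vs-rest ROC/AUC grading of group
   discrimination ("outstanding" for AUC ≥ 0.9).
4. **Procrustes shape analysis** — generalized Procrustes superimposition
   (GPA), Goodall-style Procrustes ANOVA with permutation p-values, shape
   PCA, and pairwise group mean-shape tests (Procrustes distance,
   Mahalanobis distance, permutation p, leave-one-out cross-validation,
   per-landmark "lollipop" difference vectors).
5. **Thin-plate-spline warps** — TPS fits with bending energy, relative
   warps, per-group principal score ratios (PSR = ratio of the extreme
   warp-deformation scores) and warp density scores, and Escoufier RV
   modularity between landmark subsets (hump {1,8,9} vs fins {4,5,6}).

A synthetic multi-group landmark generator with exactly known ground
truth (group mean shapes, pairwise Procrustes distances, growth exponent)
makes the whole pipeline testable without any field data.

## Worked example

Run the built-in synthetic seven-river study (149 specimens in groups of
43/16/31/16/13/20/10, 0.5 mm digitization noise, sizes 250–450 mm):

```bash
trussmorph demo --seed 42 --out demo_out --perm 199
```

prints

```
retained PCs (Kaiser): 9
DAPC LOO accuracy: 0.980
AUC Son: 0.9987 (outstanding)
AUC Tons: 1.0000 (outstanding)
...
AUC Gandak: 1.0000 (outstanding)
report bundle written to demo_out
```

Nine principal components of the size-corrected truss matrix have
eigenvalue > 1; DAPC on six of them assigns 98% of specimens to their
river of origin under leave-one-out cross-validation, and every river's
one-vs-rest AUC falls in the 0.90–1.00 "outstanding" band — the
generator's group deformations (1–3 mm on hump and fin landmarks) are
well above its noise floor. `demo_out/` then holds the full report
bundle, e.g. `table2_pca.csv`:

```
,eigenvalue,percent_variance,cumulative_percent
PC1,8.512379,24.321083,24.321083
PC2,5.903994,16.868554,41.189636
PC3,4.823255,13.780727,54.970364
...
```

and `pairwise_shape_tests.csv` with one row per river pair:

```
group1,group2,proc_dist,mahalanobis,p_perm,loo_cv,n_perm,seed
Son,Tons,0.011129,7.574059,0.005000,1.000000,199,233227757
Son,Ken,0.009470,6.185851,0.005000,0.986486,199,233227757
...
```

(a Procrustes distance of 0.011 between the Son and Tons mean shapes, a
Mahalanobis distance of 7.6 in the two-group discriminant space, and the
smallest p-value 199 permutations can produce).

The same analyses run on real data from the command line (`trussmorph
truss|adjust|screen|pca|cdfa|dapc|roc|gpa|proc-anova|pairtests|tps|psr|modularity`)
or from a config file (`trussmorph run --config config.yaml`), reading
landmarks either from TPS digitization files (`LM=`, `IMAGE=`, `ID=`,
`SCALE=` records) or from delimited tables (`id, group, x1, y1, …, x9,
y9, scale`). The library API mirrors the CLI one-to-one
(`trussmorph.truss_distances`, `fit_allometry`, `pca`, `cdfa`, `dapc`,
`gpa`, `relative_warps`, `rv_modularity`, …).

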