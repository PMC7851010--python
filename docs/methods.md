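# Methods

`mitemorph` implements the standard landmark-based geometric-morphometric
inference chain used to compare phenotypic population structure between
species — in the motivating use case, between a phoretic soil mite
(dispersing on bumblebees, expected to be phenotypically homogeneous
across Europe) and a presumed non-phoretic congener (expected to show
population structure from restricted gene flow and neutral, Brownian
drift of trait means). This note records the models, the conventions
chosen where several are in common use, and what the synthetic-data tests
do and do not establish.

## Superimposition

Configurations are k×2 planar landmark sets (k = 13 for the sternal-plate
schema). Size is measured by **centroid size** (root summed squared
landmark distances from the centroid), computed in digitized units;
`SCALE=` records are stored but not applied by default because every
downstream statistic is either scale-free (shape) or invariant to a common
unit change (correlations, % variance).

Generalized Procrustes analysis uses the **full Procrustes fit**: each
configuration is centered and scaled to unit centroid size, then rotated
*and* rescaled (by cos ρ) onto the working consensus; the consensus is the
arithmetic mean rescaled to unit size, iterated until its RMS change is
below 1e-10 (max 100 iterations — overtight is cheap at n ≤ a few
hundred). Reflections are never allowed in the fit. The final consensus is
rotated onto its principal axes with a deterministic sign rule, so the
output orientation does not depend on the input orientation; all
statistics downstream are rotation-invariant anyway. These are the default
conventions of the mainstream morphometrics programs, chosen so results
are comparable with analyses run there.

Shape variables are the aligned coordinates orthogonally projected onto
the tangent space at the consensus (`x ↦ x + (1 − x·c)c` with ‖c‖ = 1);
projection is a first-order identity for small variation and leaves
2k − 4 effective dimensions. Raw Procrustes coordinates are available via
`shape_variables(tangent=False)` for sensitivity checks.

**Procrustes distance** defaults to the full form sin ρ =
√(1 − cos²ρ); the partial form √(2 − 2 cos ρ) is available
(`kind="partial"`), since programs differ in which one they print for
group means. Note the analytic formula bottoms out near √ε ≈ 1e-8 for
identical shapes; tests treat anything below 1e-7 as zero.

## Allometry

Allometry is quantified by ordinary least squares of all shape variables
on centroid size jointly (one shared predictor; raw size by default,
log-size optional). The reported statistic is
100 · SS(predicted, centered)/SS(total, centered). "Size-free" shape is
the residual matrix re-centered on the mean shape; removal is idempotent
and the residuals are exactly uncorrelated with size. Regressions are
pooled over whatever specimen set the analysis at hand uses: joint
analyses pool species (so the inter-species size/shape contrast dominates,
giving a large % predicted), separate analyses regress within species
(small %, a few points). Under the null, the statistic has the usual
single-predictor R² bias of ≈ 100/(n−1) percent.

## Canonical variates analysis and distances

CVA solves the between- vs pooled-within-group eigenproblem after
projecting onto the within-covariance eigenspace with eigenvalues above
1e-9 of the largest (rank reduction before inversion; with 22 shape
dimensions and typical error degrees of freedom the reduction is a no-op
on real-sized data, but it keeps small synthetic cases defined). Scores
are scaled to unit pooled within-group variance per axis; axes are
sign-fixed by making the first group's mean score non-positive, because
canonical axes are otherwise sign-indeterminate (|r| is the reportable
CV1–size correlation). Mahalanobis distances are Euclidean distances of
group means in the whitened metric and are invariant to any invertible
affine map of the variables within the within-covariance row space.

Pairwise significance uses the two-group permutation convention: only the
specimens of the pair under comparison are reallocated (default 10,000
permutations), the pair's own pooled covariance is refit per permutation
(rank-reduced, after an exact orthogonal reduction onto the pair's
observed span for speed), and p = (#{perm ≥ obs} + 1)/(n_perm + 1).
Procrustes distances between group mean shapes are tested with the same
relabelings. Distance-matrix summaries are the mean of the upper
triangle; species are compared by a pooled-variance two-sample t-test on
their pairwise-distance sets (Welch optional).

Classification power is **deterministic leave-one-out**: for each
specimen, group means *and* the pooled within-covariance are refit
without it and the specimen is assigned to the nearest group mean in the
whitened metric. (Keeping the full-data covariance is an option for
sensitivity.) Under random labels LOO sits near chance 100/g %, with the
usual mild jackknife bias; at large divergence it approaches 100%.

Specimens from singleton populations never enter any statistic: the core
GPA is fit without them, they are then aligned to the fitted consensus by
ordinary Procrustes, tangent-projected, and passively projected through
the fitted canonical axes for plotting only. Dropping them from the input
therefore changes no statistical table, which is tested.

## Dispersion, geography, Mantel

The homogeneity-of-dispersion test follows the distance-based `betadisper`
+ `permutest` workflow: principal-coordinate embedding of the pairwise
Euclidean distances among shape variables, per-group **spatial median**
(geometric median by Weiszfeld iteration; negative-eigenvalue axes follow
the standard sign-split rule, though Euclidean inputs produce none),
one-way ANOVA F on member-to-median distances, and a permutation p from
group relabelings (default 999). The spatial median (not the centroid) is
used deliberately — the dispersion being tested is "average distance of
specimens to the median". The implementation's F agrees with vegan's
`betadisper` to ~1e-3 relative (the residual difference is the two
optimizers' median tolerance), which is verified in a test. Pairwise
group comparisons are reported raw, without multiplicity correction.

Geographic distances are haversine great-circle distances (Earth radius
6371 km) from decimal-degree coordinates — a programmatic replacement for
map-based measurement, agreeing with typical map readings to a few
percent. The Mantel test correlates upper triangles (Pearson), permutes
rows and columns of one matrix simultaneously (default 9,999), one-tailed
for positive association by default; an exhaustive enumerator exists for
small g and anchors the tests.

## Synthetic studies

The generator emulates the study design the pipeline expects:

| parameter | default | meaning |
|---|---|---|
| `n_per_population` | (10,10,9,9,6), (13,12,9,4) | specimens per population, per species |
| `singletons_per_species` | (0, 3) | extra single-specimen populations (passive-only) |
| `species_shape_offset` | 0.06 | Procrustes distance between species mean shapes |
| `divergence_sd` | 0.0015, 0.005 | per-coordinate SD of the Brownian endpoint perturbation of population means |
| `landmark_noise_sd` | 0.005 | isotropic digitization + individual noise (shape units) |
| `allometry_strength` | 0.03, 0.03 | fraction of within-species shape variance coupled to size |
| `size_mean_by_species` | 250, 170 | mean centroid size (µm scale) |
| `size_cv` | 0.05 | lognormal size coefficient of variation |

Population divergence is modeled as the *endpoint* of a Brownian random
walk — a single isotropic Gaussian perturbation of the species mean —
because populations are exchangeable absent a stated phylogeny; expected
squared shape distance between population means then grows linearly in
`divergence_sd²`, which is tested. The allometric component is a fixed
unit shape direction scaled so that it contributes the configured
fraction of within-species variance given the noise and divergence
levels and the realized size spread. Defaults were fixed once by forward
calculation from the study conditions being emulated: inter-population
mean Procrustes distances near 0.02, within-species allometry of ~3%, a
species contrast large enough that the joint size regression captures
roughly half the total variance, and a more divergent second species (the
restricted-dispersal scenario). Sizes are lognormal to stay positive.
Specimens are emitted in shuffled order under random rotations and
translations so superimposition is genuinely exercised.

What the synthetic model deliberately lacks: landmark-specific covariance
(digitization error is isotropic), phylogenetic structure among
populations, measurement-device trends, and any non-linear allometry.
Passing tests on this model therefore demonstrate correctness of the
*inference machinery* and recoverability of known effects — not that real
mite data satisfy the model.

## Problem sizes and numerical choices

The test suite runs everything at the default study scale (85 specimens,
13 landmarks) or smaller; permutation counts in tests are 99–999, the
type-I-error calibration uses 400 null datasets of 2 × 25 specimens at
199 permutations each, and parameter-recovery sweeps use 20 replicates
per divergence level — sizes chosen so the whole suite completes in a few
minutes while keeping Monte-Carlo error well inside the asserted bands.
The acceptance script runs the full pipeline at the publication-style
permutation counts (10,000 pairwise / 999 dispersion / 9,999 Mantel).

Ties and degenerate cases: rank-0 within-covariance, constant sizes,
collinear TPS sources, all-coincident landmarks, and dimension mismatches
raise typed errors; GPA non-convergence sets a flag rather than raising;
groups of one are dropped from dispersion tests with their labels
recorded. The Weiszfeld iteration guards against iterates landing on data
points by flooring distances at 1e-12.

## Reproducing the published statistics

The reproduction-class checks (Table-2 distance means, allometric
percentages, |r| of CV1 vs size, LOO percentages) require the original
digitized landmark coordinates, which are distributed as the study's
online supplementary spreadsheet and are not redistributable here. Place
them, converted to tps text, at `data/supplementary_landmarks.tps` with a
`data/supplementary_mapping.csv` label table, and the tests in
`tests/test_acceptance.py::TestReferenceReproduction` will run the full
pipeline on them; without the file those tests fail with an explicit
message. Everything else in the acceptance layer is synthetic and
self-contained.
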