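# mitemorph

Landmark-based geometric morphometrics for testing **phenotypic population
structure**, built for the classic two-species contrast in soil-mite
biology: a phoretic species (dispersing across Europe on bumblebee hosts,
hence well-mixed and phenotypically homogeneous) versus a presumed
non-phoretic species (restricted gene flow, population means drifting
apart by neutral Brownian motion). The package takes digitized 2-D
landmark configurations — e.g. 13 landmarks on the mite sternal plate in
tpsDig `.tps` format — and runs the full inference chain:

1. **Generalized Procrustes analysis** (full-Procrustes fit, no
   reflections) with tangent-space projection;
2. **allometry**: multivariate regression of shape on centroid size,
   reporting the % of shape variance predicted and producing size-free
   residual shape;
3. **canonical variates analysis** over a-priori populations, with
   **Mahalanobis** (`D_ij = ‖(x̄_i − x̄_j)ᵀ W^{−1/2}‖`, W the pooled
   within-group covariance) and **Procrustes** distance matrices and
   pairwise permutation tests;
4. **leave-one-out cross-validated classification** to the nearest group
   mean in the Mahalanobis metric;
5. **multivariate dispersion tests** (distance-to-spatial-median, the
   vegan `betadisper`/`permutest` procedure) and **Mantel tests** of shape
   distance against haversine great-circle geography;
6. **thin-plate-spline transformation grids** and CV1×CV2 scatter plots.

A first-class synthetic-study generator reproduces the assumed data
structure (two species, multiple populations, Brownian divergence of
population means, isotropic landmark noise, weak allometry, lognormal
centroid sizes), so the whole pipeline is testable without any specimen
data. See `docs/methods.md` for models, conventions and defaults.

## Worked example

Simulate a study and analyze it from the shell:

```sh
mitemorph simulate --seed 1 --out study/
mitemorph analyze --tps study/synthetic_study.tps \
    --mapping study/specimen_mapping.csv \
    --latlon study/population_latlon.csv \
    --out study_report/ --seed 1
```

or from Python:

```python
from mitemorph import (AnalysisConfig, SyntheticStudyConfig,
                       run_full_analysis, simulate_specimens)

dataset = simulate_specimens(SyntheticStudyConfig(seed=1))   # 85 specimens
fast = AnalysisConfig(n_perm_pairwise=99, n_perm_dispersion=99,
                      n_perm_mantel=99, seed=1)              # perms only affect p-values
report = run_full_analysis(dataset, config=fast)
block = report.blocks[("joint", "with")]                     # joint CVA, allometry kept
for sp, st in block.species.items():
    print(sp, round(st.mean_mahalanobis, 3), round(st.loo.pct_correct_overall, 1))
print("allometry %:", round(block.allometry_pct_joint, 1),
      " CV1~size r:", round(block.cv1_size_r, 2))
```

which prints (seed 1):

```
speciesA 3.998 50.0
speciesB 8.744 100.0
allometry %: 48.5  CV1~size r: -0.94
```

Read: populations of `speciesB` — generated with the larger
between-population Brownian divergence, the restricted-dispersal scenario
— sit further apart (mean pairwise Mahalanobis distance 8.74 vs 4.00) and
their specimens are assigned to the correct population far more reliably
(100% vs 50% leave-one-out), while the joint size regression captures
48.5% of shape variance and CV1 is strongly size-correlated (r = −0.94),
reflecting the built-in inter-species size/shape contrast. The report
bundle written by `analyze` contains the distance-mean table, the
combined-triangle pairwise distance tables (Mahalanobis above the
diagonal, starred at permutation p < 0.01; Procrustes below), confusion
matrices, dispersion and Mantel results, CVA scatter plots with passively
projected singleton specimens, and CV1 deformation grids.

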