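# asymtopo

Topological analysis of left–right volumetric brain asymmetries.

Voxel-based asymmetry studies compare hemispheres one voxel at a time;
`asymtopo` instead treats spatially coherent asymmetric structures as
the unit of analysis.  Given log-scaled Jacobian-determinant volumes
(deformation maps to a symmetric template), it builds the standard
asymmetry image

    A = smooth(J) − flip(smooth(J)),

whose negative values (read on the left-hemisphere grid) are rightward
and positive values leftward asymmetries, and then applies cubical
persistent homology to the sublevel-set filtration of `A`:

* **0-cycles** — connected components, born at local minima — are
  rightward asymmetric structures;
* **2-cycles** — cavities, dying at local maxima — are leftward
  asymmetric structures.

Each structure is a persistence pair (birth, death) whose lifespan is
the range of asymmetry values it spans.  Pairs are assigned to
left-hemisphere regions of interest (0-cycles by their birth voxel, with
birth < 0; 2-cycles by their peak voxel), summarized as persistence
landscapes over 15 fixed positions spanning the asymmetry-value range
(level-k value at position t: the k-th largest of
`max(0, min(t − b, d − t))`), and analyzed with permutation statistics:
Freedman–Lane permutation regressions of landscape density on
covariates, and one-sample signed-rank tests of the per-participant
0-cycle − 2-cycle density difference.

A synthetic-cohort generator with planted Gaussian asymmetries,
covariate-dependent amplitudes and known ground truth makes the whole
pipeline testable end to end without any imaging data.  See
`docs/methods.md` for conventions, parameters and limitations.

## Worked example

A 50-child synthetic cohort with one rightward superior-temporal-like
blob whose amplitude is larger in males:

```python
import numpy as np
from asymtopo import *
from asymtopo.synthetic import RoiSpec
from asymtopo.stats import build_covariate_matrix

config = SimulationConfig(
    shape=(24, 24, 24), voxel_size_mm=2.0,
    blobs=[BlobSpec(center=(17, 8, 8), sigma_mm=4.0, amplitude=0.3,
                    side="right", covariate_dependent=True)],
    noise_sd=0.05, beta_sex=0.15, seed=7,
)
cohort = generate_cohort(50, seed=7)
(roi,) = generate_roi_masks(config, [RoiSpec("sts", (6, 8, 8), 3.0)])

asyms = [compute_asymmetry(generate_jacobian_image(row, config), fwhm_mm=6.0)
         for _, row in cohort.iterrows()]
grid = global_value_range(asyms)
dens0, diffs = [], []
for asym, (_, row) in zip(asyms, cohort.iterrows()):
    diagram = assign_pairs(compute_persistence(asym), roi)
    l0 = make_landscape(diagram.of_dim(0), grid, aggregate="sum-of-levels")
    l2 = make_landscape(diagram.of_dim(2), grid, aggregate="sum-of-levels")
    dens0.append(l0.values)
    diffs.append(density_difference(l0, l2))

summary = density_difference_summary(np.array(diffs), n_perm=999, seed=1,
                                     roi_label="sts")
print(f"0-cycle vs 2-cycle density: mean diff = {summary.mean:.3f}, "
      f"p = {summary.p_value:.3g}, percent positive = {summary.percent_positive:.0f}%")

dens0 = np.stack(dens0)
pos = int(np.argmax(dens0.mean(axis=0)))
res = perm_lm(dens0[:, pos],
              build_covariate_matrix(cohort, ["sex"])[:, 0],
              build_covariate_matrix(cohort, ["age", "site"]),
              n_perm=999, seed=1, predictor_name="sex")
print(f"sex effect at landscape position {pos + 1}: t = {res.t_statistic:.2f}, "
      f"p = {res.p_permutation:.3g}, d = {res.cohens_d:.2f}, r = {res.r_equivalent:.2f}")
```

Output:

```
0-cycle vs 2-cycle density: mean diff = 0.055, p = 0.001, percent positive = 86%
sex effect at landscape position 8: t = 10.35, p = 0.001, d = 3.36, r = 0.86
```

The planted rightward structure makes the 0-cycle landscape denser than
the 2-cycle landscape for 86% of participants (signed-rank p = 0.001,
the smallest value attainable with 999 permutations), and the planted
male > female amplitude difference is detected by the permutation
regression of 0-cycle density at the position of the well depth, with
age and research site as covariates.

## Command line

The same stages are exposed as a CLI for file-based workflows:

```sh
asymtopo simulate --config sim.yaml --out-dir data/
asymtopo asymmetry --input data/sub-0000_jacobian.nii --output asym.nii --fwhm-mm 8
asymtopo ph --input asym.nii --output diagram.csv
asymtopo run --config pipeline.yaml      # full pipeline, all CSV outputs
```

`run` writes per-participant asymmetry volumes and diagram CSVs, the
landscape matrix, regression and density-difference tables, and a JSON
manifest with a config hash; reruns with the same config and seed are
bit-identical.

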