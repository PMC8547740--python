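# Methods

`asymtopo` characterizes left–right volumetric brain asymmetries
topologically instead of voxel-by-voxel.  This note records the model,
the conventions and numerical choices, what the synthetic generator does
and does not emulate, and known limitations.

## The asymmetry image

Input volumes are log-scaled Jacobian-determinant maps from a nonlinear
registration to a *symmetric* template: the value at a voxel is the log
of the local volumetric expansion needed to warp that participant's
anatomy to the template.  The standard asymmetry image is

    A = S(J) − flip(S(J)),

where `S` is Gaussian smoothing (FWHM in mm, default 8; sigma =
FWHM / (2√(2 ln 2)) voxels per axis) and `flip` reverses the left–right
axis.  Because `J` is log-scaled, the subtraction is a ratio-type
asymmetry index.  Read on the left-hemisphere grid, positive values are
leftward and negative values rightward asymmetries.

Conventions chosen here (the upstream literature does not fix them):

* **Midline between voxels.**  The left–right axis must have even
  length, so `flip` is an involution without a fixed voxel and
  `A(x) = −A(flip x)` holds exactly (to float rounding), which the test
  suite asserts at 1e−10.
* **Reflect padding for smoothing.**  Symmetric boundary padding keeps
  smoothing exactly equivariant under the flip, so the antisymmetry is
  not perturbed at the volume edges.
* The log-scaling itself happens upstream (in the registration tool);
  the functions here document but cannot verify it.

## Cubical persistent homology

The sublevel-set filtration raises a threshold `t` through `A`; voxels
with value ≤ t form a nested family of cubical complexes.  Two feature
classes are tracked:

* **0-cycles** (connected components) are born at local minima — each is
  a spatially coherent *rightward* structure, its birth value the
  deepest contrast it attains.  When two components meet, the younger
  dies (elder rule) at the merging voxel's value.
* **2-cycles** (cavities) capture *leftward* structures: a hyper-intense
  region becomes a cavity once the surrounding sublevel set encloses it,
  and dies at its interior maximum (the peak voxel).

1-cycles (loops) are not computed; the analysis never uses them.

Implementation choices:

* **Connectivity.**  0-cycles use 6-connectivity; 2-cycles are computed
  by duality on the negated image with 26-connectivity.  Complementary
  connectivities are the consistent digital-topology pairing; a single
  convention for both would create paradoxical adjacency at corners.
* **Boundary.**  For cavities the image exterior counts as the
  surrounding void: the dual union-find runs on the negated image padded
  by one layer introduced after all real voxels, and the dual essential
  component (the outside) is discarded.  A hyper-intense region touching
  the image border is therefore never a cavity.
* **Ties** are broken by ascending row-major voxel index everywhere, so
  diagrams are deterministic.  On images with exactly equal values
  (plateaus) the union-find can emit zero-lifespan pairs; they are
  retained and flagged but contribute nothing to landscapes, and
  comparisons against the oracle drop them because which diagonal pairs
  appear depends only on the tie-break.
* **Essential class.**  The one component that never dies is paired with
  the global maximum (min–max pairing) and flagged, rather than given an
  infinite death; landscapes need finite deaths, and the flag preserves
  the information.
* **Oracle.**  `oracle_diagram` recomputes diagrams by exhaustive
  threshold sweep with direct component/cavity labeling
  (`scipy.ndimage.label`), tracking births, merges, splits and fills
  explicitly.  It shares no code path with the union-find and is the
  correctness reference on grids up to 12³ voxels; the acceptance suite
  checks multiset equality on 100 random integer grids and
  diagram/Betti-number consistency at random thresholds.

## ROI assignment

Structures can extend beyond a region of interest, so membership uses
critical voxels, asymmetrically by design: a 0-cycle belongs to an ROI
only if its *birth* voxel is inside and its birth value is negative
(guaranteeing a genuinely rightward structure); a 2-cycle belongs if its
*death* (peak) voxel is inside.  The mirrored condition for 2-cycles —
requiring a positive death value — is exposed as
`require_positive_death` but off by default, following the asymmetric
phrasing of the rule this reimplements; with the flag on, negating an
image exactly exchanges the ROI-restricted 0- and 2-cycle diagrams,
which the tests exploit.  Essential pairs are filtered like any others.
Masks must be binary and entirely within the left hemisphere half.

## Persistence landscapes

Each pair (b, d) contributes a tent function
`max(0, min(t − b, d − t))`; the level-k landscape at `t` is the k-th
largest tent value.  Landscapes are evaluated at 15 evenly spaced
positions spanning the asymmetry-value range, indexed 1..15 in all
outputs.  Two operationalizations of "density at a position" are
provided:

* `single-level` (k = 1): the most persistent structure covering `t`;
  insensitive to multiplicity.
* `sum-of-levels` (default for cohort analyses): the total tent mass,
  equal to the sum over all levels; doubles when a structure is
  duplicated, hence a true density reading.

The position grid is **cohort-global** (min/max over all images) by
default so that a given position means the same contrast value for
every participant — regressions at "position 6" are meaningless
otherwise.  A per-study override exists.  Discretizing to 15 positions
loses at most the position spacing of resolution (the exact landscape
is 1-Lipschitz in `t`).

The per-participant, per-ROI **density difference** is the mean over the
15 positions of (0-cycle landscape − 2-cycle landscape): positive means
rightward structures are denser than leftward ones.

## Statistics

* **Permutation regression** (`perm_lm`).  OLS gives the coefficient,
  t-statistic and residual df; the p-value for the predictor of
  interest comes from Freedman–Lane residual permutation: residuals of
  the reduced (covariates-only) model are permuted, added back to the
  reduced fit, and the full model refitted; p = (1 + #{|t*| ≥ |t|}) /
  (1 + n_perm).  A fixed permutation count (default 4999) with an
  explicit seed replaces sequential stopping rules so every p-value is
  reproducible.  Research site enters as dummy covariates; sex is coded
  as a male indicator (male = 1).  The acceptance suite verifies type-I
  calibration (rejection rate at α = 0.05 within 3 binomial SDs over
  1000 null simulations) and agreement of t with the classical
  two-sample statistic.
* **Density-difference test.**  One-sample Wilcoxon signed-rank of the
  per-participant differences against zero, with exact sign-flip
  enumeration for n ≤ 12 and Monte-Carlo sign-flips otherwise; a
  one-sample t-test is available via `test='t'`.  The summary also
  reports the percentage of participants with a positive difference.
* **Effect sizes.**  r = t/√(t² + df); Cohen's d = 2|t|/√df (reported
  unsigned).  The d conversion is a documented convention, not an
  assertion about any particular dataset: it reproduces published-scale
  values only under the df of the regression at hand.
* **Comparing correlations.**  Fisher-z test with the regression df in
  place of n − 3: z = (atanh r₁ − atanh r₂)/√(1/(df₁−1) + 1/(df₂−1)).
* Raw per-position p-values are reported by default (15 positions × ROIs
  × predictors); Benjamini–Hochberg adjustment is available behind a
  flag but off by default, matching how such permutation p-values are
  conventionally reported in this literature.

## Synthetic cohorts

The generator provides ground truth for every downstream stage:

    J = symmetric baseline + Σ blob Gaussians + voxel noise.

* The **baseline** is a smooth random field symmetrized by averaging
  with its own flip, identical across participants; it cancels exactly
  in the asymmetry image, so every downstream structure traces to a
  planted blob or to noise.
* **Blobs** are Gaussians with voxel center, spatial scale in mm, and a
  signed amplitude in log-Jacobian contrast units.  Per participant the
  amplitude is `amplitude + β_sex z_sex + β_age z_age` (for blobs
  flagged covariate-dependent; z-scores against the cohort marginals)
  plus an individual N(0, amplitude_sd) deviation.  The default
  `amplitude_sd = 0.1` matters: without between-participant anatomical
  variability a planted covariate effect is nearly deterministic and
  effect sizes are absurd; with it, planted effects have realistic
  small-to-moderate standardized magnitudes.
* **Noise** is i.i.d. Gaussian per voxel (default SD 0.02), added
  before the downstream smoothing, mimicking acquisition noise.
* **Covariates** emulate a multi-site pediatric cohort: ages uniform on
  6.39–16.92 years (the simplest distribution consistent with a known
  range), 39% female, 10 sites, VIQ ~ N(113, 14.1), and a total brain
  volume drawn independently of the planted asymmetries — so covarying
  for it must not remove a planted sex effect, which is tested.
* **Grids** default to 24³ voxels at 2 mm.  Analyses on full-resolution
  brain grids are supported by the same code; the default keeps
  simulated cohorts cheap enough for routine, repeated validation runs.
* Reproducibility: the cohort table is a function of (n, seed); each
  volume is a function of (config seed, participant id).

What the generator does **not** emulate: registration artifacts and
spatially correlated residuals; site differences beyond random
assignment (no per-site intensity shifts by default); missing covariates
(VIQ is complete; the covariate reader rejects incomplete tables);
non-Gaussian shapes of real anatomical asymmetries.  Passing tests show
the pipeline recovers known planted structure under these idealized
conditions — they do not certify performance on real cohort data.

## Headline validation conditions

The planted-effect recovery runs use n = 50 participants, three
rightward blobs (amplitudes 0.22–0.30, scale 4 mm) mirrored by three
spherical left-hemisphere ROIs, noise SD 0.05, smoothing FWHM 6 mm, and
β_sex = 0.15 on one blob.  With `amplitude_sd = 0.1` that standardized
planted effect is large enough for essentially full single-run detection
power at n = 50 while remaining in a non-degenerate effect-size range;
statistical validity under the null is established separately by the
1000-simulation calibration check rather than by the planted-effect run.

## Known limitations

* Pair-level agreement with any particular external persistence toolkit
  is not claimed: plateau handling and the essential-pair convention
  differ between implementations.  Agreement is with the in-package
  exhaustive oracle, plus the duality and Betti invariants.
* The union-find is pure Python over numpy neighbor tables; it is
  comfortable at simulation scales (≈14k voxels per volume, ~0.15 s) but
  full-resolution 1 mm brain grids will be slow in the permutation-heavy
  pipeline.
* Only 3D sublevel filtrations of scalar images, dims 0 and 2; no
  general cubical complexes, no dim-1 persistence, no landscape
  distances or alternative vectorizations.
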