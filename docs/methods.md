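# Methods

## The question the package addresses

Orientation of a visual grating can be decoded from human V1 with fMRI at
conventional resolution (2–3 mm voxels at 3 T), but it is contested at
which spatial scale the underlying neuronal selectivity lives.  Two
accounts compete:

1. **Global areal maps.**  V1 responds slightly more to radial and to
   vertical orientations.  These coarse, smoothly varying preference maps
   alone could drive decoding.
2. **Fine-grained patterns.**  Sub-millimetre orientation columns,
   irregularly sampled by voxels, leave a reliable voxel-scale salt-and-
   pepper pattern that carries additional information.

The discriminating observable is the **voxel gain field**: voxels differ
in sensitivity to local neural activity (partial-volume effects, vein
proximity), but a gain is strictly positive, so it can rescale a
between-condition response contrast — never invert its sign.  Under the
coarse-only account every voxel inside a small quarterfield patch shares
the sign of the coarse contrast; voxels that *reliably* prefer the
opposite orientation are therefore evidence of fine-grained information.
The pipeline operationalizes "reliably" in two ways: split-set decoding
(train a classifier only on voxels labeled with the minority preference,
where the labels come from independent training data) and a
preference-replicability index (below).

## Simulator

### Geometry

Stimuli live on an annulus (inner radius 1.5°, outer 7.04° of visual
angle) tiled log-polarly (12 wedges × 3 rings at geometrically spaced
radii 1.50°, 2.51°, 4.20°, 7.04°).  Two stimulus families, each with two
exemplars orthogonal everywhere:

* **Gratings** at ±45° from vertical (uniform orientation fields,
  balanced about vertical, so a vertical bias cannot distinguish them);
* **Logarithmic spirals** whose edges keep a constant ±45° angle to the
  radius (balanced about radial, so a radial bias cannot distinguish
  them).  The local spiral orientation at polar angle φ is (φ ± 45°) mod
  180°.

Four ROI patches cover the central third (30°) of each quarterfield's
polar range, centered at 45/135/225/315° clockwise from vertical; each is
subdivided into three eccentricity bands at log-equal radii — the flat
stand-in for bands of roughly equal cortical surface under logarithmic
cortical magnification.  On the diagonal patch centers each grating is
exactly radial or tangential and each spiral exactly vertical or
horizontal, which fixes the patch-relative condition labels.  The paper
trail of spiral handedness is anchored to one recoverable fact — in the
upper-right quarterfield the anticlockwise spiral is locally vertical —
rather than to image chirality, which the variant names deliberately do
not encode.

### Neural model

Each patch is a flat square cortical sheet of orientation columns
(default 64 × 64 columns at 0.25 mm pitch = 16 × 16 mm).  A pinwheel-like
preference map is synthesized as half the argument of a band-pass
filtered complex Gaussian field (Gaussian annular filter centered at
spatial frequency 1/`columnar_period`, bandwidth one third of that, DC
removed).  This makes the marginal preference distribution exactly
uniform on [0°, 180°) and concentrates the power of the double-angle
field near the requested period.  Column responses follow a double-angle
cosine with all terms inside one bracket so amplitudes read directly in
%-signal-change:

    R(x) = B · [1 + a_col·cos 2(θ_pref(x) − θ_stim(x))
                  + a_rad·cos 2(θ_stim(x) − θ_radial(x))
                  + a_vert·cos 2 θ_stim(x)]

Voxels are square 2-mm footprints tiling the sheet; each voxel's
amplitude is its footprint mean times a strictly positive log-normal
gain.  Per-subrun patterns are the amplitudes plus i.i.d. Gaussian noise
(pattern mode) or, in timeseries mode, come from a full block-design BOLD
synthesis pushed through the GLM module.

### Parameters, units, defaults

| parameter | unit | default | rationale |
|---|---|---|---|
| `baseline` (B) | %SC | 2.0 | published mean patch responses ≈ 2.0–2.2 %SC |
| `a_rad` | fraction of B | 0.01 | gives a mean radial−tangential contrast 2·B·a_rad = 0.04 %SC, the published order (≈0.038) |
| `a_vert` | fraction of B | 0.008 | vertical−horizontal contrast 0.032 %SC (published ≈0.031) |
| `a_col` | fraction of B | 0.6 | columnar tuning is strong at the neural scale; after 2-mm voxel averaging of 0.8-mm columns it leaves a voxel-scale contrast SD ≈ 0.17 %SC |
| `columnar_period` | mm | 0.8 | V1 orientation-column periodicity, well below voxel width |
| `column_pitch` | mm | 0.25 | 8× oversampling of the voxel; keeps the map resolvable (period > 2·pitch) |
| `sigma_log` (gain) | log-units | 0.4 | substantial voxel-to-voxel sensitivity spread; i.i.d. (smoothness 0) is the worst case for spurious high-frequency structure |
| `sigma_pattern` | pattern units | 0.5 | per-voxel per-subrun noise SD |
| `sigma_subject` | relative | 0.2 | multiplicative between-subject jitter on the three amplitudes |
| `n_subjects` | – | 18 | the study's sample size |

`a_col` and `sigma_pattern` are the only genuinely free magnitudes; they
were fixed once by a coarse grid search so that the default **mixed**
scenario lands in the published effect-size regime (all-voxel accuracy in
the 70–90% range with the minority-set accuracy ≈ 10–25 points lower,
minority replicability positive but several-fold smaller than the
majority's, measured preference proportions a few points above 50%).  No
single setting reproduces every published value simultaneously — see
Limitations — and the chosen point errs toward a robustly positive
minority-set effect, since that dissociation is what the pipeline exists
to exhibit.

### Scenarios

* `coarse_only` (a_col = 0): the gain-field world.  Noise-free, every
  voxel's contrast keeps the coarse sign (assertable exhaustively); with
  noise, minority-labeled voxels are pure selection artifacts.
* `fine_only` (a_rad = a_vert = 0): symmetric world, preference
  proportions are 50% in expectation.
* `mixed`: both components, the realistic case.

Seeding is hierarchical (master → subject → run streams via
`numpy.random.SeedSequence.spawn`), so identical scenarios are
bit-reproducible and adding subjects never perturbs existing ones.

## GLM

One scanner run is four subruns of six 14-s blocks (three per condition,
conditions alternating, the leading condition alternating across
subruns; 6 s rest after each block; TR 2 s; 240 volumes).  The design
matrix has one HRF-convolved boxcar per (condition, subrun) — eight task
columns — plus optional Legendre drift columns and an intercept.  The HRF
is the gamma kernel h(t) ∝ ((t−δ)/τ)^{n−1} e^{−(t−δ)/τ} with n = 3,
τ = 1.25 s, δ = 0 (the simplest published parameterization; configurable),
rescaled to unit sum.  Ordinary least squares gives t = β̂/SE(β̂) with
residual dof = volumes − rank(X); the per-subrun, per-condition *t-value
pattern* is the currency of everything downstream.  t against baseline
(not a contrast t) is used, matching the per-predictor reading; the
contrast reading is available in the replicability module as the
`tstat` switch.  Near-zero residual variance (relative tolerance 1e−20
of the data scale) flags the t-values as undefined rather than returning
huge finite numbers.

## Preference labeling and decoding

Cross-validation is four-fold over the subrun index: fold k tests on
subrun k of *both* runs (4 patterns) and trains on the remaining six
subruns (12 patterns).  Within each fold, each voxel's preference is the
sign of its mean training t-difference between the patch-relative
reference condition (radial / vertical) and the orthogonal one; exact
ties (measure zero under continuous noise) are excluded from both sets
rather than randomized, so set membership never depends on a seed.
Decoding uses a linear two-class maximum-margin SVM with fixed cost
C = 1 and no feature scaling, trained per fold on the selected voxels
only.  Group inference is a one-sided Wilcoxon signed-rank test across
subjects against chance (exact null for n ≤ 25 without ties, normal
approximation with continuity correction otherwise), and a two-sided
paired signed-rank test between voxel selections.

## Replicability index

For a voxel set V with training contrast vector u and test contrast
vector v (one signed t-contrast per voxel),

    index = ⟨u, v⟩ / (‖u‖·‖v‖)  ∈ [−1, 1].

No mean-centering: unlike a Pearson correlation the regression intercept
is pinned at the origin, so a positive index requires the per-voxel signs
to replicate.  Under the null of no replicability it is symmetric about
0; a set selected purely by training noise *reverts* in test data and
yields a negative index.  Per subject the index is averaged over the four
folds, excluding folds with an empty set or zero-norm vector (never
imputed).  Group inference is a participant bootstrap (10,000 resamples,
percentile CI95, one-sided add-one p with half-weight on resampled means
exactly at zero — for continuous data identical to counting means ≤ 0).
ROI effects (4 quarterfields; 3 eccentricity bands) are probed by
classical one-way fixed-effects ANOVAs on the fold-averaged per-subject
indices, one per orientation set and factor.

## Spatial shifts

Test patterns are shifted by 0.5, 1, 2 or 3 voxels (1, 2, 4, 6 mm) along
the in-plane grid axes; half-voxel shifts average each voxel with its
neighbor along the direction.  Voxels whose source falls outside the
patch grid are dropped from both the training and test views (symmetric
dropping — zero-padding would fabricate a decodable border).  The default
direction set is the four in-plane axes of the 2-D sheet; a 3-D volume
would use six.  Accuracies are averaged over directions within subject
before group tests.  Because the simulated columns are sub-voxel, large
shifts decorrelate the fine-grained pattern completely while a purely
coarse signal survives relabeling — which is exactly the diagnostic the
shift control provides.

## Numerical and design choices

* Preference ties: excluded, not randomized (see above).
* Undefined replicability folds and empty voxel selections: recorded as
  missing and excluded, never imputed as zero.
* Wilcoxon zeros: excluded (Wilcoxon's original treatment).
* Bootstrap p uses the add-one (permutation-style) estimator so p > 0
  always.
* %-signal-change summaries come from the simulator's noise-free
  amplitude channel when available (the conversion from measured t to
  %SC is otherwise under-determined); with user-supplied data they fall
  back to the measured t-contrast in pattern units.
* No multiple-testing correction by default, mirroring uncorrected
  per-ROI reporting; a Bonferroni switch exists in the pipeline config.
* Report TSVs use a fixed float format, so reruns with the same master
  seed are byte-identical.

## What the generator does and does not emulate

Emulated: the study design (18 subjects, 2 stimulus families × 2
exemplars, 2 runs × 4 subruns, one t-pattern per condition per subrun,
2-mm voxels, four quarterfield ROIs × three eccentricity bands), coarse
radial/vertical biases of the published magnitude, columnar-scale
heterogeneity, a strictly positive heterogeneous gain field, and
measurement noise.

Not emulated: cortical folding and surface reconstruction (the sheet is
flat and the voxel grid 2-D), spatially correlated and temporally
autocorrelated fMRI noise, scanner drift and motion, retinotopic-mapping
GLMs on real meshes, vascular geometry.  Consequently, passing tests
show that the *pipeline* draws the correct inferences in worlds where
the ground truth is known; they do not certify any claim about real
cortical data, whose effect sizes the simulator only matches in order of
magnitude.

## Known limitations

* The simulator cannot match all published effect sizes at once: with
  i.i.d. noise and a single columnar amplitude, all-voxel accuracy runs
  ~10 points above the published value when the minority-set accuracy
  and replicability are matched.  Real data presumably contain
  correlated noise that hurts the all-voxel classifier more than the
  split-set ones.
* In the coarse-only world, minority-set decoding is not merely at
  chance but systematically *below* it: the classifier learns the
  selection artifact while the true contrast keeps the opposite sign.
  This is the decoding-space mirror of the negative minority
  replicability and is visible in the `coarse_only` outputs.
* Half-voxel shifts are implemented as two-point averages (as in the
  original shifting procedure), which also low-pass filters the pattern;
  shift magnitudes confound displacement with smoothing at 1 mm.
* The exact Wilcoxon path requires tie-free ranks; tied data fall back
  to the normal approximation even at small n.
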