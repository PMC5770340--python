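# genatlas

Generative groupwise modelling of multi-channel MR volumes: joint
probabilistic tissue segmentation, bias-field correction, affine and
diffeomorphic registration, and average-shaped tissue-probability-template
construction, all optimised as a single variational objective.

## Who this is for

Neuroimaging methods researchers who need population-specific probabilistic
tissue templates, and anyone studying coupled segmentation/registration
models. The package fits a hierarchical Bayesian model to a population of
subjects — each with one or more image channels, optionally with partial
manual labels and missing channels — and returns the population template,
per-subject tissue posteriors, bias fields, affine transforms and
diffeomorphic deformations. Everything is exercisable on synthetic phantoms
sampled from the model itself, with full ground truth retained.

## The model

For subject *i* and voxel *j* with intensity vector x<sub>ij</sub> ∈ ℝ^D:

- **Tissue prior.** A K-class probability template π (trilinear coefficients
  on its own grid, simplex at every voxel, Dirichlet prior) is warped into
  each subject by ξ<sub>i</sub> = T<sub>i</sub> ∘ φ<sub>i</sub>, where
  T<sub>i</sub> = exp(Q(a<sub>i</sub>)) is a nine-parameter exponential-map
  affine plus translation t<sub>i</sub>, and φ<sub>i</sub> is the endpoint of
  a velocity-field flow computed by geodesic shooting from an initial
  velocity u<sub>i</sub> penalised by ‖L u‖². Per-subject positive weights
  w<sub>ik</sub> rescale the warped priors:

      p(z_ijk = 1) = w_ik π_k(ξ_i(y_j)) / Σ_c w_ic π_c(ξ_i(y_j))

- **Intensity likelihood.** Given the class, intensities follow a
  multivariate Gaussian whose mean and precision carry conjugate
  Gauss–Wishart priors shared across the population (learned by empirical
  Bayes). A smooth multiplicative bias field b (exponential of a low-order
  DCT expansion per channel) rescales each component:
  p(x|z_k) = det(diag b) · N(b ⊙ x | μ_k, Σ_k).

- **Supervision.** Manual labels enter through a rater-sensitivity prior
  (sensitivity ζ = 0.9 by default): p(z_k|l) = ζ if k = l, (1−ζ)/(K−1)
  otherwise, combined with the intensity evidence by Bayes' rule.

Fitting is coordinate ascent on one evidence lower bound: per subject a
variational E-step, conjugate mixture M-step, and Gauss–Newton updates for
bias, affine and initial velocity (each with a backtracking line search);
per outer iteration a groupwise template update from Jacobian-weighted
pushed responsibilities and an empirical-Bayes intensity-prior update. The
bound is recomputed after every update and may never decrease — a decrease
raises an error naming the offending update.

## Worked example

```python
from genatlas import AtlasConfig, AtlasModel, PhantomSpec, sample_population
from genatlas.phantom import recovery_report

# 4 subjects, 2 channels, 24^3 voxels, 3% noise, 10% bias, smooth warps
spec = PhantomSpec(n_subjects=4, n_classes=3, n_channels=2, shape=(24, 24, 24),
                   noise_level=0.03, bias_amplitude=0.1, deformation_amplitude=1.0)
phantom = sample_population(spec, seed=11)

config = AtlasConfig(n_classes=3, affine_warmup=2, max_outer=8)
results = AtlasModel(phantom.volumes, config=config).fit()
print(results.summary())
report = recovery_report(results, phantom)
print(f"macro Dice {report['macro_dice']:.3f}  "
      f"bias r {report['mean_bias_r']:.3f}  "
      f"displacement error {report['mean_displacement_error']:.3f} vox")
```

Output from the run above:

```
Generative groupwise atlas fit
==============================================
subjects:            4
classes (K):         3
channels (D):        2
template grid:       (24, 24, 24)
outer iterations:    8
final lower bound:   214948.3127
bound gain:          107264.2318
monotone updates:    200
  subject 0: |t| = 0.000 mm, weights [0.945 1.436 0.619]
  subject 1: |t| = 0.000 mm, weights [0.909 1.511 0.58 ]
  subject 2: |t| = 0.000 mm, weights [0.882 1.472 0.646]
  subject 3: |t| = 0.003 mm, weights [0.956 1.508 0.536]
macro Dice 1.000  bias r 0.987  displacement error 0.260 vox
```

Macro Dice compares the fitted per-voxel class posteriors (thresholded at
0.5, classes aligned for the label-switching gauge) with the phantom's true
labels; bias r is the Pearson correlation between fitted and true bias
fields; the displacement error is measured after removing the global-pose
gauge shared by template and subjects.

A command-line interface wraps the same library:

```sh
genatlas simulate --out sim --subjects 4 --shape 24 24 24 --seed 1
genatlas fit sim/sub*.nii.gz --out fitdir
genatlas apply sim/sub00.nii.gz --template fitdir/template.nii.gz --out applied
genatlas evaluate applied_labels.nii.gz sim/sub00_truth.nii.gz
```

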