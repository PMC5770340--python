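# Methods

This note records the model, the numerical choices behind the
implementation, and what the synthetic experiments do and do not establish.

## Model

The observed data are M subjects, each a D-channel volume on its own voxel
grid, optionally with integer-coded manual labels on a subset of voxels and
with some channels unobserved. The generative story, top down:

1. **Template.** A K-class tissue-probability template lives on the template
   grid as trilinear (first-degree B-spline) coefficients π_jk that form a
   probability simplex at every voxel. Each voxel's coefficient vector has a
   Dirichlet prior with concentration α₀ (default 1.01 for every class —
   near-flat, while keeping the MAP update defined when a class receives no
   pushed mass).
2. **Deformation.** Subject anatomy is reached by warping the template:
   ξ_i = T_i ∘ φ_i. The affine part T_i = exp(Σ_m a_im B_m) uses nine fixed
   generators of ga(3) (rotations, log-zooms, shears), so det T > 0 for any
   parameter vector; translations are a separate vector. The prior is
   zero-mean Gaussian with variance 1 on rotations and translations and
   0.001 on zooms and shears. The diffeomorphic part is the endpoint of the
   flow of an initial velocity field u_i with quadratic penalty
   ½‖L u‖², integrated by geodesic shooting (below). The affine acts in
   world (mm) coordinates so voxel-size differences between subjects are
   absorbed.
3. **Class labels.** z_ij is categorical with probabilities proportional to
   w_ik π_k(ξ_i(y_j)); the per-subject positive weights w_i compensate for
   individual differences in tissue composition and are normalised to mean 1
   (the model is invariant to their overall scale).
4. **Intensities.** Given the class, x_ij is Gaussian with subject-specific
   mean and covariance under conjugate Gauss–Wishart priors shared across
   the population. A multiplicative per-channel bias field — the exponential
   of a separable DCT-II expansion (default 4 modes per axis) — enters
   through the identity det(diag b)·N(b⊙x|μ,Σ) = N(x|diag(b)⁻¹μ,
   diag(b)⁻¹Σdiag(b)⁻¹). The bias prior is a Gaussian penalty on the
   Laplacian of the log-field, diagonal in the DCT basis (weight λ_β,
   default 100).
5. **Rater model.** A manual label l is treated as a noisy observation of z
   with sensitivity ζ (default 0.9): p(l|z=k) ∝ ζ if k=l else (1−ζ)/(K−1).
   One label may map to a subset of mixture classes (configuration block);
   the ζ mass is then split uniformly over the subset at the prior level and
   the Bayes product with the intensity evidence resolves the within-subset
   assignment.

## Inference

Fitting maximises one evidence lower bound by coordinate ascent. The bound
is the standard variational decomposition — expected data log-likelihood,
expected latent log-prior, Gauss–Wishart cross terms and entropies, the
Dirichlet template prior, and the quadratic affine/velocity/bias priors
(parameter-prior normalising constants that do not affect any update are
dropped). For labelled voxels the bound additionally carries the expected
rater log-likelihood E[log p(l|z)], which makes the semisupervised E-step
the exact conditional maximiser; without this term a fixed-form labelled
E-step could move the bound backwards.

Update order per subject: E-step (routing unlabelled, labelled and
partially observed voxels), conjugate M-step, mixing weights
(multiplicative fixed point, accepted only if its objective improves), bias
(one Gauss–Newton step), affine (Gauss–Newton with the exact Fréchet
derivative of the matrix exponential), velocity (Gauss–Newton with a
preconditioned conjugate-gradient inner solve). Then the template and the
empirical-Bayes intensity priors are updated. The bound is recomputed after
every named update; a decrease beyond 1e-6 relative slack raises an error
naming the update — this is the main regression tripwire, and a completed
fit certifies monotonicity.

During the first `affine_warmup` outer iterations (default 3) the velocity
update is skipped, so the coarse pose is resolved before the
high-dimensional deformation starts.

The affine and velocity search directions use half-voxel *centred* template
gradients rather than the exact derivative of the degree-1 interpolant.
The interpolant is piecewise linear, so its exact gradient is one-sided at
lattice vertices; whenever a warped subject lattice coincides with the
template lattice (common in synthetic settings, and locally common in real
fits), the discrete objective has kinks at the current state and the
one-sided slope points nowhere useful — the optimiser can lock at a vertex.
Centred gradients average the two adjacent cell slopes, the standard choice
in registration software. The backtracking line searches always evaluate
the exact objective, so monotonicity is unaffected.

### Geodesic shooting

The initial momentum m₀ = (LᵀL)u₀ is transported by the coadjoint action of
the evolving map (conservation of momentum): at each of the default 8 time
steps the velocity is recovered spectrally (the operator is circulant, so
LᵀL and its Green's function are 3×3 problems per Fourier mode), the
forward map advances by a midpoint (RK2) rule, the inverse map composes the
backtraced increment, and the momentum is re-transported from m₀ by
trilinear splatting (the adjoint of interpolation) of (Dφ)⁻ᵀm₀ — splatting
integrates rather than samples, which keeps the transport stable for
momentum densities far rougher than the velocities themselves.

The operator weights (absolute displacement 0.01, membrane 0.3, bending 64,
linear elasticity (1, 2), voxel units) and the spectral apodisation of the
Gauss–Newton search direction (exp(−κs) with κ = 2 applied symmetrically,
so the effective system matrix stays positive-definite and every step is a
descent direction) were chosen together so that accepted velocity fields
live in the band where this discrete transport is accurate: with these
defaults the momentum pairing ⟨m_t, u_t⟩ is conserved to well under 1%
along each geodesic of a full fit, Jacobians stay positive, and the
inverse-consistency error stays far below 0.1 voxel. Weaker regularisation
lets the fit accumulate mid-frequency velocity content whose momentum no
grid-based transport conserves; the recovery metrics (Dice, bias
correlation, displacement error) are insensitive to this choice across a
wide range of weights.

### Template update

Responsibilities are pushed to the template grid through the inverse warps
with Jacobian-determinant weighting (volume preservation under the change
of variables). With all rescaling weights equal to one the update is the
exact closed form (N_jk + α₀−1)/(Σ_c(N_jc+α₀)−K), kept as a bitwise fast
path. With non-unit weights the per-voxel simplex-constrained stationary
point π_k = (N_k+α₀−1)/(D_k+λ_j) is solved exactly with a vectorised Newton
iteration on the Lagrange multiplier λ_j — the printed approximate scheme
(treat the weighted normaliser as constant, then renormalise) is its first
iteration, and only the exact solve passes a numeric-gradient stationarity
check. Because the det-weighted pushed objective is the continuum change of
variables rather than the exact discrete adjoint of warping, the update is
accepted through a backtracking blend toward the previous template,
evaluated on the true subject-space bound.

### Missing channels

Voxels with some channels unobserved contribute through a variational
posterior over the missing intensities: sufficient statistics use the
conditional Gaussian expectation given the observed channels under the
class posterior mean parameters, plus the conditional covariance in the
second moments; E-step densities use the marginal Gaussian over the
observed channels at the posterior mean parameters with the 1/β
broadening. Voxels with no observed channel are excluded from intensity
sums (they still carry no evidence). With nothing missing both paths reduce
exactly to the complete-data formulas.

### Identifiability gauges

Three exact or near-exact gauge freedoms matter when scoring fits against
synthetic truth, and the evaluation fixes each one explicitly:

- mixture class indices are exchangeable → classes are aligned by a
  population-wide optimal one-to-one assignment before Dice is computed;
- the global pose between template and subjects is arbitrary →
  displacement errors are measured after removing the best affine between
  estimated and true warps;
- the mean log-bias trades off against the Gaussian means →
  `BiasField.recentred()` pins it to zero (and provably leaves class
  likelihood ratios unchanged), and Pearson correlation — the reported bias
  metric — is invariant to this gauge. Recentring is not applied inside the
  fit loop because even likelihood-compensated recentring perturbs the
  Gauss–Wishart cross terms and would fight the strict bound-monotonicity
  contract.

## Synthetic data

The phantom generator samples the generative model in the forward
direction: a smooth random simplex template (softmax of smoothed Gaussian
fields), per-subject affine parameters (rotation sd 0.05 rad, translation
sd 1 voxel, zoom/shear sd 0.02 — realistic anatomical scatter; the
registration prior's literal variances would imply ~60° rotations),
initial velocities drawn from the operator prior N(0, (LᵀL)⁻¹) and then
band-limited (Gaussian σ = 2 voxels) and rescaled to the deformation
amplitude, because raw prior draws carry voxel-scale roughness no anatomy
exhibits; low-order DCT bias fields scaled to the requested amplitude
(0.1 → field in [1/1.1, 1.1]); class labels sampled from the warped priors;
intensities from the class Gaussians with means spread over [0.2, 1] per
channel, so `noise_level` is the noise s.d. relative to the signal range
(0.03 ≈ "3%" noise). An optional Rician mode replaces the Gaussian noise
for stress tests. Deterministic per seed.

What passing tests on these phantoms do **not** show: behaviour on real MR
contrast distributions (heavier tails, partial-volume mixing), anatomically
structured deformations, non-DCT-representable bias, or rater error
structure beyond the symmetric ζ model. The phantoms are matched to the
model by construction; recovery numbers are upper bounds on real-data
performance.

## Default problem sizes

The test suite and the acceptance script run 4-subject populations on
24³ grids with K = 3 classes and D = 2 channels — chosen as the smallest
configuration in which all couplings of the model (groupwise template,
deformations with non-trivial Jacobians, multi-channel bias) are active.
Measured at these sizes: macro Dice 1.000 and bias-field Pearson
r ≈ 0.99 at 3% noise with 10% bias amplitude, displacement error
≈ 0.25 voxel (modulo the global-pose gauge), affine translation recovery
≈ 0.16 voxel.

A property of the joint model worth knowing at this scale: with only four
subjects the free per-voxel template can absorb most of the population's
shape variability by blending, so the fitted initial velocities stay small
(sometimes exactly zero, when the warped lattice sits at a genuine local
optimum of the piecewise-linear objective). Dice and bias recovery are
unaffected; the diffeomorphic machinery is additionally exercised in
isolation by dedicated registration-recovery tests with a fixed template,
where it must do all the work.

## Known limitations

- The template grid must currently match the subject grids' scale for the
  push/pull operations to be well-sampled; strongly anisotropic or
  very different resolutions are untested.
- Gauss–Newton registration is local: initial misalignments beyond the
  template's feature scale (a few voxels on textured phantoms) can converge
  to a nearby optimum. The affine warm-up mitigates, not eliminates, this.
- The missing-channel E-step uses posterior-mean marginal densities rather
  than the full expected marginal under the Gauss–Wishart posterior; with
  heavy missingness the bound-monotonicity of the M-step is only
  approximate (complete-data fits are exact).
- K is fixed by configuration (default 12, matching common practice for
  whole-head segmentation; the desk-scale experiments use K = 3); no model
  selection over K is attempted.
- One Gauss–Newton step per update per outer iteration: convergence needs
  a handful of outer iterations (default cap 30, relative-gain tolerance
  1e-4).
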