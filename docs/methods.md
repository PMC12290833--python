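# Methods

This note documents the models implemented in `dwikit`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate, and
the known limitations. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal models

### Diffusion tensor

The voxel-wise model is `S(b, g) = S0 exp(−b gᵀDg)` with `D` symmetric
(coefficients ordered Dxx, Dxy, Dxz, Dyy, Dyz, Dzz, in mm²/s; b in s/mm²).
Scalar maps come from the eigendecomposition: MD = (λ1+λ2+λ3)/3, AD = λ1,
RD = (λ2+λ3)/2, FA the normalized eigenvalue dispersion. Eigenvalues are
sorted descending; eigenvector signs are fixed by making the first nonzero
component positive. Negative eigenvalues are retained in the λ-maps but
flagged; there is no positive-definiteness constraint (constrained fitting
would silently bias the downstream biophysical inversions).

### Diffusion kurtosis

`ln S = ln S0 − b D(g) + (b²/6) MD² W(g)`, where `W` is the fully symmetric
fourth-order kurtosis tensor in the dimensionless, MD²-scaled convention
(the b² regressor carries MD²·W). The linearized fit solves a 22-column
design for `[ln S0, D, MD²W]`, which is exactly linear; `W` itself is
obtained by dividing out the fitted MD². The 15 unique components are
indexed by the sorted quadruples (i ≤ j ≤ k ≤ l) in lexicographic order with
multinomial multiplicities.

Directional kurtosis is `K(n) = (MD/D(n))² W(n)`. Two metric families are
kept deliberately distinct:

- MK / AK / RK — sphere average, axial evaluation, and perpendicular
  great-circle average of `K(n)`;
- MW / AW / RW — the same constructions applied to `W(n)` itself, with
  `MW = W_iijj/5` evaluated algebraically (it is a full contraction and
  needs no quadrature).

`K` is not clipped: out-of-range values (including `D(n) ≤ 0` along a
quadrature direction) are flagged, never truncated.

### Axisymmetric kurtosis

When both tensors share a symmetry axis `u`, the model reduces to eight
parameters: `ln S0`, the axis angles (θ, φ), D∥, D⊥, and the three kurtosis
amplitudes W̄ (mean), W∥ (axial) and W⊥ (radial). In the symmetry frame the
full tensor has `W1111 = W∥`, `W2222 = W3333 = W⊥`, `W2233 = W⊥/3` and
`W1122 = W1133 = (5W̄ − W∥ − 8W⊥/3)/4`, giving the closed directional form
`W(g) = c⁴W∥ + (1−c²)²W⊥ + 6c²(1−c²)W1122` with `c = g·u`. The antipodal
gauge is fixed to θ ∈ [0, π/2]. Fitting is Gauss–Newton from a full-DKI OLS
initialization (axis = principal eigenvector); near-isotropic voxels, where
the axis is undefined, are flagged degenerate.

## Estimators

**OLS/WLS/robust** operate on log signals. Non-positive intensities carry no
information in the log domain and receive weight zero rather than being
clipped — clipping would bias exactly the residual distribution the WLS
weighting is meant to repair. WLS weights are the squared predicted signals
from a one-pass OLS prediction.

**Robust IRLS** uses the three-factor weight `w = w_signal · w_local ·
w_slice` (each in (0, 1]):

- `w_signal`: the WLS magnitude weighting, normalized per voxel by its
  largest predicted signal;
- `w_local = exp(−(r/(C·ŝ))²)` with `ŝ = 1.4826·MAD(r)` per voxel and
  C = 1.5 — a Gaussian kernel on studentized residuals;
- `w_slice = exp(−(e_s/(C·ŝ_s))²)` where `m_s` is the median absolute
  residual of the observation's slice in that volume, `e_s = max(m_s −
  median(m), 0)` its excess over the dataset median, and `ŝ_s` the robust
  scale of the slice medians. Centering on the excess makes the factor 1 for
  ordinary slices (a raw `m_s/ŝ_s` statistic would down-weight every slice
  on clean noisy data) while still collapsing the weight of slices whose
  residuals are collectively anomalous.

Both robust scales are floored at 1e-9 in log-signal units — far below any
physical noise level — so that machine-precision residuals on noiseless data
are not studentized into spurious outliers. IRLS runs at most 20 iterations,
stopping when the largest relative coefficient change drops below 1e-6. When
the weighted normal matrix condition number exceeds 1e8 a Tikhonov ridge
λ = 1e-4·trace(XᵀWX)/p is added; all linear solves use column
equilibration. The kernel form is a configurable commitment of this package;
the three-factor structure is the contract.

**NLLS** is Gauss–Newton in the signal domain (OLS initialization,
step-halving line search, at most 50 iterations, gradient tolerance 1e-8),
with column equilibration of the Jacobian. Non-converged voxels are flagged,
not fatal.

**Rician-aware NLLS** replaces the model prediction by the first moment of
the noncentral χ distribution,
`E[S] = σ√2 Γ(n+½)/Γ(n) · ₁F₁(−½; n; −A²/2σ²)`, with the analytic
derivative via the ₁F₁ contiguous relation. The closed form is used in
production because a fixed-node Gauss–Laguerre evaluation of the same moment
loses the integrand once the noncentrality (A/σ)² exceeds the largest node
(≈220 for 64 nodes) — precisely the moderate-SNR regime the estimator
exists for. The 64-node quadrature is retained
(`noncentral_chi_mean_quadrature`) and cross-checked against the closed form
and Monte Carlo in the tests. This mode assumes *uncorrected* magnitude
data; combining it with the M2 correction is refused.

## Noise

σ is a single global scalar (homogeneous variance assumption). The standard
estimator pools all background voxels of all volumes:
σ̂² = mean(S²)/(2n), exact on pure-noise noncentral-χ backgrounds because
E[S²] = 2nσ² at zero amplitude. The repeated-measures estimator averages the
per-voxel sample standard deviation (n−1 denominator; the small-k bias of
the sample std is the user's to weigh) across ≥3 repeats of either the b≈0
or the strongest shell.

The M2 correction maps S → √(max(S² − 2nσ², 0)); the clamp keeps magnitudes
real and its trigger fraction is monitored as a QC signal. Two properties
worth knowing:

- The correction is idempotent only at σ = 0; re-application over-corrects
  and raises a warning (the series carries an RBC label in its history).
- The *per-draw* corrected mean is not unbiased for A at low SNR: the square
  root's Jensen gap, ≈ Var(S²)/(8A³), happens to equal the raw Rician bias
  ≈ σ²/2A at A/σ = 5. The M2 method's output quantity is the second-moment
  amplitude estimate √(mean(S²) − 2nσ²), which at A/σ = 5 is ~30× closer to
  A than the raw magnitude mean; the tests assert that quantity.

## Biophysical models

The two-compartment Watson standard model: sticks (f, Da) plus an
axisymmetric extra-axonal Gaussian (De∥, De⊥), axis orientations
Watson-distributed with concentration κ ≥ 0. Within the cumulant regime the
model is fully characterized by (AD, RD, MW, AW, RW), and those five moments
have closed forms in the even Watson moments m2 = ⟨cos²ψ⟩ and m4 = ⟨cos⁴ψ⟩:
every compartment's directional diffusivity is quadratic in cosψ, and the
trace/Frobenius invariants entering MW are orientation-independent. m2 and
m4 come from the Dawson-function identity
(`m2 = 1/(2√κ D(√κ)) − 1/(2κ)`, with a Taylor series below κ = 0.5 where the
closed form cancels); the public `watson_moment` also offers the adaptive
quadrature route (tolerance 1e-12) and both agree to 1e-10.

**WMTI-Watson** solves the five-moment forward map numerically
(trust-region least squares, multi-start, bounds f ∈ [0,1], diffusivities
∈ [0, 4e-3] mm²/s in vivo / [0, 1.5e-3] ex vivo, κ ∈ [0, 128]). The paper
trail for closed-form inversions is deliberately avoided: the numeric route
is validated by forward–inverse round trips (max relative error ~1e-13 on
random admissible sets). The *plus* branch (Da > De∥) is the default; branch
selection controls both the initialization half-space and the accepted
root's sign. Voxels with no in-bounds root, a branch-sign violation, or a
large residual are flagged invalid, never clamped — a single-Gaussian voxel
(zero kurtosis metrics) is correctly rejected this way.

**NODDI-DTI** constrains Da = De∥ = d (fixed: 1.7e-3 mm²/s in vivo, 0.6e-3
ex vivo, user-overridable) and De⊥ = (1−f)d. Under these constraints
MD = d(3 − 4f + 2f²)/3 independent of κ, so f follows from MD alone and is
real-valued in [0,1] exactly when MD ∈ [d/3, d] — that interval *is* the
admissibility test. κ is then the Brent root of FA(f, κ) = FA on [0, 128].
ODI = (2/π)·arctan(1/κ) (κ = 0 → ODI = 1).

All three white-matter models are developed for white matter; applying them
elsewhere is a documentation contract, not a runtime check.

## Phantoms

The generator produces everything the fitters consume: multi-shell schemes,
regionized parameter maps, noiseless signals, noise, and outliers.

- **Schemes**: per-shell directions minimize the antipodally symmetric
  electrostatic repulsion energy (L-BFGS with analytic gradients,
  multi-start, deterministic given the seed); b0 volumes lead the series.
  Preset layouts mirror three reference protocols — brain
  b = 0(18)/600(30)/1100(45)/2500(60), cervical cord
  b = 0(11)/500(30)/1000(30)/1500(30), ex vivo
  b = 0(36)/550(30)/1100(75)/2200(45)/2500(60)/5000(60) s/mm².
- **Signals**: tensor- and kurtosis-level regions evaluate the fitters' own
  forward models, so noiseless round trips are exact by construction;
  standard-model regions evaluate the true spherical convolution of the
  two-compartment kernel with the Watson ODF by product quadrature. The
  convolution signal agrees with the closed-form moments only to second
  order in b: the kurtosis-metric truncation error is O(b·D) and reaches
  ~20% on AW/RW at b_max = 2500 s/mm² (b·Da ≈ 5.5); the generator warns
  beyond b·D = 3 and the tests assert convergence toward the moments as
  b_max shrinks rather than a fixed tolerance at 2500. For the same reason
  the WMTI noise-recovery checks use kurtosis-level phantoms, isolating
  noise propagation from this separate, systematic offset.
- **Noise**: noncentral-χ is synthesized channel-wise — the magnitude of
  2n Gaussian channels with the signal in the first channel's mean — exact
  for any coil count, and validating E[S²] = A² + 2nσ² by construction.
- **Outliers**: slice-wise multiplicative dropouts (each volume×slice pair
  selected independently at the given rate, multiplied by the attenuation),
  modeling cardiac-pulsation signal loss; additive spikes are not modeled.
- The crossing-band layout mixes two orthogonal populations 50/50 at the
  signal level and is deliberately outside every single-fiber model's
  validity; tests must not assert parameter recovery there.

What the phantoms do **not** emulate: anatomy, partial volume, motion, eddy
currents, susceptibility distortion, Gibbs ringing, spatially varying σ, or
exchange. Passing tests demonstrate the estimators' correctness and noise
behavior under the stated models, not robustness to those real-data effects.

## Quadratures and problem sizes

Spherical means (MK, the standard-model convolution) use a Gauss–Legendre
(cosθ) × trapezoid (φ) product rule — 32×64 nodes for metrics, 48×96 for
convolution — exact for spherical harmonics far beyond the integrands'
effective bandwidth and verified against 10⁶-point Monte-Carlo sphere
averages to ~1e-4 absolute (the product rule was chosen over precomputed
spherical grids because it is generated on the fly at any order). RK and RW
use a 64-point trapezoid on the perpendicular great circle, which is exact
for the degree-4 trigonometric polynomial `W(n)` on that circle.

Test and acceptance problem sizes (10×10×4 grids, 100–500 voxels per Monte
Carlo comparison, 50–200 round-trip parameter sets, 10⁴–10⁶ noise draws)
were chosen so each check's Monte-Carlo error sits well below the asserted
effect while the whole suite stays interactive.

## Known limitations

- σ is global; spatially varying noise fields (parallel imaging) are out of
  scope, as are coil-map-based estimators.
- The robust kernel's exact functional form is this package's commitment;
  other kernels fitting the same three-factor structure are configurable.
- No positivity/monotonicity constraints on D or K; flags over clamps.
- The WMTI-Watson inversion inherits the DKI fit's cumulant bias when the
  acquisition pushes b·D well past the expansion's reach; at
  b = 1000/2500 s/mm² with in vivo diffusivities this appears as an f
  underestimate of ~0.06 on true-convolution signals even without noise.
- NODDI-DTI's two-observable design cannot detect violations of its fixed
  diffusivity and tortuosity assumptions; it reports admissibility, not
  model adequacy.
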