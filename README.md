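# dwikit

Diffusion-MRI model fitting and white-matter biophysical modeling:
DTI and DKI estimation with four fitting families, Rician / noncentral-χ
noise handling, the WMTI-Watson and NODDI-DTI inversions of the two-compartment
white-matter standard model, and a synthetic multi-shell phantom generator
that makes the whole stack testable without any scanner data.

## Who this is for

Researchers processing diffusion-weighted MRI — brain, spinal cord, or ex
vivo tissue — who need quantitative microstructure maps (FA, MD, kurtosis
metrics, axonal water fraction, orientation dispersion) from multi-shell
acquisitions, including the low-SNR regimes where magnitude-image noise bias
dominates.

## Models

**Diffusion tensor (DTI).** Per voxel, `ln S = ln S0 − b gᵀDg` with a
symmetric tensor `D` (6 independent coefficients, mm²/s). Estimators:

- **OLS** — unweighted least squares on the log signals;
- **WLS** — weighted by the squared predicted signal, undoing the noise
  distortion the log transform introduces;
- **robust** — iteratively reweighted WLS whose weights factorize into
  signal × local × slice components, down-weighting isolated outliers and
  whole corrupted slices (cardiac pulsation dropouts), with Tikhonov
  regularization of ill-conditioned normal matrices;
- **NLLS** — Gauss–Newton on the non-logarithmic signals, optionally with a
  noncentral-χ mean prediction ("Rician-aware", for uncorrected data only).

**Diffusion kurtosis (DKI).** `ln S = ln S0 − b D(g) + (b²/6) MD² W(g)` with
a fully symmetric fourth-order kurtosis tensor `W` (15 independent,
dimensionless components). Metrics: directional summaries MK/AK/RK and
tensor-contraction summaries MW/AW/RW. An **axisymmetric** variant reduces
the model to 8 parameters (axis, D∥, D⊥, W̄, W∥, W⊥).

**Noise.** Magnitude images follow a Rician (1 coil) or noncentral-χ
(n coils) law. σ is estimated from a background region
(σ ≈ √(Σ Sᵢ²/(2Ln))) or from repeated acquisitions (mean over an ROI of the
per-voxel std across repeats). The M2 correction inverts the second-moment
identity `E[S²] = A² + 2nσ²`.

**Biophysical inversions.** The standard model: intra-axonal "sticks"
(fraction `f`, diffusivity `Da`) plus an axisymmetric extra-axonal tensor
(`De∥`, `De⊥`), orientations Watson-distributed with concentration `κ`
(reported alongside `ODI = (2/π) arctan(1/κ)`).

- **WMTI-Watson** inverts the axisymmetric DKI metrics (AD, RD, MW, AW, RW)
  for (f, Da, De∥, De⊥, κ); the estimation is degenerate with a *plus*
  branch (Da > De∥, default, biologically favored) and a *minus* branch.
- **NODDI-DTI** needs only FA and MD: it fixes `Da = De∥ = d`
  (1.7·10⁻³ mm²/s in vivo, 0.6·10⁻³ ex vivo) with the tortuosity constraint
  `De⊥ = (1−f) d`, and flags voxels whose MD leaves the admissible range
  `[d/3, d]` instead of extrapolating.

## Worked example

Generate a standard-model voxel population at SNR 50, fit the axisymmetric
kurtosis model, and invert it:

```python
import numpy as np
from dwikit import phantom, kurtosis, biophysical

scheme = phantom.make_scheme([(1000.0, 30), (2500.0, 30)], n_b0=4, seed=0)
gt = biophysical.StandardModelParams(f=0.6, Da=2.2e-3, De_par=1.5e-3,
                                     De_perp=0.6e-3, kappa=8.0)
m = biophysical.sm_forward_moments(gt)
p8 = np.array([0.0, 0.0, 0.0, m["AD"], m["RD"], m["MW"], m["AW"], m["RW"]])
sig = np.exp(kurtosis.axi_log_signal(p8, scheme))
noisy = phantom.noncentral_chi_samples(np.tile(sig, (100, 1)), 1/50, 1,
                                       np.random.default_rng(0))
afit = kurtosis.fit_axisymmetric_dki_signals(noisy, scheme)
res = biophysical.wmti_watson({"AD": afit.params[:, 3], "RD": afit.params[:, 4],
                               "MW": afit.params[:, 5], "AW": afit.params[:, 6],
                               "RW": afit.params[:, 7]}, branch="plus")
```

Output:

```
forward moments: {'AD': 0.001688, 'RD': 0.000356, 'MW': 0.636531,
                  'AW': 0.604125, 'RW': 0.441161}
valid voxels: 90/100
f    = 0.597 +/- 0.029  (truth 0.600)
Da   = 2.270 um^2/ms    (truth 2.200)
kappa= 8.22             (truth 8.00)
ODI  = 0.077
```

The forward moments are the axisymmetric DKI metrics the ground-truth
parameters imply; after adding noncentral-χ noise and refitting, the
plus-branch inversion recovers the axonal water fraction with ~0.03 spread
and negligible bias, while voxels whose noisy metrics admit no physical root
are flagged invalid rather than clamped.

## Command line

```bash
dwikit phantom --preset brain --out data/          # synthetic dataset
dwikit dti   --dwi data/phantom_dwi.nii --bval ... --bvec ... \
             --algo robust --sigma 0.02 --out out/
dwikit dki --algo ols ... ; dwikit dkiax ...
dwikit wmti-watson --branch plus ... ; dwikit noddi-dti --preset invivo ...
dwikit pipeline --config pipeline.json             # multi-step run
dwikit replay --provenance out/provenance.json     # bit-identical re-run
```

Outputs follow the BIDS derivatives layout: processing labels are
concatenated into the filename's `desc` entity
(`sub01_desc-RBC-DTI-ROB-FA_dwi.nii`), and each 4-D output is accompanied by
its bval/bvec pair. b-vectors are interpreted in the image coordinate frame
of the NIfTI affine.

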