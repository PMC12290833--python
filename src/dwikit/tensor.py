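"""Per-voxel diffusion-tensor fitting (OLS / WLS / robust IRLS / NLLS) and scalar maps.

The linearized model is ``ln S = ln S0 - b g^T D g`` with six independent
tensor coefficients ordered (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) in mm^2/s.

* OLS minimizes the unweighted sum of squared log-domain residuals.
* WLS weights each observation by the squared predicted signal magnitude,
  undoing the distortion the log transform applies to the noise distribution.
* Robust fitting is an iteratively reweighted WLS whose weights factorize
  into signal, local and slice components, with a Tikhonov ridge applied when
  the weighted normal matrix becomes ill conditioned.
* NLLS runs Gauss-Newton on the non-logarithmic signals, optionally replacing
  the model prediction by the noncentral-chi first moment (Rician-aware mode,
  for *uncorrected* magnitude data only).

Non-positive intensities carry no information in the log domain and receive
weight zero in the linearized fits rather than being clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._optimize import gauss_newton
from .io_bids import DWISeries, GradientScheme, Mask
from .noise import NoiseEstimate, noncentral_chi_mean, noncentral_chi_mean_deriv

__all__ = [
    "TensorFit",
    "TensorMetrics",
    "dti_design_matrix",
    "fit_dti",
    "fit_dti_signals",
    "robust_weights",
    "dti_metrics",
    "dti_metrics_from_coeffs",
]

#: default options for robust IRLS and NLLS
DEFAULT_OPTIONS = {
    "robust_c": 1.5,            # kernel width in robust-scale units
    "irls_max_iter": 20,
    "irls_rtol": 1e-6,          # relative coefficient change
    "cond_threshold": 1e8,      # gate for the Tikhonov ridge
    "tikhonov_scale": 1e-4,     # lambda = scale * trace(X^T W X) / n_params
    "nlls_max_iter": 50,
    "nlls_gtol": 1e-8,
}


def dti_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(N, 7) design for [ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz]."""
    b = scheme.bvals
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx,
        -2 * b * gx * gy,
        -2 * b * gx * gz,
        -b * gy * gy,
        -2 * b * gy * gz,
        -b * gz * gz,
    ])


def coeffs_to_tensors(coeffs: np.ndarray) -> np.ndarray:
    """(V, 7) coefficient rows -> (V, 3, 3) symmetric tensors."""
    c = np.asarray(coeffs)
    dxx, dxy, dxz, dyy, dyz, dzz = (c[..., i] for i in range(1, 7))
    t = np.empty(c.shape[:-1] + (3, 3))
    t[..., 0, 0] = dxx
    t[..., 1, 1] = dyy
    t[..., 2, 2] = dzz
    t[..., 0, 1] = t[..., 1, 0] = dxy
    t[..., 0, 2] = t[..., 2, 0] = dxz
    t[..., 1, 2] = t[..., 2, 1] = dyz
    return t


def tensor_to_coeff_row(lnS0: float, d: np.ndarray) -> np.ndarray:
    """(3,3) tensor -> 7-vector in the package's coefficient ordering."""
    return np.array([lnS0, d[0, 0], d[0, 1], d[0, 2], d[1, 1], d[1, 2], d[2, 2]])


@dataclass
class TensorFit:
    """Voxel-wise diffusion-tensor fit.

    ``coeffs`` holds one row per voxel: ``[ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz]``.
    ``rms_error`` is the root-mean-square model-fit error in the fitting
    domain (log signals for the linearized algorithms, raw signals for NLLS);
    thresholding it yields a reliability mask.
    """

    coeffs: np.ndarray          # (V, 7)
    algorithm: str              # OLS | WLS | ROB | NLLS
    rms_error: np.ndarray       # (V,)
    converged: np.ndarray | None = None  # (V,), NLLS only
    mask: Mask | None = None    # voxel -> grid correspondence, if fitted on a volume
    grid_shape: tuple | None = None

    @property
    def n_voxels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def tensors(self) -> np.ndarray:
        return coeffs_to_tensors(self.coeffs)

    def to_map(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3-D grid."""
        if self.mask is None or self.grid_shape is None:
            raise ValueError("fit was not performed on a gridded series")
        out = np.full(self.grid_shape, fill, dtype=float)
        out[self.mask.data] = values
        return out

    @property
    def rms_error_map(self) -> np.ndarray:
        return self.to_map(self.rms_error)


@dataclass
class TensorMetrics:
    """Rotation-invariant tensor summaries per voxel."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    evals: np.ndarray   # (V, 3) descending
    evecs: np.ndarray   # (V, 3, 3); evecs[v, :, k] pairs with evals[v, k]
    negative_eval: np.ndarray = field(default=None)  # flag per voxel

    def as_dict(self) -> dict:
        return {"FA": self.fa, "MD": self.md, "AD": self.ad, "RD": self.rd,
                "L1": self.evals[:, 0], "L2": self.evals[:, 1],
                "L3": self.evals[:, 2]}


# ---------------------------------------------------------------------------
# linear solvers


def _weighted_linear_solve(design: np.ndarray, logs: np.ndarray,
                           weights: np.ndarray, options=DEFAULT_OPTIONS):
    """Batched weighted normal-equation solve with column equilibration.

    design: (N, P); logs: (V, N) log signals; weights: (V, N) >= 0.
    Returns coefficients (V, P). A Tikhonov ridge (relative to the trace) is
    added where the weighted normal matrix condition number exceeds the gate.
    """
    scale = np.maximum(np.abs(design).max(axis=0), 1e-300)
    xs = design / scale  # (N, P)
    a = np.einsum("vn,np,nq->vpq", weights, xs, xs)
    rhs = np.einsum("vn,np,vn->vp", weights, xs, np.nan_to_num(logs, nan=0.0,
                                                               neginf=0.0, posinf=0.0))
    p = design.shape[1]
    cond = np.linalg.cond(a)
    bad = ~np.isfinite(cond) | (cond > options["cond_threshold"])
    if bad.any():
        lam = options["tikhonov_scale"] * np.einsum("vpp->v", a) / p
        a[bad] += lam[bad, None, None] * np.eye(p)
    try:
        beta = np.linalg.solve(a, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.einsum("vpq,vq->vp", np.linalg.pinv(a), rhs)
    return beta / scale


def _log_valid(signals: np.ndarray):
    """Log signals with zero weight (not clipping) for non-positive intensities."""
    valid = signals > 0
    logs = np.full(signals.shape, 0.0)
    logs[valid] = np.log(signals[valid])
    return logs, valid.astype(float)


def robust_weights(residuals: np.ndarray, predicted_signal: np.ndarray,
                   slice_of_voxel: np.ndarray | None = None,
                   options=DEFAULT_OPTIONS, valid: np.ndarray | None = None):
    """Three-factor robust weights ``w = w_signal * w_local * w_slice``.

    * ``w_signal`` is the WLS magnitude weighting (squared predicted signal),
      normalized per voxel into (0, 1].
    * ``w_local = exp(-(r / (C s))^2)`` with ``s = 1.4826 MAD(r)`` per voxel
      and ``C = 1.5`` by default, down-weighting locally outlying volumes.
    * ``w_slice = exp(-(e_s / (C s_s))^2)`` where ``e_s`` is the excess of the
      slice's median absolute residual over the dataset median and ``s_s`` the
      robust scale of the slice medians; a slice whose residuals are
      collectively anomalous is down-weighted even where individual residuals
      look ordinary. Requires ``slice_of_voxel`` (z index per voxel); without
      it the factor is 1.

    All factors are 1 when the residuals vanish.
    """
    residuals = np.atleast_2d(residuals)
    predicted_signal = np.atleast_2d(predicted_signal)
    c = options["robust_c"]
    if valid is None:
        valid = np.ones_like(residuals)

    # signal factor: squared magnitude weighting, scaled into (0, 1]
    pmax = np.maximum(np.max(predicted_signal * valid, axis=1, keepdims=True), 1e-300)
    w_signal = (predicted_signal / pmax) ** 2
    w_signal = np.clip(w_signal, 1e-300, 1.0)

    # local factor: Gaussian kernel on studentized residuals. The scale is
    # floored at a log-domain precision far below any physical noise level so
    # machine-precision residuals on (near-)noiseless data are not
    # studentized into spurious outliers.
    scale_floor = options.get("scale_floor", 1e-9)
    r = np.where(valid > 0, residuals, np.nan)
    med = np.nanmedian(r, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(r - med), axis=1, keepdims=True)
    s_local = 1.4826 * mad
    tiny = s_local <= 0
    if (tiny & (np.nanmax(np.abs(r), axis=1, keepdims=True) > scale_floor)).any():
        warnings.warn("zero MAD in robust weighting; scale floored",
                      stacklevel=2)
    s_local = np.maximum(s_local, scale_floor)
    with np.errstate(over="ignore"):
        w_local = np.exp(-np.clip(np.nan_to_num(residuals / (c * s_local)), -30, 30) ** 2)
    # voxels whose residuals are identically zero keep weight 1
    all_zero = np.nanmax(np.abs(r), axis=1, keepdims=True) == 0
    w_local = np.where(all_zero, 1.0, w_local)

    # slice factor
    w_slice = np.ones_like(residuals)
    if slice_of_voxel is not None:
        slice_of_voxel = np.asarray(slice_of_voxel)
        slices = np.unique(slice_of_voxel)
        m = np.full((slices.size, residuals.shape[1]), np.nan)
        for i, z in enumerate(slices):
            rows = np.abs(r[slice_of_voxel == z, :])
            if rows.size:
                m[i] = np.nanmedian(rows, axis=0)
        m_flat = m[np.isfinite(m)]
        if m_flat.size:
            m_med = np.median(m_flat)
            s_s = max(1.4826 * np.median(np.abs(m_flat - m_med)), scale_floor)
            if s_s > 0:
                excess = np.maximum(np.nan_to_num(m) - m_med, 0.0)
                factor = np.exp(-(excess / (c * s_s)) ** 2)
                for i, z in enumerate(slices):
                    w_slice[slice_of_voxel == z, :] = factor[i]
    return w_signal * w_local * w_slice


def _fit_nlls_voxel(design, signal, beta0, noise: NoiseEstimate | None,
                    rician_aware: bool, options):
    """Gauss-Newton in the signal domain for one voxel."""
    if rician_aware:
        if noise is None:
            raise ValueError("Rician-aware NLLS requires a NoiseEstimate")
        sigma, n = noise.sigma, noise.ncoils

        def predict_jac(beta):
            amp = np.exp(design @ beta)
            pred = noncentral_chi_mean(amp, sigma, n)
            dmu = noncentral_chi_mean_deriv(amp, sigma, n)
            return pred, (dmu * amp)[:, None] * design
    else:

        def predict_jac(beta):
            pred = np.exp(design @ beta)
            return pred, pred[:, None] * design

    return gauss_newton(predict_jac, beta0, signal,
                        max_iter=options["nlls_max_iter"],
                        gtol=options["nlls_gtol"])


def fit_dti_signals(signals: np.ndarray, scheme: GradientScheme,
                    algorithm: str = "ols", noise: NoiseEstimate | None = None,
                    slice_of_voxel: np.ndarray | None = None,
                    rician_aware: bool = False, options: dict | None = None) -> TensorFit:
    """Fit the diffusion tensor to a (V, N) signal matrix.

    This is the computational core behind :func:`fit_dti`; it accepts bare
    signal rows so phantoms and simulations can bypass volume plumbing.
    """
    opts = dict(DEFAULT_OPTIONS)
    if options:
        opts.update(options)
    algorithm = algorithm.lower()
    if algorithm not in ("ols", "wls", "robust", "rob", "nlls"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if rician_aware and algorithm != "nlls":
        raise ValueError("Rician-aware fitting is only available for NLLS")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    design = dti_design_matrix(scheme)
    _check_design(design, scheme)
    if algorithm in ("wls", "robust", "rob") and noise is None:
        raise ValueError(f"{algorithm.upper()} requires a NoiseEstimate")
    return _fit_linear_exponent_model(
        signals, design, scheme, algorithm, noise, slice_of_voxel,
        rician_aware, opts, label_map={"ols": "OLS", "wls": "WLS",
                                       "robust": "ROB", "rob": "ROB",
                                       "nlls": "NLLS"},
        fit_cls=TensorFit)


def _check_design(design: np.ndarray, scheme: GradientScheme):
    if design.shape[0] < design.shape[1]:
        raise ValueError(
            f"{design.shape[0]} volumes cannot determine {design.shape[1]} "
            "parameters")
    # coplanar / degenerate direction sets make the (unweighted) design singular
    s = np.linalg.svd(design / np.maximum(np.abs(design).max(axis=0), 1e-300),
                      compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError("singular design: gradient directions are coplanar "
                         "or do not span six independent tensor components")


def _fit_linear_exponent_model(signals, design, scheme, algorithm, noise,
                               slice_of_voxel, rician_aware, opts, label_map,
                               fit_cls, extra_builder=None):
    """Shared OLS/WLS/robust/NLLS driver for models with S = exp(X beta)."""
    v, n = signals.shape
    logs, valid = _log_valid(signals)

    beta = _weighted_linear_solve(design, logs, valid, opts)  # OLS
    weights = valid
    if algorithm == "wls":
        pred = np.exp(beta @ design.T)
        weights = valid * pred ** 2
        beta = _weighted_linear_solve(design, logs, weights, opts)
    elif algorithm in ("robust", "rob"):
        prev = beta
        for _ in range(opts["irls_max_iter"]):
            pred = np.exp(prev @ design.T)
            resid = np.where(valid > 0, logs - prev @ design.T, 0.0)
            w = robust_weights(resid, pred, slice_of_voxel, opts, valid=valid)
            weights = valid * w
            beta = _weighted_linear_solve(design, logs, weights, opts)
            delta = np.max(np.abs(beta - prev) / np.maximum(np.abs(prev), 1e-12))
            prev = beta
            if delta < opts["irls_rtol"]:
                break

    converged = None
    if algorithm == "nlls":
        out = np.empty_like(beta)
        converged = np.zeros(v, dtype=bool)
        for i in range(v):
            out[i], converged[i], _ = _fit_nlls_voxel(
                design, signals[i], beta[i], noise, rician_aware, opts)
        if not converged.all():
            warnings.warn(f"{int((~converged).sum())} of {v} NLLS voxels did "
                          "not converge", stacklevel=3)
        beta = out
        resid = signals - np.exp(beta @ design.T)
        if rician_aware:
            resid = signals - noncentral_chi_mean(
                np.exp(beta @ design.T), noise.sigma, noise.ncoils)
        rms = np.sqrt(np.mean(resid ** 2, axis=1))
    else:
        resid = np.where(valid > 0, logs - beta @ design.T, 0.0)
        denom = np.maximum(valid.sum(axis=1), 1)
        rms = np.sqrt(np.sum(resid ** 2, axis=1) / denom)

    kwargs = {}
    if extra_builder is not None:
        kwargs = extra_builder(beta)
    return fit_cls(coeffs=beta, algorithm=label_map[algorithm], rms_error=rms,
                   converged=converged, **kwargs)


def fit_dti(dwi: DWISeries, mask: Mask, algorithm: str = "ols",
            noise: NoiseEstimate | None = None, rician_aware: bool = False,
            options: dict | None = None) -> TensorFit:
    """Fit the diffusion tensor inside ``mask`` on a 4-D series.

    The robust algorithm uses each voxel's z index for the slice weight
    factor, so slice-wise artifacts (e.g. cardiac-pulsation dropouts) are
    down-weighted coherently across a slice.
    """
    if rician_aware and "RBC" in dwi.labels:
        raise ValueError(
            "Rician-aware NLLS assumes uncorrected data; it must not be "
            "combined with the M2 (RBC) correction")
    sel = mask.data
    if sel.shape != dwi.data.shape[:3]:
        raise ValueError("mask misaligned with series")
    signals = dwi.data[sel, :]
    zz = np.nonzero(sel)[2]
    fit = fit_dti_signals(signals, dwi.scheme, algorithm, noise,
                          slice_of_voxel=zz, rician_aware=rician_aware,
                          options=options)
    fit.mask = mask
    fit.grid_shape = dwi.data.shape[:3]
    return fit


# ---------------------------------------------------------------------------
# scalar metrics


def _eig_descending(tensors: np.ndarray):
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    # sign convention: first nonzero component of each eigenvector positive
    for k in range(3):
        vk = evecs[..., :, k]
        lead = np.where(np.abs(vk[..., 0]) > 1e-12, vk[..., 0],
                        np.where(np.abs(vk[..., 1]) > 1e-12, vk[..., 1], vk[..., 2]))
        flip = lead < 0
        evecs[flip, :, k] *= -1
    return evals, evecs


def dti_metrics(fit: TensorFit | np.ndarray) -> TensorMetrics:
    """Eigen-decompose tensors and derive FA, MD, AD, RD.

    Negative eigenvalues are retained in the eigenvalue maps but flagged.
    Voxels with non-finite tensors yield NaN metrics.
    """
    tensors = fit.tensors if isinstance(fit, TensorFit) else coeffs_to_tensors(fit)
    tensors = np.atleast_3d(tensors).reshape(-1, 3, 3)
    finite = np.isfinite(tensors).all(axis=(1, 2))
    safe = np.where(finite[:, None, None], tensors, np.eye(3))
    evals, evecs = _eig_descending(safe)
    md = evals.mean(axis=1)
    ad = evals[:, 0]
    rd = evals[:, 1:].mean(axis=1)
    num = np.sum((evals - md[:, None]) ** 2, axis=1)
    den = np.sum(evals ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    for arr in (fa, md, ad, rd):
        arr[~finite] = np.nan
    evals[~finite] = np.nan
    return TensorMetrics(fa=fa, md=md, ad=ad, rd=rd, evals=evals, evecs=evecs,
                         negative_eval=(evals < 0).any(axis=1))


def dti_metrics_from_coeffs(coeffs: np.ndarray) -> dict:
    """Convenience: FA/MD/AD/RD arrays keyed in lowercase."""
    m = dti_metrics(np.asarray(coeffs))
    return {"fa": m.fa, "md": m.md, "ad": m.ad, "rd": m.rd}
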