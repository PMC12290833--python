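"""Diffusion-kurtosis model fitting (full and axisymmetric) and kurtosis metrics.

Signal model (dimensionless kurtosis-tensor convention)
-------------------------------------------------------
``ln S = ln S0 - b D(g) + (b^2 / 6) MD^2 W(g)`` with ``D(g) = g^T D g``,
``W(g) = sum_ijkl g_i g_j g_k g_l W_ijkl`` and ``MD = tr(D)/3``. W is a fully
symmetric fourth-order tensor with 15 independent components; the b^2 term
carries ``MD^2 W`` so W itself is dimensionless.

The linearized fit solves a 22-column design for ``[ln S0, D (6), MD^2 W (15)]``,
which is exactly linear; W is recovered by dividing out the fitted MD^2. NLLS
refines the same exponent-linear model in the signal domain.

The axisymmetric model constrains both tensors to share one symmetry axis,
reducing the parameterization to eight values: ln S0, the axis (theta, phi),
parallel/perpendicular diffusivity, and the mean/axial/radial kurtosis-tensor
amplitudes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from ._optimize import gauss_newton
from ._sphere import great_circle, orthonormal_frame, sphere_quadrature
from .io_bids import DWISeries, GradientScheme, Mask
from .noise import NoiseEstimate, noncentral_chi_mean, noncentral_chi_mean_deriv
from .tensor import (DEFAULT_OPTIONS, TensorFit, _check_design,
                     _fit_linear_exponent_model, coeffs_to_tensors,
                     dti_design_matrix, dti_metrics)

__all__ = [
    "KurtosisFit",
    "AxiKurtosisFit",
    "KurtosisMetrics",
    "W_INDICES",
    "W_MULTIPLICITY",
    "dki_design_matrix",
    "fit_dki",
    "fit_dki_signals",
    "fit_axisymmetric_dki",
    "fit_axisymmetric_dki_signals",
    "axi_to_full",
    "dki_metrics",
    "w_unique_to_full",
    "w_full_to_unique",
]

#: the 15 independent index quadruples (i <= j <= k <= l), lexicographic
W_INDICES = tuple(combinations_with_replacement(range(3), 4))

#: permutation multiplicity of each quadruple (4! / prod of index-count factorials)
W_MULTIPLICITY = np.array([
    math.factorial(4) // np.prod([math.factorial(q.count(i)) for i in set(q)])
    for q in W_INDICES
], dtype=float)


def w_monomials(dirs: np.ndarray) -> np.ndarray:
    """(M, 15) matrix of multiplicity-weighted direction monomials.

    ``w_monomials(dirs) @ w_unique`` evaluates W(n) for each direction.
    """
    d = np.asarray(dirs, dtype=float)
    cols = [W_MULTIPLICITY[m] * d[:, i] * d[:, j] * d[:, k] * d[:, l]
            for m, (i, j, k, l) in enumerate(W_INDICES)]
    return np.stack(cols, axis=1)


def d_quadratic(dirs: np.ndarray) -> np.ndarray:
    """(M, 6) monomials matching the tensor coefficient order; ``@ d6`` = D(n)."""
    d = np.asarray(dirs, dtype=float)
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    return np.stack([x * x, 2 * x * y, 2 * x * z, y * y, 2 * y * z, z * z], axis=1)


def w_unique_to_full(w_unique: np.ndarray) -> np.ndarray:
    """15 unique components -> full symmetric (3, 3, 3, 3) tensor."""
    full = np.zeros(w_unique.shape[:-1] + (3, 3, 3, 3))
    lookup = {q: w_unique[..., m] for m, q in enumerate(W_INDICES)}
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    full[..., i, j, k, l] = lookup[tuple(sorted((i, j, k, l)))]
    return full


def w_full_to_unique(full: np.ndarray) -> np.ndarray:
    """Full (…, 3, 3, 3, 3) tensor -> 15 unique components."""
    return np.stack([full[..., i, j, k, l] for (i, j, k, l) in W_INDICES], axis=-1)


def dki_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(N, 22) design for [ln S0, D (6), MD^2 W (15)]."""
    b = scheme.bvals
    dti_part = dti_design_matrix(scheme)  # includes the constant column
    kurt_part = (b ** 2 / 6.0)[:, None] * w_monomials(scheme.bvecs)
    return np.hstack([dti_part, kurt_part])


@dataclass
class KurtosisFit:
    """Voxel-wise DKI fit.

    ``coeffs`` rows are the 22 design coefficients
    ``[ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz, MD^2 W_1 .. MD^2 W_15]``;
    the dimensionless kurtosis tensor is exposed via :attr:`w_unique`.
    """

    coeffs: np.ndarray
    algorithm: str
    rms_error: np.ndarray
    converged: np.ndarray | None = None
    mask: Mask | None = None
    grid_shape: tuple | None = None

    @property
    def n_voxels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def lnS0(self) -> np.ndarray:
        return self.coeffs[:, 0]

    @property
    def tensors(self) -> np.ndarray:
        return coeffs_to_tensors(self.coeffs[:, :7])

    @property
    def md(self) -> np.ndarray:
        return np.einsum("vii->v", self.tensors) / 3.0

    @property
    def w_unique(self) -> np.ndarray:
        """(V, 15) dimensionless kurtosis-tensor components."""
        md2 = self.md ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(md2[:, None] > 0, self.coeffs[:, 7:] / md2[:, None], np.nan)

    def predict(self, scheme: GradientScheme) -> np.ndarray:
        return np.exp(self.coeffs @ dki_design_matrix(scheme).T)


@dataclass
class AxiKurtosisFit:
    """Axisymmetric DKI fit: eight parameters per voxel.

    ``params`` columns: ``[ln S0, theta, phi, D_par, D_perp, MW, AW, RW]``
    with the axis gauge fixed to theta in [0, pi/2] (antipodal equivalence).
    """

    params: np.ndarray  # (V, 8)
    rms_error: np.ndarray
    converged: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # isotropic voxels: axis arbitrary
    algorithm: str = "NLLS"

    COLUMNS = ("lnS0", "theta", "phi", "d_par", "d_perp", "mw", "aw", "rw")

    @property
    def n_voxels(self) -> int:
        return self.params.shape[0]

    @property
    def axes(self) -> np.ndarray:
        th, ph = self.params[:, 1], self.params[:, 2]
        return np.stack([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                         np.cos(th)], axis=1)


@dataclass
class KurtosisMetrics:
    """Directional-kurtosis (MK/AK/RK) and tensor-contraction (MW/AW/RW) summaries."""

    mk: np.ndarray
    ak: np.ndarray
    rk: np.ndarray
    mw: np.ndarray
    aw: np.ndarray
    rw: np.ndarray
    invalid: np.ndarray  # True where D(n) <= 0 along some quadrature direction

    def as_dict(self) -> dict:
        return {"MK": self.mk, "AK": self.ak, "RK": self.rk,
                "MW": self.mw, "AW": self.aw, "RW": self.rw}


def _require_multishell(scheme: GradientScheme):
    nonzero = scheme.n_shells - 1
    if nonzero < 2:
        raise ValueError(
            f"kurtosis fitting needs at least 2 nonzero shells, got {nonzero}")


def fit_dki_signals(signals: np.ndarray, scheme: GradientScheme,
                    algorithm: str = "ols", noise: NoiseEstimate | None = None,
                    slice_of_voxel: np.ndarray | None = None,
                    rician_aware: bool = False,
                    options: dict | None = None) -> KurtosisFit:
    """Fit the full DKI model to a (V, N) signal matrix (OLS or NLLS)."""
    opts = dict(DEFAULT_OPTIONS)
    if options:
        opts.update(options)
    algorithm = algorithm.lower()
    if algorithm not in ("ols", "nlls"):
        raise ValueError("DKI offers the OLS and NLLS algorithms")
    if rician_aware and algorithm != "nlls":
        raise ValueError("Rician-aware fitting is only available for NLLS")
    _require_multishell(scheme)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    design = dki_design_matrix(scheme)
    _check_design(design, scheme)
    return _fit_linear_exponent_model(
        signals, design, scheme, algorithm, noise, slice_of_voxel,
        rician_aware, opts, label_map={"ols": "OLS", "nlls": "NLLS"},
        fit_cls=KurtosisFit)


def fit_dki(dwi: DWISeries, mask: Mask, algorithm: str = "ols",
            noise: NoiseEstimate | None = None, rician_aware: bool = False,
            options: dict | None = None) -> KurtosisFit:
    """Fit the full DKI model inside ``mask`` on a 4-D series."""
    if rician_aware and "RBC" in dwi.labels:
        raise ValueError(
            "Rician-aware NLLS assumes uncorrected data; it must not be "
            "combined with the M2 (RBC) correction")
    sel = mask.data
    if sel.shape != dwi.data.shape[:3]:
        raise ValueError("mask misaligned with series")
    fit = fit_dki_signals(dwi.data[sel, :], dwi.scheme, algorithm, noise,
                          slice_of_voxel=np.nonzero(sel)[2],
                          rician_aware=rician_aware, options=options)
    fit.mask = mask
    fit.grid_shape = dwi.data.shape[:3]
    return fit


# ---------------------------------------------------------------------------
# axisymmetric model


def _axi_mix(mw, aw, rw):
    """The off-axis component W_uupp from the three reported amplitudes."""
    return (5.0 * mw - aw - 8.0 * rw / 3.0) / 4.0


def axi_log_signal(params: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """ln S of the axisymmetric model for one parameter row."""
    lnS0, th, ph, dpar, dperp, mw, aw, rw = params
    u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    c2 = (scheme.bvecs @ u) ** 2
    d_n = dperp + (dpar - dperp) * c2
    wmix = _axi_mix(mw, aw, rw)
    w_n = c2 ** 2 * aw + (1 - c2) ** 2 * rw + 6 * c2 * (1 - c2) * wmix
    md = (dpar + 2 * dperp) / 3.0
    b = scheme.bvals
    return lnS0 - b * d_n + (b ** 2 / 6.0) * md ** 2 * w_n


def _axi_predict_jac_factory(scheme, noise=None, rician_aware=False):
    h = 1e-7

    def predict(p):
        amp = np.exp(axi_log_signal(p, scheme))
        if rician_aware:
            return noncentral_chi_mean(amp, noise.sigma, noise.ncoils)
        return amp

    def predict_jac(p):
        pred = predict(p)
        jac = np.empty((pred.size, p.size))
        for i in range(p.size):
            step = h * max(1.0, abs(p[i]))
            hi, lo = p.copy(), p.copy()
            hi[i] += step
            lo[i] -= step
            jac[:, i] = (predict(hi) - predict(lo)) / (2 * step)
        return pred, jac

    return predict_jac


def _canonicalize_axis(params: np.ndarray) -> np.ndarray:
    """Fix the antipodal gauge: theta in [0, pi/2], phi in [0, 2 pi)."""
    out = params.copy()
    th = out[1] % (2 * np.pi)
    ph = out[2]
    if th > np.pi:  # wrap into [0, pi]
        th = 2 * np.pi - th
        ph += np.pi
    if th > np.pi / 2:  # antipode
        th = np.pi - th
        ph += np.pi
    out[1] = th
    out[2] = ph % (2 * np.pi)
    return out


def fit_axisymmetric_dki_signals(signals: np.ndarray, scheme: GradientScheme,
                                 noise: NoiseEstimate | None = None,
                                 rician_aware: bool = False,
                                 options: dict | None = None,
                                 init: KurtosisFit | None = None) -> AxiKurtosisFit:
    """NLLS fit of the eight-parameter axisymmetric DKI model.

    Initialized from a full-DKI OLS fit: the axis from the principal
    eigenvector, diffusivities from AD/RD, and kurtosis amplitudes from the
    tensor-contraction metrics. Near-isotropic voxels (axis undefined) are
    flagged degenerate.
    """
    opts = dict(DEFAULT_OPTIONS)
    if options:
        opts.update(options)
    _require_multishell(scheme)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if init is None:
        init = fit_dki_signals(signals, scheme, "ols")
    met = dki_metrics(init)
    dmet = dti_metrics(TensorFit(coeffs=init.coeffs[:, :7], algorithm="OLS",
                                 rms_error=np.zeros(init.n_voxels)))
    predict_jac = _axi_predict_jac_factory(scheme, noise, rician_aware)

    v = signals.shape[0]
    params = np.empty((v, 8))
    conv = np.zeros(v, dtype=bool)
    rms = np.empty(v)
    degenerate = np.zeros(v, dtype=bool)
    for i in range(v):
        e1 = dmet.evecs[i, :, 0]
        th = np.arccos(np.clip(e1[2], -1, 1))
        ph = np.arctan2(e1[1], e1[0])
        anis = dmet.ad[i] - dmet.rd[i]
        degenerate[i] = abs(anis) <= 1e-12 * max(abs(dmet.md[i]), 1e-30)
        p0 = np.array([init.lnS0[i], th, ph, dmet.ad[i], dmet.rd[i],
                       np.nan_to_num(met.mw[i]), np.nan_to_num(met.aw[i]),
                       np.nan_to_num(met.rw[i])])
        p, c, _ = gauss_newton(predict_jac, p0, signals[i],
                               max_iter=opts["nlls_max_iter"],
                               gtol=opts["nlls_gtol"])
        params[i] = _canonicalize_axis(p)
        conv[i] = c
        pred = np.exp(axi_log_signal(params[i], scheme))
        if rician_aware:
            pred = noncentral_chi_mean(pred, noise.sigma, noise.ncoils)
        rms[i] = np.sqrt(np.mean((signals[i] - pred) ** 2))
    if not conv.all():
        warnings.warn(f"{int((~conv).sum())} of {v} axisymmetric-DKI voxels "
                      "did not converge", stacklevel=2)
    return AxiKurtosisFit(params=params, rms_error=rms, converged=conv,
                          degenerate=degenerate)


def fit_axisymmetric_dki(dwi: DWISeries, mask: Mask,
                         noise: NoiseEstimate | None = None,
                         rician_aware: bool = False,
                         options: dict | None = None) -> AxiKurtosisFit:
    if rician_aware and "RBC" in dwi.labels:
        raise ValueError(
            "Rician-aware NLLS assumes uncorrected data; it must not be "
            "combined with the M2 (RBC) correction")
    sel = mask.data
    return fit_axisymmetric_dki_signals(dwi.data[sel, :], dwi.scheme, noise,
                                        rician_aware, options)


def axi_to_full(fit: AxiKurtosisFit) -> KurtosisFit:
    """Expand axisymmetric parameters to full (D, W) tensors.

    The directional kurtosis of the expanded tensors equals the axisymmetric
    model's prediction for every direction, making this the equivalence
    bridge between the two parameterizations.
    """
    v = fit.n_voxels
    coeffs = np.empty((v, 22))
    for i in range(v):
        lnS0, _, _, dpar, dperp, mw, aw, rw = fit.params[i]
        u = fit.axes[i]
        rot = orthonormal_frame(u)
        d_lab = rot @ np.diag([dpar, dperp, dperp]) @ rot.T
        wmix = _axi_mix(mw, aw, rw)
        w_eig = np.zeros((3, 3, 3, 3))
        vals = {(0, 0, 0, 0): aw, (1, 1, 1, 1): rw, (2, 2, 2, 2): rw,
                (1, 1, 2, 2): rw / 3.0, (0, 0, 1, 1): wmix, (0, 0, 2, 2): wmix}
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    for d in range(3):
                        w_eig[a, b, c, d] = vals.get(tuple(sorted((a, b, c, d))), 0.0)
        w_lab = np.einsum("ia,jb,kc,ld,abcd->ijkl", rot, rot, rot, rot, w_eig)
        md = (dpar + 2 * dperp) / 3.0
        coeffs[i, 0] = lnS0
        coeffs[i, 1:7] = [d_lab[0, 0], d_lab[0, 1], d_lab[0, 2],
                          d_lab[1, 1], d_lab[1, 2], d_lab[2, 2]]
        coeffs[i, 7:] = md ** 2 * w_full_to_unique(w_lab)
    return KurtosisFit(coeffs=coeffs, algorithm="AXI",
                       rms_error=fit.rms_error.copy(),
                       converged=None if fit.converged is None else fit.converged.copy())


# ---------------------------------------------------------------------------
# metrics


def dki_metrics(fit: KurtosisFit, n_theta: int = 32, n_phi: int = 64,
                n_circle: int = 64) -> KurtosisMetrics:
    """Directional and tensor-contraction kurtosis summaries.

    MK is the spherical mean of the directional apparent kurtosis
    ``K(n) = (MD / D(n))^2 W(n)`` over a Gauss-Legendre x trapezoid product
    grid; AK evaluates K along the principal diffusion eigenvector, RK
    averages K over the perpendicular great circle. MW/AW/RW are the
    corresponding evaluations of the W tensor itself, with
    ``MW = W_iijj / 5``. Voxels where D(n) <= 0 along any quadrature
    direction are flagged and their directional metrics set to NaN.
    """
    tensors = fit.tensors
    w_unique = fit.w_unique
    md = fit.md
    dirs, wq = sphere_quadrature(n_theta, n_phi)
    d_n = np.einsum("mi,vij,mj->vm", dirs, tensors, dirs)
    w_n = w_unique @ w_monomials(dirs).T
    invalid = (d_n <= 0).any(axis=1) | ~np.isfinite(w_unique).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k_n = (md[:, None] / d_n) ** 2 * w_n
    mk = np.where(invalid, np.nan, k_n @ wq)

    # MW = full contraction / 5 (rotation invariant, no quadrature needed)
    idx = {q: m for m, q in enumerate(W_INDICES)}
    mw = (w_unique[:, idx[(0, 0, 0, 0)]] + w_unique[:, idx[(1, 1, 1, 1)]]
          + w_unique[:, idx[(2, 2, 2, 2)]]
          + 2 * (w_unique[:, idx[(0, 0, 1, 1)]] + w_unique[:, idx[(0, 0, 2, 2)]]
                 + w_unique[:, idx[(1, 1, 2, 2)]])) / 5.0

    dmet = dti_metrics(TensorFit(coeffs=fit.coeffs[:, :7], algorithm=fit.algorithm,
                                 rms_error=np.zeros(fit.n_voxels)))
    v = fit.n_voxels
    ak = np.empty(v)
    rk = np.empty(v)
    aw = np.empty(v)
    rw = np.empty(v)
    for i in range(v):
        e1 = dmet.evecs[i, :, 0]
        mono_ax = w_monomials(e1[None, :])[0]
        aw[i] = w_unique[i] @ mono_ax
        d_ax = float(e1 @ tensors[i] @ e1)
        ak[i] = (md[i] / d_ax) ** 2 * aw[i] if d_ax > 0 else np.nan
        circ = great_circle(e1, n_circle)
        w_c = w_monomials(circ) @ w_unique[i]
        d_c = np.einsum("mi,ij,mj->m", circ, tensors[i], circ)
        rw[i] = w_c.mean()
        if (d_c > 0).all():
            rk[i] = np.mean((md[i] / d_c) ** 2 * w_c)
        else:
            rk[i] = np.nan
            invalid[i] = True
    ak[invalid & ~np.isfinite(ak)] = np.nan
    mk[invalid] = np.nan
    rk[invalid] = np.nan
    return KurtosisMetrics(mk=mk, ak=ak, rk=rk, mw=mw, aw=aw, rw=rw,
                           invalid=invalid)
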