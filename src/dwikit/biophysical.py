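"""Two-compartment Watson standard model: forward moments and inversions.

The white-matter standard model treats a voxel as non-exchanging intra-axonal
"sticks" (zero radius, diffusivity ``Da``, water fraction ``f``) plus an
axisymmetric extra-axonal Gaussian compartment (``De_par``, ``De_perp``),
with the shared symmetry axis distributed over orientations by a Watson
distribution of concentration ``kappa``.

Within the cumulant (DKI) regime the model is fully characterized by the
axisymmetric kurtosis metrics (AD, RD, MW, AW, RW). Those five moments have
closed forms in the even Watson moments ``<cos^2 psi>`` and ``<cos^4 psi>``,
because every compartment's directional diffusivity is a quadratic in
``cos psi`` and the trace/Frobenius invariants entering MW are orientation
independent. The inversions solve the forward map numerically:

* WMTI-Watson: five observables -> (f, Da, De_par, De_perp, kappa), with a
  plus branch (Da > De_par, the default and biologically favored solution)
  and a minus branch (Da < De_par).
* NODDI-DTI: FA and MD alone -> (f, kappa), under the constraints
  Da = De_par = d_fixed and the tortuosity relation De_perp = (1 - f) d_fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "StandardModelParams",
    "WMTIWatsonResult",
    "NODDIDTIResult",
    "watson_moment",
    "watson_moments24",
    "watson_sample",
    "kappa_to_odi",
    "odi_to_kappa",
    "sm_forward_moments",
    "wmti_watson",
    "noddi_dti",
    "D_INTRA_IN_VIVO",
    "D_INTRA_EX_VIVO",
]

#: fixed intraneurite diffusivities for NODDI-DTI [mm^2/s]
D_INTRA_IN_VIVO = 1.7e-3
D_INTRA_EX_VIVO = 0.6e-3

#: parameter bounds for the inversions [mm^2/s and Watson concentration]
DIFFUSIVITY_BOUND_IN_VIVO = 4.0e-3
DIFFUSIVITY_BOUND_EX_VIVO = 1.5e-3
KAPPA_BOUND = 128.0


@dataclass
class StandardModelParams:
    """Ground-truth or estimated standard-model parameters for one population."""

    f: float
    Da: float
    De_par: float
    De_perp: float
    kappa: float
    mu: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not 0 <= self.f <= 1:
            raise ValueError("f must lie in [0, 1]")
        if min(self.Da, self.De_par, self.De_perp) < 0:
            raise ValueError("diffusivities must be non-negative")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0 (oblate Watson unsupported)")
        if self.De_perp > self.De_par:
            warnings.warn("De_perp exceeds De_par; unusual for white matter",
                          stacklevel=2)
        mu = np.asarray(self.mu, dtype=float)
        self.mu = tuple(mu / np.linalg.norm(mu))


@dataclass
class WMTIWatsonResult:
    f: np.ndarray
    Da: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    kappa: np.ndarray
    odi: np.ndarray
    branch: str
    valid: np.ndarray
    residual: np.ndarray


@dataclass
class NODDIDTIResult:
    f: np.ndarray
    kappa: np.ndarray
    odi: np.ndarray
    d_fixed: float
    valid: np.ndarray


# ---------------------------------------------------------------------------
# Watson distribution


def watson_moment(kappa: float) -> float:
    """``<cos^2 psi>`` under the Watson axial distribution, by adaptive
    quadrature (tolerance 1e-12).

    kappa = 0 gives the uniform-sphere value 1/3; the moment increases
    monotonically to 1 as the distribution concentrates on the axis.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    # factor out e^kappa so the integrand never overflows
    num = integrate.quad(lambda x: x ** 2 * np.exp(kappa * (x ** 2 - 1.0)), 0, 1,
                         epsabs=1e-14, epsrel=1e-12)[0]
    den = integrate.quad(lambda x: np.exp(kappa * (x ** 2 - 1.0)), 0, 1,
                         epsabs=1e-14, epsrel=1e-12)[0]
    return num / den


def watson_moments24(kappa):
    """Vectorized ``(<cos^2>, <cos^4>)`` via the Dawson-function closed form.

    With F(k) = int_0^1 exp(k x^2) dx = e^k D(sqrt k)/sqrt k (D the Dawson
    integral), integration by parts gives
    ``m2 = 1/(2 sqrt(k) D(sqrt k)) - 1/(2k)`` and
    ``m4 = 1/(2 sqrt(k) D(sqrt k)) - 3 m2 / (2k)``. A Taylor series covers
    small kappa where the closed form cancels catastrophically.
    """
    k = np.atleast_1d(np.asarray(kappa, dtype=float))
    if (k < 0).any():
        raise ValueError("kappa must be >= 0")
    m2 = np.empty_like(k)
    m4 = np.empty_like(k)
    small = k < 0.5
    if small.any():
        ks = k[small]
        # F_p(k) = int_0^1 x^p e^{k x^2} dx = sum_j k^j / (j! (2j + p + 1))
        j = np.arange(16)[:, None]
        terms = ks[None, :] ** j / special.factorial(j)
        f0 = np.sum(terms / (2 * j + 1), axis=0)
        f2 = np.sum(terms / (2 * j + 3), axis=0)
        f4 = np.sum(terms / (2 * j + 5), axis=0)
        m2[small] = f2 / f0
        m4[small] = f4 / f0
    big = ~small
    if big.any():
        kb = k[big]
        rk = np.sqrt(kb)
        daw = special.dawsn(rk)
        inv = 1.0 / (2.0 * rk * daw)
        m2[big] = inv - 1.0 / (2.0 * kb)
        m4[big] = inv - 3.0 * m2[big] / (2.0 * kb)
    if np.isscalar(kappa):
        return float(m2[0]), float(m4[0])
    return m2, m4


def watson_sample(kappa: float, mu, n: int, rng) -> np.ndarray:
    """Draw ``n`` unit orientations from Watson(mu, kappa) by rejection."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    out = np.empty((0,))
    xs = []
    got = 0
    while got < n:
        m = max(2 * (n - got), 1000)
        x = rng.uniform(-1, 1, m)
        accept = rng.uniform(0, 1, m) < np.exp(kappa * (x ** 2 - 1.0))
        x = x[accept]
        xs.append(x)
        got += x.size
    x = np.concatenate(xs)[:n]
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - x ** 2)
    local = np.stack([s * np.cos(phi), s * np.sin(phi), x], axis=1)
    # rotate local z to mu
    from ._sphere import orthonormal_frame
    frame = orthonormal_frame(mu)  # first column = mu
    rot = np.column_stack([frame[:, 1], frame[:, 2], frame[:, 0]])  # maps z -> mu
    return local @ rot.T


def kappa_to_odi(kappa):
    """Orientation dispersion index ``odi = (2/pi) arctan(1/kappa)``.

    kappa = 0 (uniform orientations) maps to odi = 1; perfect alignment
    (kappa -> inf) maps to odi -> 0.
    """
    k = np.asarray(kappa, dtype=float)
    with np.errstate(divide="ignore"):
        odi = (2.0 / np.pi) * np.arctan2(1.0, k)
    return float(odi) if np.isscalar(kappa) else odi


def odi_to_kappa(odi):
    """Inverse of :func:`kappa_to_odi`, defined for odi in (0, 1]."""
    o = np.asarray(odi, dtype=float)
    if np.any((o <= 0) | (o > 1)):
        raise ValueError("odi must lie in (0, 1]")
    k = 1.0 / np.tan(np.pi * o / 2.0)
    return float(k) if np.isscalar(odi) else k


# ---------------------------------------------------------------------------
# forward model


def sm_forward_moments(params: StandardModelParams) -> dict:
    """Axisymmetric DKI metrics (AD, RD, MW, AW, RW) of the standard model.

    The total directional diffusivity averages the compartment diffusivities
    over the Watson orientation distribution; the directional kurtosis is
    ``K(n) = 3 Var[D_c(n)] / <D_c(n)>^2`` with variance taken across
    compartments and orientations. All five metrics reduce to closed forms in
    the Watson moments m2 = <cos^2 psi> and m4 = <cos^4 psi>.
    """
    f, da, dep, dpp, kappa = (params.f, params.Da, params.De_par,
                              params.De_perp, params.kappa)
    if max(da, dep, dpp) <= 0:
        raise ValueError("all diffusivities are zero: degenerate model")
    m2, m4 = watson_moments24(kappa)
    dde = dep - dpp

    # axial / radial projections of <cos^2> under Watson
    t2_ax, t4_ax = m2, m4
    t2_rad = (1.0 - m2) / 2.0
    t4_rad = 3.0 * (1.0 - 2.0 * m2 + m4) / 8.0

    ad = f * da * t2_ax + (1 - f) * (dpp + dde * t2_ax)
    rd = f * da * t2_rad + (1 - f) * (dpp + dde * t2_rad)
    md = (ad + 2 * rd) / 3.0
    if md <= 0:
        raise ValueError("degenerate model: mean diffusivity is zero")

    def second_moment(t2, t4):
        return (f * da ** 2 * t4
                + (1 - f) * (dpp ** 2 + 2 * dpp * dde * t2 + dde ** 2 * t4))

    aw = 3.0 * (second_moment(t2_ax, t4_ax) - ad ** 2) / md ** 2
    rw = 3.0 * (second_moment(t2_rad, t4_rad) - rd ** 2) / md ** 2

    # MW = W_iijj / 5; the trace and Frobenius invariants of each compartment
    # tensor do not depend on its orientation
    tr2 = f * da ** 2 + (1 - f) * (dep + 2 * dpp) ** 2
    frob = f * da ** 2 + (1 - f) * (dep ** 2 + 2 * dpp ** 2)
    mw = (tr2 + 2 * frob - (3 * md) ** 2 - 2 * (ad ** 2 + 2 * rd ** 2)) / (5 * md ** 2)

    return {"AD": ad, "RD": rd, "MW": mw, "AW": aw, "RW": rw}


def _forward_vector(theta: np.ndarray) -> np.ndarray:
    """Forward map on a raw parameter vector (f, Da, De_par, De_perp, kappa)."""
    p = StandardModelParams(*theta)
    m = sm_forward_moments(p)
    return np.array([m["AD"], m["RD"], m["MW"], m["AW"], m["RW"]])


# ---------------------------------------------------------------------------
# WMTI-Watson inversion


def _invert_one(y: np.ndarray, branch: str, d_bound: float):
    md = (y[0] + 2 * y[1]) / 3.0
    if not np.all(np.isfinite(y)) or md <= 0:
        return None
    lo = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
    hi = np.array([1.0, d_bound, d_bound, d_bound, KAPPA_BOUND])
    scale = np.array([md, md, 1.0, 1.0, 1.0])

    def residual(theta):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return (_forward_vector(theta) - y) / scale
            except ValueError:
                return np.full(5, 1e6)

    if branch == "plus":
        starts = [
            np.array([0.6, min(2.2 * md, 0.9 * d_bound), 0.8 * md, 0.4 * md, 8.0]),
            np.array([0.4, min(2.8 * md, 0.95 * d_bound), 1.2 * md, 0.6 * md, 3.0]),
            np.array([0.8, min(1.8 * md, 0.8 * d_bound), 0.6 * md, 0.3 * md, 20.0]),
        ]
    else:
        starts = [
            np.array([0.4, 0.6 * md, min(2.0 * md, 0.9 * d_bound), 0.5 * md, 8.0]),
            np.array([0.6, 0.3 * md, min(2.5 * md, 0.95 * d_bound), 0.8 * md, 3.0]),
        ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        sol = optimize.least_squares(residual, x0, bounds=(lo, hi),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                     max_nfev=400)
        cost = float(np.sqrt(2 * sol.cost))
        if best is None or cost < best[1]:
            best = (sol.x, cost)
        if cost < 1e-9:
            break
    return best


def wmti_watson(metrics: dict, branch: str = "plus",
                preset: str = "invivo", rtol: float = 1e-6) -> WMTIWatsonResult:
    """Invert axisymmetric DKI metrics to standard-model parameters.

    Parameters
    ----------
    metrics : dict of arrays
        ``AD``, ``RD``, ``MW``, ``AW``, ``RW`` per voxel (scalars allowed).
    branch : {"plus", "minus"}
        The degeneracy branch: plus assumes Da > De_par at the solution
        (default, the biologically favored branch), minus the opposite.
    preset : {"invivo", "exvivo"}
        Sets the diffusivity upper bound (4e-3 vs 1.5e-3 mm^2/s).
    rtol : float
        Relative residual above which a voxel is marked invalid (no root).

    Voxels whose best root lies outside bounds, violates the branch sign, or
    leaves a large residual are flagged invalid rather than clamped.
    """
    if branch not in ("plus", "minus"):
        raise ValueError("branch must be 'plus' or 'minus'")
    d_bound = DIFFUSIVITY_BOUND_IN_VIVO if preset == "invivo" \
        else DIFFUSIVITY_BOUND_EX_VIVO
    keys = ("AD", "RD", "MW", "AW", "RW")
    cols = [np.atleast_1d(np.asarray(metrics[k], dtype=float)) for k in keys]
    n = cols[0].size
    out = np.full((n, 5), np.nan)
    resid = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        y = np.array([c[i] for c in cols])
        res = _invert_one(y, branch, d_bound)
        if res is None:
            continue
        theta, cost = res
        out[i] = theta
        resid[i] = cost
        scale_ref = max(np.linalg.norm(y[:2]) / ((y[0] + 2 * y[1]) / 3.0), 1.0)
        ok = cost < rtol * scale_ref
        f, da, dep, dpp, kappa = theta
        sign_ok = (da >= dep) if branch == "plus" else (da <= dep)
        ok = ok and sign_ok and np.isfinite(theta).all()
        valid[i] = bool(ok)
    return WMTIWatsonResult(
        f=out[:, 0], Da=out[:, 1], De_par=out[:, 2], De_perp=out[:, 3],
        kappa=out[:, 4], odi=kappa_to_odi(out[:, 4]), branch=branch,
        valid=valid, residual=resid)


# ---------------------------------------------------------------------------
# NODDI-DTI


def _noddi_forward(f: float, kappa: float, d: float):
    """(FA, MD) of the tortuosity-constrained model."""
    p = StandardModelParams(f=f, Da=d, De_par=d, De_perp=(1 - f) * d,
                            kappa=kappa)
    m = sm_forward_moments(p)
    ad, rd = m["AD"], m["RD"]
    md = (ad + 2 * rd) / 3.0
    fa = np.sqrt(1.5 * ((ad - md) ** 2 + 2 * (rd - md) ** 2)
                 / (ad ** 2 + 2 * rd ** 2))
    return fa, md


def noddi_dti(fa_map, md_map, d_fixed: float = D_INTRA_IN_VIVO,
              mask=None) -> NODDIDTIResult:
    """Estimate (f, kappa, odi) from FA and MD maps.

    The model fixes ``Da = De_par = d_fixed`` and couples the perpendicular
    extra-axonal diffusivity by the tortuosity relation
    ``De_perp = (1 - f) d_fixed``. Under these constraints
    ``MD = d_fixed (3 - 4 f + 2 f^2) / 3`` independent of kappa, so f follows
    from MD alone (admissible only for MD in [d_fixed/3, d_fixed]); kappa is
    then the root of FA(f, kappa) = FA. Voxels with MD outside the admissible
    range, or FA beyond the model's reach, are flagged invalid rather than
    extrapolated.
    """
    if d_fixed <= 0:
        raise ValueError("d_fixed must be > 0")
    fa = np.atleast_1d(np.asarray(fa_map, dtype=float)).ravel()
    md = np.atleast_1d(np.asarray(md_map, dtype=float)).ravel()
    if mask is not None:
        sel = mask.data.ravel() if hasattr(mask, "data") else np.asarray(mask, bool).ravel()
        idx = np.flatnonzero(sel)
    else:
        idx = np.arange(fa.size)
    f_out = np.full(fa.size, np.nan)
    k_out = np.full(fa.size, np.nan)
    valid = np.zeros(fa.size, dtype=bool)
    for i in idx:
        disc = 6.0 * md[i] / d_fixed - 2.0
        if not np.isfinite(fa[i]) or disc < 0 or disc > 4.0 + 1e-12:
            continue  # MD outside [d/3, d]: no real f in [0, 1]
        f = 1.0 - np.sqrt(max(disc, 0.0)) / 2.0
        f = min(max(f, 0.0), 1.0)
        fa_max, _ = _noddi_forward(f, KAPPA_BOUND, d_fixed)
        if fa[i] > fa_max + 1e-12:
            continue
        if fa[i] <= 0 or f == 0:
            kappa = 0.0 if fa[i] <= _noddi_forward(f, 0.0, d_fixed)[0] + 1e-12 else np.nan
            if not np.isfinite(kappa):
                continue
        else:
            kappa = optimize.brentq(
                lambda k: _noddi_forward(f, k, d_fixed)[0] - fa[i],
                0.0, KAPPA_BOUND, xtol=1e-12, rtol=1e-14)
        f_out[i] = f
        k_out[i] = kappa
        valid[i] = True
    odi = np.where(np.isfinite(k_out), kappa_to_odi(np.nan_to_num(k_out)), np.nan)
    return NODDIDTIResult(f=f_out, kappa=k_out, odi=odi, d_fixed=d_fixed,
                          valid=valid)
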