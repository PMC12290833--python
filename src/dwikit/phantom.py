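"""Synthetic multi-shell dMRI phantoms with known ground truth.

Every fitter and inversion in the package is testable against phantoms built
here: multi-shell gradient schemes with uniform spherical coverage, voxel
grids whose regions carry tensor-, kurtosis- or standard-model-level ground
truth, exact noncentral-chi noise, and slice-wise signal-dropout outliers
modeling cardiac-pulsation artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._sphere import sphere_quadrature
from .io_bids import DWISeries, GradientScheme
from .kurtosis import dki_design_matrix
from .tensor import dti_design_matrix, tensor_to_coeff_row
from .biophysical import StandardModelParams

__all__ = [
    "PhantomSpec",
    "OutlierLog",
    "PRESET_SHELLS",
    "make_scheme",
    "repulsion_energy",
    "synthesize",
    "add_noise",
    "noncentral_chi_samples",
    "inject_outliers",
    "preset_spec",
]

#: shell layouts of the three reference protocols: (b [s/mm^2], n_dirs), n_b0
PRESET_SHELLS = {
    "brain": ([(600.0, 30), (1100.0, 45), (2500.0, 60)], 18),
    "cord": ([(500.0, 30), (1000.0, 30), (1500.0, 30)], 11),
    "exvivo": ([(550.0, 30), (1100.0, 75), (2200.0, 45), (2500.0, 60),
                (5000.0, 60)], 36),
}


# ---------------------------------------------------------------------------
# gradient schemes


def repulsion_energy(dirs: np.ndarray) -> float:
    """Antipodally symmetric electrostatic energy of a direction set."""
    d = np.asarray(dirs, dtype=float)
    diff = np.linalg.norm(d[:, None, :] - d[None, :, :], axis=-1)
    summ = np.linalg.norm(d[:, None, :] + d[None, :, :], axis=-1)
    iu = np.triu_indices(len(d), k=1)
    return float(np.sum(1.0 / diff[iu]) + np.sum(1.0 / summ[iu]))


def _energy_grad(flat: np.ndarray, n: int):
    x = flat.reshape(n, 3)
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / norm
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    e = 0.5 * np.sum(1.0 / dd) + 0.5 * np.sum(1.0 / ds)
    g_u = -np.sum(diff / dd[..., None] ** 3, axis=1) \
        - np.sum(summ / ds[..., None] ** 3, axis=1)
    # project through the normalization x -> x/|x|
    g = (g_u - u * np.sum(g_u * u, axis=1, keepdims=True)) / norm
    return e, g.ravel()


def _optimize_directions(n_dirs: int, rng, n_starts: int = 4) -> np.ndarray:
    best = None
    for _ in range(n_starts):
        x0 = rng.standard_normal((n_dirs, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = optimize.minimize(_energy_grad, x0.ravel(), args=(n_dirs,),
                                jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-15,
                                         "gtol": 1e-12})
        dirs = res.x.reshape(n_dirs, 3)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        e = repulsion_energy(dirs)
        if best is None or e < best[1]:
            best = (dirs, e)
    return best[0]


def make_scheme(shells, n_b0: int = 1, seed: int = 0,
                b0_threshold: float = 50.0) -> GradientScheme:
    """Multi-shell scheme with uniform spherical coverage per shell.

    Directions minimize the antipodally symmetric electrostatic repulsion
    energy on the sphere (deterministic given ``seed``); the ``n_b0``
    non-diffusion-weighted volumes lead the series, followed by the shells in
    ascending b.
    """
    rng = np.random.default_rng(seed)
    shells = sorted(shells, key=lambda s: s[0])
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b, n_dirs in shells:
        dirs = _optimize_directions(int(n_dirs), rng)
        bvals.extend([float(b)] * int(n_dirs))
        bvecs.extend(dirs)
    return GradientScheme.from_bvals_bvecs(np.array(bvals), np.array(bvecs),
                                           b0_threshold=b0_threshold)


# ---------------------------------------------------------------------------
# phantom specification and synthesis


@dataclass
class PhantomSpec:
    """Everything needed to generate a phantom reproducibly.

    ``regions`` is a list of ground-truth dicts, one per region:

    * ``{"kind": "dti", "s0": 1.0, "tensor": (3, 3) array}``
    * ``{"kind": "dki", "s0": 1.0, "tensor": (3, 3), "w_unique": (15,)}``
      (w dimensionless, MD^2-scaled convention)
    * ``{"kind": "sm", "s0": 1.0, "params": StandardModelParams}``

    ``layout``: ``uniform`` (one region everywhere), ``two-region`` (split
    along x), or ``crossing-band`` (two orthogonal bands whose overlap mixes
    the two populations 50/50 at the signal level — deliberately beyond every
    single-fiber model's validity).
    """

    grid_size: tuple = (10, 10, 6)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    layout: str = "uniform"
    regions: list = field(default_factory=list)
    shells: list = field(default_factory=lambda: [(1000.0, 30), (2500.0, 30)])
    n_b0: int = 4
    sigma: float = 0.0
    ncoils: int = 1
    outlier_rate: float = 0.0
    outlier_attenuation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier rate must lie in [0, 1]")
        if not 0 <= self.outlier_attenuation < 1:
            raise ValueError("attenuation must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible phantoms")


@dataclass
class OutlierLog:
    """Record of injected slice dropouts: (volume, slice, attenuation)."""

    entries: list

    def __len__(self):
        return len(self.entries)


def _region_map(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_size
    rid = np.zeros(spec.grid_size, dtype=int)
    if spec.layout == "uniform":
        pass
    elif spec.layout == "two-region":
        rid[nx // 2:, :, :] = 1
    elif spec.layout == "crossing-band":
        # region 1: band along y; region 2: band along x; 3: their crossing
        third = slice(nx // 3, max(2 * nx // 3, nx // 3 + 1))
        third_y = slice(ny // 3, max(2 * ny // 3, ny // 3 + 1))
        band_a = np.zeros(spec.grid_size, dtype=bool)
        band_b = np.zeros(spec.grid_size, dtype=bool)
        band_a[third, :, :] = True
        band_b[:, third_y, :] = True
        rid[band_a] = 1
        rid[band_b] = 2
        rid[band_a & band_b] = 3
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")
    return rid


def sm_signal(params: StandardModelParams, scheme: GradientScheme,
              s0: float = 1.0, n_theta: int = 48, n_phi: int = 96) -> np.ndarray:
    """Noiseless standard-model signal by spherical convolution.

    The two-compartment kernel is convolved numerically with the Watson ODF
    over a product quadrature grid; consistent with the cumulant forward
    moments to second order in b.
    """
    dirs, wq = sphere_quadrature(n_theta, n_phi)
    dens = np.exp(params.kappa * (dirs @ np.asarray(params.mu)) ** 2)
    w = wq * dens
    w /= w.sum()
    c2 = (scheme.bvecs @ dirs.T) ** 2  # (N, M)
    b = scheme.bvals[:, None]
    intra = np.exp(-b * params.Da * c2) @ w
    dde = params.De_par - params.De_perp
    extra = np.exp(-scheme.bvals * params.De_perp) * (np.exp(-b * dde * c2) @ w)
    b_d = scheme.bvals.max() * max(params.Da, params.De_par, 1e-30)
    if b_d > 3.0:
        warnings.warn(
            f"b_max * D = {b_d:.2f} exceeds the cumulant-faithful range; "
            "DKI fits of this signal will deviate from the moment expansion",
            stacklevel=2)
    return s0 * (params.f * intra + (1 - params.f) * extra)


def _region_signal(region: dict, scheme: GradientScheme) -> np.ndarray:
    kind = region.get("kind")
    s0 = float(region.get("s0", 1.0))
    if kind == "dti":
        row = tensor_to_coeff_row(np.log(s0), np.asarray(region["tensor"]))
        return np.exp(dti_design_matrix(scheme) @ row)
    if kind == "dki":
        d = np.asarray(region["tensor"])
        md = np.trace(d) / 3.0
        coeffs = np.concatenate([
            tensor_to_coeff_row(np.log(s0), d),
            md ** 2 * np.asarray(region["w_unique"], dtype=float),
        ])
        return np.exp(dki_design_matrix(scheme) @ coeffs)
    if kind == "sm":
        return sm_signal(region["params"], scheme, s0)
    raise ValueError(f"unknown region kind {kind!r}")


def synthesize(spec: PhantomSpec, scheme: GradientScheme | None = None):
    """Generate the noiseless series and ground-truth maps for a spec.

    Returns ``(DWISeries, ground_truth)`` where ``ground_truth`` holds the
    region-id map, the per-region parameter dicts and the scheme. Noise and
    outliers are *not* applied here; chain :func:`add_noise` and
    :func:`inject_outliers` so the clean reference stays available.
    """
    if not spec.regions:
        raise ValueError("spec.regions is empty")
    if scheme is None:
        scheme = make_scheme(spec.shells, spec.n_b0, seed=spec.seed)
    rid = _region_map(spec)
    n_regions = rid.max() + 1
    signals = []
    for r in range(n_regions):
        if spec.layout == "crossing-band" and r == 3:
            # 50/50 signal-level mixture of the two band populations
            signals.append(0.5 * (signals[1] + signals[2]))
        else:
            region = spec.regions[min(r, len(spec.regions) - 1)]
            signals.append(_region_signal(region, scheme))
    data = np.empty(spec.grid_size + (len(scheme),))
    for r in range(n_regions):
        data[rid == r] = signals[r]
    affine = np.diag(list(spec.voxel_size) + [1.0])
    series = DWISeries(data=data, affine=affine, scheme=scheme,
                       voxel_size=np.asarray(spec.voxel_size, dtype=float))
    truth = {"region_id": rid, "regions": list(spec.regions),
             "region_signals": signals, "scheme": scheme, "spec": spec}
    return series, truth


# ---------------------------------------------------------------------------
# noise and outliers


def noncentral_chi_samples(amplitude: np.ndarray, sigma: float, ncoils: int,
                           rng) -> np.ndarray:
    """Magnitude of 2*ncoils Gaussian channels around ``amplitude``.

    The noiseless signal enters the first channel's mean, which is exactly
    the noncentral-chi magnitude law for any coil count and validates the
    second-moment identity E[S^2] = A^2 + 2 n sigma^2 by construction.
    """
    a = np.asarray(amplitude, dtype=float)
    if sigma == 0:
        return a.copy()
    sq = (a + rng.normal(0.0, sigma, a.shape)) ** 2
    for _ in range(2 * int(ncoils) - 1):
        sq = sq + rng.normal(0.0, sigma, a.shape) ** 2
    return np.sqrt(sq)


def add_noise(dwi: DWISeries, sigma: float, ncoils: int = 1,
              seed: int = 0) -> DWISeries:
    """Apply noncentral-chi noise to a series (identity when sigma = 0)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return dwi.with_data(noncentral_chi_samples(dwi.data, sigma, ncoils, rng))


def inject_outliers(dwi: DWISeries, rate: float, attenuation: float,
                    seed: int = 0):
    """Slice-wise multiplicative signal dropouts.

    Each (volume, slice) pair is independently selected with probability
    ``rate``; selected slices are multiplied by ``attenuation``, modeling the
    signal loss of cardiac-pulsation artifacts. Returns the corrupted series
    and an :class:`OutlierLog`.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nz, nvol = dwi.data.shape[2], dwi.data.shape[3]
    hit = rng.random((nvol, nz)) < rate
    data = dwi.data.copy()
    entries = []
    for v, z in zip(*np.nonzero(hit)):
        data[:, :, z, v] *= attenuation
        entries.append((int(v), int(z), float(attenuation)))
    return dwi.with_data(data), OutlierLog(entries=entries)


def preset_spec(name: str, **overrides) -> PhantomSpec:
    """A ready-made spec mirroring one of the reference shell layouts."""
    shells, n_b0 = PRESET_SHELLS[name]
    defaults = dict(
        shells=shells, n_b0=n_b0,
        regions=[{"kind": "sm", "s0": 1.0,
                  "params": StandardModelParams(
                      f=0.6, Da=2.2e-3, De_par=1.5e-3, De_perp=0.6e-3,
                      kappa=8.0)}],
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
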