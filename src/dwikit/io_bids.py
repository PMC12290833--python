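"""NIfTI + FSL gradient-table I/O, shell grouping, masks, ROIs, derivative naming.

Conventions
-----------
* b-vectors are interpreted in the image coordinate frame of the NIfTI affine;
  no scanner-frame conversion is applied.
* bval/bvec files use the FSL row-major text dialect: one whitespace-separated
  row of N b-values, and three rows of N b-vector components.
* Output filenames follow the BIDS derivatives convention: processing-step
  labels are concatenated into the ``desc`` entity, e.g.
  ``sub01_desc-RBC-DTI-OLS-FA_dwi.nii``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientScheme",
    "DWISeries",
    "Mask",
    "DerivativeName",
    "DESC_LABELS",
    "read_dwi",
    "write_dwi",
    "group_shells",
    "write_derivative",
    "create_brain_mask",
    "reliability_mask",
    "roi_mean",
]

#: Known processing-step labels for the BIDS ``desc`` entity.
DESC_LABELS = frozenset(
    {
        "ECMOCO", "msPOAS", "RBC", "HySCO", "fmap", "COMB-WM", "COMB-AM",
        "DTI", "OLS", "WLS", "ROB", "NLLS",
        "FA", "MD", "AD", "RD", "L1", "L2", "L3", "V1", "V2", "V3",
        "DKI", "DKIax", "MK", "AK", "RK", "MW", "AW", "RW",
        "WMTI-W", "NODDI-DTI", "AWF", "DA", "DE-PARA", "DE-PERP",
        "KAPPA", "ODI", "RMS-ERROR",
    }
)

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2
DEFAULT_SHELL_TOLERANCE = 50.0  # s/mm^2


def group_shells(bvals, tolerance: float = DEFAULT_SHELL_TOLERANCE,
                 b0_threshold: float = DEFAULT_B0_THRESHOLD) -> np.ndarray:
    """Assign an integer shell id to every volume.

    Volumes whose b-values differ by at most ``tolerance`` share a shell
    (single-linkage on the sorted b-values). Shells are numbered by ascending
    mean b-value; shell 0 collects every volume with b <= ``b0_threshold``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    bvals = np.asarray(bvals, dtype=float)
    if bvals.ndim != 1 or bvals.size == 0:
        raise ValueError("bvals must be a nonempty 1-D array")
    order = np.argsort(bvals, kind="stable")
    sorted_b = bvals[order]
    cluster = np.zeros(bvals.size, dtype=int)
    cid = 0
    for k in range(1, bvals.size):
        if sorted_b[k] - sorted_b[k - 1] > tolerance:
            cid += 1
        cluster[order[k]] = cid
    cluster[order[0]] = 0
    # merge every cluster whose mean b is below the b0 threshold into shell 0
    shell_id = cluster.copy()
    is_b0 = bvals <= b0_threshold
    if is_b0.any():
        b0_clusters = np.unique(cluster[is_b0])
        remap = {}
        nxt = 1
        for c in np.unique(cluster):
            remap[c] = 0 if c in b0_clusters else None
        means = {c: bvals[cluster == c].mean() for c in np.unique(cluster)}
        for c in sorted(means, key=means.get):
            if remap[c] is None:
                remap[c] = nxt
                nxt += 1
        shell_id = np.array([remap[c] for c in cluster], dtype=int)
    return shell_id


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion weightings and unit gradient directions with shell labels."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3), image frame, unit norm where b > b0_threshold
    shell_id: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} incompatible with {bvals.size} b-values"
            )
        if not np.all(np.isfinite(bvals)):
            raise ValueError("non-finite b-values")
        if np.any(bvals < 0):
            raise ValueError("negative b-values")
        dw = bvals > self.b0_threshold
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero direction at nonzero b")
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("non-unit b-vector at nonzero b (|norm-1| > 1e-3)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_id", np.asarray(self.shell_id, dtype=int))

    @classmethod
    def from_bvals_bvecs(cls, bvals, bvecs, b0_threshold: float = DEFAULT_B0_THRESHOLD,
                         shell_tolerance: float = DEFAULT_SHELL_TOLERANCE) -> "GradientScheme":
        """Build a scheme, normalizing diffusion-weighted directions and grouping shells."""
        bvals = np.asarray(bvals, dtype=float)
        bvecs = np.array(bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size) and bvecs.shape[0] != bvecs.shape[1]:
            bvecs = bvecs.T
        dw = bvals > b0_threshold
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(dw & (norms < 1e-12)):
            raise ValueError("zero direction at nonzero b")
        bvecs = bvecs.copy()
        bvecs[dw] /= norms[dw, None]
        bvecs[~dw & (norms < 1e-12)] = 0.0
        shells = group_shells(bvals, shell_tolerance, b0_threshold)
        return cls(bvals=bvals, bvecs=bvecs, shell_id=shells, b0_threshold=b0_threshold)

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def n_shells(self) -> int:
        return int(self.shell_id.max()) + 1

    def shell_bvalue(self, shell: int) -> float:
        return float(self.bvals[self.shell_id == shell].mean())

    def volumes_in_shell(self, shell) -> np.ndarray:
        """Volume indices for a shell given by id, 'b0', or 'highest_b'."""
        if shell == "b0":
            shell = 0
        elif shell == "highest_b":
            shell = self.n_shells - 1
        return np.flatnonzero(self.shell_id == int(shell))


@dataclass
class DWISeries:
    """A 4-D diffusion-weighted volume bound to its gradient scheme and geometry."""

    data: np.ndarray  # (X, Y, Z, N), non-negative intensities
    affine: np.ndarray  # 4x4
    scheme: GradientScheme
    voxel_size: np.ndarray | None = None  # mm
    labels: list = field(default_factory=list)  # processing-step history

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (X, Y, Z, N)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"series has {self.data.shape[3]} volumes but the scheme has "
                f"{len(self.scheme)}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxel_size is None:
            self.voxel_size = np.abs(np.linalg.norm(self.affine[:3, :3], axis=0))
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray, extra_label: str | None = None) -> "DWISeries":
        labels = self.labels + [extra_label] if extra_label else list(self.labels)
        return DWISeries(data=data, affine=self.affine, scheme=self.scheme,
                         voxel_size=self.voxel_size, labels=labels)


@dataclass
class Mask:
    """3-D binary mask aligned to a series grid."""

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class DerivativeName:
    """BIDS-style derivative filename: labels concatenated into the desc entity."""

    base: str  # e.g. "sub01_dwi"
    labels: tuple = ()

    def append(self, *labels: str) -> "DerivativeName":
        return replace(self, labels=self.labels + tuple(labels))

    def render(self, extension: str = ".nii") -> str:
        if not self.labels:
            return self.base + extension
        if "_" in self.base:
            stem, suffix = self.base.rsplit("_", 1)
            return f"{stem}_desc-{'-'.join(self.labels)}_{suffix}{extension}"
        return f"{self.base}_desc-{'-'.join(self.labels)}{extension}"


def _read_fsl_table(path: str) -> np.ndarray:
    with open(path) as fh:
        rows = [
            [float(tok) for tok in line.split()]
            for line in fh
            if line.strip()
        ]
    return np.array(rows, dtype=float)


def read_dwi(image_path: str, bval_path: str, bvec_path: str,
             b0_threshold: float = DEFAULT_B0_THRESHOLD) -> DWISeries:
    """Load a 4-D NIfTI with FSL-dialect bval/bvec files.

    Diffusion-weighted b-vectors are renormalized to unit length; shells are
    assigned by :func:`group_shells`.
    """
    img = nib.load(image_path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    bvals = _read_fsl_table(bval_path).ravel()
    bvecs = _read_fsl_table(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    n_img, n_bval, n_bvec = data.shape[3], bvals.size, bvecs.shape[0]
    if not (n_img == n_bval == n_bvec):
        raise ValueError(
            f"count mismatch: image has {n_img} volumes, bval has {n_bval} "
            f"entries, bvec has {n_bvec} columns"
        )
    if not np.all(np.isfinite(bvals)):
        raise ValueError("non-finite b-values in bval file")
    scheme = GradientScheme.from_bvals_bvecs(bvals, bvecs, b0_threshold)
    return DWISeries(data=data, affine=img.affine, scheme=scheme)


def write_dwi(series: DWISeries, image_path: str) -> tuple[str, str, str]:
    """Write a series as NIfTI + FSL bval/bvec. Returns the three paths."""
    nib.save(nib.Nifti1Image(series.data.astype(np.float64), series.affine), image_path)
    stem = image_path
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    bval_path, bvec_path = stem + ".bval", stem + ".bvec"
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:.10g}" for b in series.scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in series.scheme.bvecs.T:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return image_path, bval_path, bvec_path


def write_derivative(volume, name: DerivativeName, out_dir: str,
                     step: str | None = None, overwrite: bool = False) -> str:
    """Write a volume under ``out_dir/derivatives/<step>/`` with a desc-labeled name.

    ``volume`` is a :class:`DWISeries` (bval/bvec are emitted alongside) or a
    ``(array, affine)`` pair for 3-D maps.
    """
    for lab in name.labels:
        if lab not in DESC_LABELS and not lab.isidentifier():
            raise ValueError(f"label {lab!r} is not in the known vocabulary")
    step = step or (name.labels[-1] if name.labels else "Misc")
    target_dir = os.path.join(out_dir, "derivatives", step)
    os.makedirs(target_dir, exist_ok=True)
    path = os.path.join(target_dir, name.render())
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    if isinstance(volume, DWISeries):
        write_dwi(volume, path)
    else:
        arr, affine = volume
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), path)
    return path


def create_brain_mask(tpm_gm, tpm_wm, tpm_csf, threshold: float = 0.8) -> Mask:
    """Mask = 1 where the summed GM+WM+CSF tissue probability exceeds ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    maps = [np.asarray(m, dtype=float) for m in (tpm_gm, tpm_wm, tpm_csf)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValueError("tissue probability maps are not aligned")
    total = maps[0] + maps[1] + maps[2]
    return Mask((total > threshold).astype(np.uint8))


def reliability_mask(rms_error_map, threshold: float) -> Mask:
    """Keep voxels whose root-mean-square model-fit error is at most ``threshold``.

    Voxels above the threshold are considered irreversibly corrupted by
    artifacts and excluded from downstream analyses.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    rms = np.asarray(rms_error_map, dtype=float)
    return Mask((rms <= threshold).astype(np.uint8))


def roi_mean(map_list, roi_masks, reliability_masks=None, by_slice: bool = False) -> pd.DataFrame:
    """Mean parameter value per map × ROI (optionally per axial slice).

    When reliability masks are supplied their intersection with the ROI is
    applied. An empty intersection is reported as NaN with ``n_voxels = 0``,
    never as zero.
    """
    if isinstance(map_list, dict):
        maps = map_list
    else:
        maps = {f"map{i}": m for i, m in enumerate(map_list)}
    if isinstance(roi_masks, dict):
        rois = roi_masks
    else:
        rois = {f"roi{i}": m for i, m in enumerate(roi_masks)}
    rows = []
    for mname, vol in maps.items():
        vol = np.asarray(vol, dtype=float)
        rel = None
        if reliability_masks is not None:
            rel = reliability_masks.get(mname) if isinstance(reliability_masks, dict) \
                else reliability_masks
        for rname, roi in rois.items():
            sel = roi.data if isinstance(roi, Mask) else np.asarray(roi, dtype=bool)
            if sel.shape != vol.shape:
                raise ValueError(f"ROI {rname!r} shape {sel.shape} != map shape {vol.shape}")
            if rel is not None:
                rdat = rel.data if isinstance(rel, Mask) else np.asarray(rel, dtype=bool)
                if rdat.shape != vol.shape:
                    raise ValueError("reliability mask misaligned with map")
                sel = sel & rdat
            if by_slice:
                for z in range(vol.shape[2]):
                    s = sel[:, :, z]
                    rows.append({
                        "map": mname, "roi": rname, "slice": z,
                        "mean": float(vol[:, :, z][s].mean()) if s.any() else np.nan,
                        "n_voxels": int(s.sum()),
                    })
            else:
                rows.append({
                    "map": mname, "roi": rname,
                    "mean": float(vol[sel].mean()) if sel.any() else np.nan,
                    "n_voxels": int(sel.sum()),
                })
    return pd.DataFrame(rows)
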