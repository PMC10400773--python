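"""Diffusion-tensor estimation and derived scalar maps.

The ALPS statistic consumes per-voxel directional diffusivities (Dxx, Dyy,
Dzz) and fractional anisotropy. This module fits the single diffusion tensor
per voxel by ordinary least squares on the log signal and derives the scalar
maps, assuming data already on a common 2 mm template grid.

Axis convention (used throughout the package): x = left-right (perivascular
direction at the lateral-ventricle plane), y = anterior-posterior
(association-fiber axis), z = head-foot (projection-fiber axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientTable",
    "DWIVolume",
    "DiffusionTensorField",
    "TensorMaps",
    "design_matrix",
    "fit_tensor_loglinear",
    "derive_maps",
    "smooth_maps",
    "spread_directions",
    "default_gradient_table",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GradientTableError(ValueError):
    """Invalid acquisition geometry (b-values / directions)."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit direction vectors.

    Invariants enforced at construction: all ``bvals >= 0``, at least one
    b=0 measurement, every direction with b > 0 has unit norm to within
    1e-3 (and is renormalized exactly), and at least 6 distinct
    non-collinear diffusion directions are present.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvecs.shape[0] != bvals.shape[0]:
            raise GradientTableError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) length mismatch"
            )
        if np.any(bvals < 0):
            raise GradientTableError("negative b-value")
        dwi = bvals > 0
        if not np.any(~dwi):
            raise GradientTableError("gradient table needs at least one b=0 entry")
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise GradientTableError("diffusion directions must have unit norm (within 1e-3)")
        bvecs = bvecs.copy()
        bvecs[dwi] /= norms[:, None]
        if _count_distinct_directions(bvecs[dwi]) < 6:
            raise GradientTableError(
                "insufficient directions: need >= 6 distinct non-collinear diffusion directions"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def _count_distinct_directions(vecs: np.ndarray, tol: float = 1e-6) -> int:
    """Count directions distinct up to sign (antipodal pairs identified)."""
    kept: list[np.ndarray] = []
    for v in vecs:
        if not any(abs(abs(v @ u) - 1.0) < tol for u in kept):
            kept.append(v)
    return len(kept)


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal on a regular grid.

    ``data`` is (X, Y, Z, N) in arbitrary signal units; ``affine`` maps
    0-based voxel indices to world mm; ``mask`` restricts fitting.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_size: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("DWI signal must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        self.voxel_size = np.broadcast_to(np.asarray(self.voxel_size, dtype=float).ravel(), (3,)).copy()
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the first three data dimensions")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric tensor as 6 coefficients + estimated S0.

    ``coeffs`` is (X, Y, Z, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in
    mm^2/s. ``valid`` marks voxels that were actually fitted; excluded or
    degenerate voxels are left as zeros.
    """

    coeffs: np.ndarray
    s0: np.ndarray
    affine: np.ndarray
    voxel_size: np.ndarray
    valid: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Return the field as (X, Y, Z, 3, 3) symmetric matrices."""
        c = self.coeffs
        out = np.zeros(c.shape[:-1] + (3, 3))
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out


@dataclass
class TensorMaps:
    """Scalar maps derived from a tensor field.

    Dxx/Dyy/Dzz are the (unclamped) tensor diagonals; eigenvalues are
    clamped at zero before FA/MD so FA stays in [0, 1] under noise.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    evals: np.ndarray  # (..., 3) descending, clamped >= 0
    principal_direction: np.ndarray  # (..., 3) unit vectors
    affine: np.ndarray
    voxel_size: np.ndarray
    mask: np.ndarray

    def scalar_items(self):
        return (("dxx", self.dxx), ("dyy", self.dyy), ("dzz", self.dzz),
                ("fa", self.fa), ("md", self.md))


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """OLS design for the log-linear tensor model.

    Row i is ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]``
    so that ``X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] = ln S``.
    """
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _collapse_b0(dwi: DWIVolume, gtab: GradientTable) -> tuple[np.ndarray, GradientTable]:
    """Average all b=0 volumes into a single leading b=0 measurement."""
    b0 = gtab.b0_mask
    mean_b0 = dwi.data[..., b0].mean(axis=-1, keepdims=True)
    data = np.concatenate([mean_b0, dwi.data[..., ~b0]], axis=-1)
    eff = GradientTable(
        bvals=np.concatenate([[0.0], gtab.bvals[~b0]]),
        bvecs=np.vstack([[0.0, 0.0, 1.0], gtab.bvecs[~b0]]),
    )
    return data, eff


def fit_tensor_loglinear(dwi: DWIVolume, gtab: GradientTable) -> DiffusionTensorField:
    """Fit the diffusion tensor per voxel by OLS on the log signal.

    Multiple b=0 volumes are averaged before fitting. Voxels outside the
    mask, or with any non-positive signal, are left as zeros and marked
    invalid rather than raising.
    """
    if dwi.data.shape[-1] != gtab.n:
        raise ValueError(
            f"DWI has {dwi.data.shape[-1]} volumes but gradient table has {gtab.n} entries"
        )
    data, eff = _collapse_b0(dwi, gtab)
    X = design_matrix(eff)
    if X.shape[0] < 7:
        raise GradientTableError("fewer than 7 usable measurements per voxel")
    if np.linalg.matrix_rank(X) < 7:
        raise GradientTableError("insufficient directions: rank-deficient tensor design")
    pinv = np.linalg.pinv(X)

    mask = dwi.mask if dwi.mask is not None else np.ones(dwi.shape, dtype=bool)
    usable = mask & np.all(data > 0, axis=-1)

    coeffs = np.zeros(dwi.shape + (6,))
    s0 = np.zeros(dwi.shape)
    if np.any(usable):
        ln_s = np.log(data[usable])
        beta = ln_s @ pinv.T  # (n_vox, 7)
        s0[usable] = np.exp(beta[:, 0])
        coeffs[usable] = beta[:, 1:]
    return DiffusionTensorField(
        coeffs=coeffs, s0=s0, affine=dwi.affine, voxel_size=dwi.voxel_size, valid=usable
    )


def derive_maps(tensor_field: DiffusionTensorField) -> TensorMaps:
    """Eigen-decompose the tensor field and derive FA/MD/diffusivity maps.

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda|| with eigenvalues clamped
    at zero; an all-zero tensor gets FA = 0, not NaN.
    """
    mats = tensor_field.as_matrices()
    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    principal = evecs[..., :, 0]

    clamped = np.clip(evals, 0.0, None)
    md = clamped.mean(axis=-1)
    num = ((clamped - md[..., None]) ** 2).sum(axis=-1)
    den = (clamped**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)

    c = tensor_field.coeffs
    return TensorMaps(
        dxx=c[..., 0].copy(),
        dyy=c[..., 1].copy(),
        dzz=c[..., 2].copy(),
        fa=fa,
        md=md,
        evals=clamped,
        principal_direction=principal,
        affine=tensor_field.affine,
        voxel_size=tensor_field.voxel_size,
        mask=tensor_field.valid.copy(),
    )


def smooth_maps(maps: TensorMaps, fwhm_mm: float) -> TensorMaps:
    """Smooth each scalar map with an isotropic Gaussian of the given FWHM.

    Convolution is mask-normalized: values outside the mask do not bleed
    in, and a constant map stays constant inside the mask. ``fwhm_mm = 0``
    returns an identical copy. The eigen-structure maps (eigenvalues,
    principal directions) are carried over unsmoothed.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(
            maps,
            dxx=maps.dxx.copy(), dyy=maps.dyy.copy(), dzz=maps.dzz.copy(),
            fa=maps.fa.copy(), md=maps.md.copy(),
        )
    sigma_vox = (fwhm_mm * _FWHM_TO_SIGMA) / maps.voxel_size
    m = maps.mask.astype(float)
    weight = ndimage.gaussian_filter(m, sigma_vox)

    def _smooth(arr: np.ndarray) -> np.ndarray:
        num = ndimage.gaussian_filter(arr * m, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / weight
        return np.where(maps.mask, out, 0.0)

    return replace(
        maps,
        dxx=_smooth(maps.dxx), dyy=_smooth(maps.dyy), dzz=_smooth(maps.dzz),
        fa=_smooth(maps.fa), md=_smooth(maps.md),
    )


def spread_directions(n: int, iterations: int = 200, step: float = 0.005) -> np.ndarray:
    """Generate ``n`` well-spread unit directions on the hemisphere.

    Starts from a golden-angle spiral and relaxes it with a few iterations
    of antipodally symmetric electrostatic repulsion. Deterministic.
    """
    if n < 6:
        raise ValueError("need at least 6 directions")
    i = np.arange(n) + 0.5
    z = i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    v = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    for _ in range(iterations):
        diff = v[:, None, :] - v[None, :, :]
        anti = v[:, None, :] + v[None, :, :]
        d3 = (np.linalg.norm(diff, axis=-1) ** 3)[..., None]
        a3 = (np.linalg.norm(anti, axis=-1) ** 3)[..., None]
        np.fill_diagonal(d3[..., 0], np.inf)
        force = (diff / d3).sum(axis=1) + (anti / a3).sum(axis=1)
        # project force onto the tangent plane, then renormalize
        force -= (force * v).sum(axis=1, keepdims=True) * v
        v = v + step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def default_gradient_table(n_directions: int = 32, b: float = 1000.0) -> GradientTable:
    """One b=0 plus ``n_directions`` spread directions at b (s/mm^2)."""
    dirs = spread_directions(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, b)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)
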