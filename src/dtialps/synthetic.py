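"""Synthetic DWI phantoms and cohorts with known ground truth.

Every downstream stage of the pipeline is exercised against data whose
generating parameters are known exactly:

* ``generate_phantom_dwi`` builds a small volume containing the white-matter
  geometry the ALPS statistic relies on at the lateral-ventricle plane —
  projection fibers running head-foot (principal axis z), association fibers
  running anterior-posterior (principal axis y), and a perivascular
  diffusivity component along x controlled by a single glymphatic-activity
  parameter ``g`` — then synthesizes the diffusion signal and adds Rician
  magnitude noise.

* ``generate_cohort`` draws a three-group (NC / MCI / AD) cohort whose
  demographics, Fazekas white-matter-hyperintensity scores and thirteen
  cognitive-scale scores follow configurable group means and SDs, with ALPS
  values coupled to a latent severity variable, covariate effects, and
  scanner-batch location/scale effects.

The perivascular x-axis diffusivity interpolates between the cross-fiber
and along-fiber diffusivities: ``Dxx = d_perp + g * (d_axial - d_perp)``,
so the noise-free ALPS-index of the phantom is analytically
``Dxx / d_perp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alps import ROISpec
from .tensor import (
    DiffusionTensorField,
    DWIVolume,
    GradientTable,
    default_gradient_table,
)

__all__ = [
    "BoxRegion",
    "SphereRegion",
    "PhantomSpec",
    "CohortGenSpec",
    "CohortGroundTruth",
    "TABLE1_DEFAULTS",
    "SCALE_COLUMNS",
    "add_rician_noise",
    "generate_phantom_dwi",
    "generate_cohort",
    "default_phantom_spec",
]


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box in voxel index space; ``hi`` is exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        sl = tuple(slice(a, b) for a, b in zip(self.lo, self.hi))
        m[sl] = True
        return m

    def center_voxel(self) -> np.ndarray:
        return (np.asarray(self.lo) + np.asarray(self.hi) - 1) / 2.0

    def min_extent_vox(self) -> float:
        return float(min(b - a for a, b in zip(self.lo, self.hi)))


@dataclass(frozen=True)
class SphereRegion:
    """Sphere in voxel index space."""

    center: tuple[float, float, float]
    radius_vox: float

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(shape)
        d2 = sum((idx[i] - self.center[i]) ** 2 for i in range(3))
        return d2 <= self.radius_vox**2

    def center_voxel(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def min_extent_vox(self) -> float:
        return 2.0 * self.radius_vox


_FIBER_REGIONS = ("projection_L", "projection_R", "association_L", "association_R")


def _default_regions() -> dict[str, BoxRegion]:
    # 7-voxel (14 mm at 2 mm) boxes: left/right split on x, projection vs
    # association split on y; comfortably holds a 5 mm-radius ROI sphere.
    return {
        "projection_L": BoxRegion((2, 2, 2), (9, 9, 9)),
        "projection_R": BoxRegion((15, 2, 2), (22, 9, 9)),
        "association_L": BoxRegion((2, 15, 2), (9, 22, 9)),
        "association_R": BoxRegion((15, 15, 2), (22, 22, 9)),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of the DWI phantom.

    ``g`` (unitless, in [0, 1]) scales the perivascular x-axis diffusivity
    in both fiber regions: ``Dxx = d_perp + g * (d_axial - d_perp)``.
    Diffusivities are in mm^2/s, signal in arbitrary units.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size: float = 2.0
    regions: dict[str, BoxRegion | SphereRegion] = field(default_factory=_default_regions)
    d_axial: float = 1.4e-3
    d_perp: float = 0.4e-3
    g: float = 0.5
    s0: float = 1000.0
    noise_sigma: float = 0.0
    roi_radius_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.d_axial >= self.d_perp > 0):
            raise ValueError("need d_axial >= d_perp > 0")
        if not (0.0 <= self.g <= 1.0):
            raise ValueError("g must be in [0, 1]")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        missing = [k for k in _FIBER_REGIONS if k not in self.regions]
        if missing:
            raise ValueError(f"missing fiber regions: {missing}")

    @property
    def dxx(self) -> float:
        return self.d_perp + self.g * (self.d_axial - self.d_perp)

    @property
    def analytic_alps(self) -> float:
        """Noise-free ALPS-index implied by the spec: Dxx / d_perp."""
        return self.dxx / self.d_perp

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff


def default_phantom_spec(**overrides) -> PhantomSpec:
    return PhantomSpec(**overrides)


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Apply Rician magnitude noise: sqrt((S + n1)^2 + n2^2).

    n1, n2 are independent zero-mean Gaussians of SD ``sigma``; ``sigma = 0``
    returns the input unchanged. Output is non-negative by construction.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be non-negative")
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _region_tensor(name: str, spec: PhantomSpec) -> np.ndarray:
    """Diagonal tensor (3,) for a named region under the phantom model."""
    if name.startswith("projection"):
        return np.array([spec.dxx, spec.d_perp, spec.d_axial])
    if name.startswith("association"):
        return np.array([spec.dxx, spec.d_axial, spec.d_perp])
    raise ValueError(f"unknown fiber region {name!r}")


def generate_phantom_dwi(
    spec: PhantomSpec, gtab: GradientTable | None = None
) -> tuple[DWIVolume, DiffusionTensorField, list[ROISpec]]:
    """Synthesize a DWI phantom: signal, ground-truth tensors and ROIs.

    Projection regions carry diag(Dxx, d_perp, d_axial) (principal axis z),
    association regions diag(Dxx, d_axial, d_perp) (principal axis y); the
    background is isotropic with diffusivity ``d_perp``. The noiseless
    signal is ``S0 * exp(-b * g^T D g)`` per voxel and direction; Rician
    noise with ``noise_sigma`` is then applied. Returned ROIs are radius
    ``roi_radius_mm`` spheres centered in each fiber region.
    """
    if gtab is None:
        gtab = default_gradient_table()
    shape = spec.grid_shape

    masks = {name: reg.mask(shape) for name, reg in spec.regions.items()}
    total = np.zeros(shape, dtype=int)
    for m in masks.values():
        total += m
    if np.any(total > 1):
        raise ValueError("phantom regions overlap")
    for name in _FIBER_REGIONS:
        if spec.regions[name].min_extent_vox() * spec.voxel_size < 2 * spec.roi_radius_mm:
            raise ValueError(
                f"region {name!r} too small to contain a {spec.roi_radius_mm} mm-radius ROI sphere"
            )

    # diagonal tensors per voxel (phantom tensors are diagonal by design)
    diag = np.empty(shape + (3,))
    diag[...] = spec.d_perp  # isotropic background
    for name in _FIBER_REGIONS:
        diag[masks[name]] = _region_tensor(name, spec)

    # S = S0 * exp(-b * sum_k g_k^2 D_kk) for diagonal D
    b_gsq = gtab.bvals[:, None] * gtab.bvecs**2  # (N, 3)
    signal = spec.s0 * np.exp(-np.tensordot(diag, b_gsq, axes=([3], [1])))
    signal = add_rician_noise(signal, spec.noise_sigma, seed=spec.seed)

    affine = spec.affine()
    dwi = DWIVolume(
        data=signal,
        affine=affine,
        voxel_size=np.full(3, spec.voxel_size),
        mask=np.ones(shape, dtype=bool),
    )

    coeffs = np.zeros(shape + (6,))
    coeffs[..., :3] = diag
    truth = DiffusionTensorField(
        coeffs=coeffs,
        s0=np.full(shape, spec.s0),
        affine=affine,
        voxel_size=np.full(3, spec.voxel_size),
        valid=np.ones(shape, dtype=bool),
    )

    rois = []
    for name in _FIBER_REGIONS:
        label, hemi = name.split("_")
        center_world = affine[:3, :3] @ spec.regions[name].center_voxel() + affine[:3, 3]
        rois.append(
            ROISpec(label=label, hemisphere=hemi, center_mm=tuple(center_world),
                    radius_mm=spec.roi_radius_mm)
        )
    return dwi, truth, rois


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

GROUPS = ("NC", "MCI", "AD")

SCALE_COLUMNS = (
    "MoCA-B", "MMSE", "IADL", "HVLT1", "HVLT2", "HVLT3", "WMS",
    "TMT-A", "TMT-B", "ROCFT1", "ROCFT2", "VFT", "BNT",
)

#: Per-group (mean, sd) for demographics and cognitive scales; male:female
#: counts for gender. These are the defaults of the cohort generator.
TABLE1_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"NC": (68.6, 7.5), "MCI": (72.0, 7.1), "AD": (74.0, 8.5)},
    "education": {"NC": (12.2, 3.6), "MCI": (10.0, 4.4), "AD": (9.4, 5.2)},
    "WMH": {"NC": (2.0, 1.5), "MCI": (2.5, 1.5), "AD": (3.1, 1.6)},
    "MoCA-B": {"NC": (23.8, 3.7), "MCI": (16.9, 3.8), "AD": (7.9, 3.6)},
    "MMSE": {"NC": (27.0, 2.2), "MCI": (24.2, 2.9), "AD": (14.9, 5.8)},
    "IADL": {"NC": (15.2, 2.6), "MCI": (16.7, 2.9), "AD": (24.1, 6.4)},
    "HVLT1": {"NC": (20.5, 4.5), "MCI": (15.3, 4.2), "AD": (7.4, 4.6)},
    "HVLT2": {"NC": (7.2, 2.3), "MCI": (3.0, 2.9), "AD": (0.2, 1.0)},
    "HVLT3": {"NC": (7.3, 2.2), "MCI": (2.8, 2.8), "AD": (0.3, 0.9)},
    "WMS": {"NC": (9.5, 2.4), "MCI": (6.2, 2.3), "AD": (3.0, 2.3)},
    "TMT-A": {"NC": (54.7, 16.7), "MCI": (76.6, 28.0), "AD": (120.0, 48.8)},
    "TMT-B": {"NC": (139.6, 44.4), "MCI": (180.1, 51.5), "AD": (211.7, 50.3)},
    "ROCFT1": {"NC": (25.2, 13.3), "MCI": (23.9, 12.6), "AD": (15.1, 12.9)},
    "ROCFT2": {"NC": (13.4, 8.7), "MCI": (6.7, 6.8), "AD": (0.9, 2.8)},
    "VFT": {"NC": (14.7, 3.5), "MCI": (11.6, 3.2), "AD": (6.3, 3.3)},
    "BNT": {"NC": (23.9, 3.4), "MCI": (19.9, 4.2), "AD": (14.2, 5.7)},
}

#: male:female counts per group, converted to P(female)
_GENDER_COUNTS = {"NC": (54, 57), "MCI": (52, 68), "AD": (31, 38)}

#: Scales rated "worse = higher" carry negative coupling to glymphatic function.
_NEGATIVE_SCALES = ("IADL", "TMT-A", "TMT-B")


def _default_scale_corr() -> dict[str, float]:
    return {s: (-0.25 if s in _NEGATIVE_SCALES else 0.25) for s in SCALE_COLUMNS}


@dataclass(frozen=True)
class CohortGenSpec:
    """Parameters of the synthetic three-group cohort.

    Scale scores are generated by linear coupling to the subject's latent
    severity (the same standardized latent that drives ALPS), so the stated
    ``scale_corr`` magnitudes are realized as ALPS-scale correlations when
    batch and covariate effects are absent. Fazekas WMH scores are rounded
    and clamped to integers in [0, 6]; continuous scores are left unbounded.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NC": 111, "MCI": 120, "AD": 69}
    )
    table: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_DEFAULTS.items()}
    )
    alps_mean: dict[str, float] = field(
        default_factory=lambda: {"NC": 1.52, "MCI": 1.40, "AD": 1.30}
    )
    alps_sd: float = 0.12
    fa_mean: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.380, "MCI": 0.372, "AD": 0.360}
    )
    fa_sd: float = 0.025
    fa_latent_corr: float = 0.3
    # additive effects of centered covariates on ALPS
    coef_age: float = -0.004
    coef_education: float = 0.003
    coef_wmh: float = -0.012
    covariate_ref: dict[str, float] = field(
        default_factory=lambda: {"age": 71.5, "education": 10.5, "WMH": 2.5}
    )
    scale_corr: dict[str, float] = field(default_factory=_default_scale_corr)
    hemi_asym_sd: float = 0.03
    # scanner batches: proportions follow the three acquisition protocols
    batch_names: tuple[str, ...] = ("prisma", "verio1", "verio2")
    batch_props: tuple[float, ...] = (0.53, 0.32, 0.15)
    batch_location: tuple[float, ...] = (0.0, 0.06, -0.04)
    batch_scale: tuple[float, ...] = (1.0, 1.15, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("every group needs n >= 2")
        for var, groups in self.table.items():
            for grp, (_, sd) in groups.items():
                if sd <= 0:
                    raise ValueError(f"non-positive SD for {var}/{grp}")
        if self.alps_sd <= 0 or self.fa_sd <= 0:
            raise ValueError("SDs must be > 0")
        if abs(sum(self.batch_props) - 1.0) > 1e-9:
            raise ValueError("batch proportions must sum to 1")
        if not (len(self.batch_names) == len(self.batch_props)
                == len(self.batch_location) == len(self.batch_scale)):
            raise ValueError("batch parameter lengths differ")
        for s, r in self.scale_corr.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"scale_corr[{s!r}] outside [-1, 1]")


@dataclass
class CohortGroundTruth:
    """Sidecar of generating parameters; never written into the cohort CSV."""

    spec: CohortGenSpec
    latent: np.ndarray  # standardized latent severity per subject
    true_alps: np.ndarray  # batch-free ALPS per subject
    group_alps_mean: dict[str, float]
    batch_location: dict[str, float]
    batch_scale: dict[str, float]


def generate_cohort(spec: CohortGenSpec) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Draw a synthetic cohort; deterministic for a fixed spec/seed.

    Returns the cohort table (one row per subject) and a ground-truth
    sidecar used only by recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    latents: list[np.ndarray] = []
    trues: list[np.ndarray] = []
    sid = 0
    for grp in GROUPS:
        n = spec.n_per_group[grp]
        z = rng.standard_normal(n)
        age = rng.normal(*spec.table["age"][grp], n)
        edu = rng.normal(*spec.table["education"][grp], n)
        wmh = np.clip(np.round(rng.normal(*spec.table["WMH"][grp], n)), 0, 6).astype(int)
        n_m, n_f = _GENDER_COUNTS[grp]
        female = rng.random(n) < n_f / (n_m + n_f)

        cov_eff = (
            spec.coef_age * (age - spec.covariate_ref["age"])
            + spec.coef_education * (edu - spec.covariate_ref["education"])
            + spec.coef_wmh * (wmh - spec.covariate_ref["WMH"])
        )
        residual = spec.alps_sd * z
        biological = spec.alps_mean[grp] + cov_eff
        true_alps = biological + residual

        batch_idx = rng.choice(len(spec.batch_names), size=n, p=spec.batch_props)
        gamma = np.asarray(spec.batch_location)[batch_idx]
        delta = np.asarray(spec.batch_scale)[batch_idx]
        bi = biological + gamma + delta * residual
        asym = rng.normal(0.0, spec.hemi_asym_sd, n)
        l_alps = bi + asym
        r_alps = bi - asym

        rho_fa = spec.fa_latent_corr
        fa = spec.fa_mean[grp] + spec.fa_sd * (
            rho_fa * z + np.sqrt(1 - rho_fa**2) * rng.standard_normal(n)
        )

        scales = {}
        for s in SCALE_COLUMNS:
            m, sd = spec.table[s][grp]
            r = spec.scale_corr[s]
            scales[s] = m + sd * (r * z + np.sqrt(1 - r**2) * rng.standard_normal(n))

        for i in range(n):
            rows.append({
                "subject_id": f"S{sid:04d}",
                "group": grp,
                "gender": "F" if female[i] else "M",
                "age": age[i],
                "education": edu[i],
                "WMH": wmh[i],
                "batch": spec.batch_names[batch_idx[i]],
                **{s: scales[s][i] for s in SCALE_COLUMNS},
                "L_ALPS": l_alps[i],
                "R_ALPS": r_alps[i],
                "Bi_ALPS": bi[i],
                "FA_mean": fa[i],
            })
            sid += 1
        latents.append(z)
        trues.append(true_alps)

    df = pd.DataFrame(rows)
    truth = CohortGroundTruth(
        spec=spec,
        latent=np.concatenate(latents),
        true_alps=np.concatenate(trues),
        group_alps_mean=dict(spec.alps_mean),
        batch_location=dict(zip(spec.batch_names, spec.batch_location)),
        batch_scale=dict(zip(spec.batch_names, spec.batch_scale)),
    )
    return df, truth
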