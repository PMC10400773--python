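"""ALPS-index: diffusivity along the perivascular space from ROI means.

At the level of the lateral ventricles, the perivascular space around the
medullary veins runs left-right (x), perpendicular both to projection
fibers (head-foot, z) and to association fibers (anterior-posterior, y).
The ALPS-index contrasts diffusivity along x in both fiber regions against
the diffusivity perpendicular to each tract:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

An index of 1 means no preferential perivascular diffusion; larger values
indicate more water movement along the perivascular channel and are read
as a proxy for glymphatic activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROISpec",
    "ALPSInputs",
    "ALPSResult",
    "sphere_mask",
    "average_roi_centers",
    "extract_alps_inputs",
    "alps_index",
    "bilateral_alps",
    "compute_alps",
]

ROI_LABELS = ("projection", "association")
HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class ROISpec:
    """Spherical ROI in world (mm) coordinates."""

    label: str
    hemisphere: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


@dataclass(frozen=True)
class ALPSInputs:
    """ROI-mean diffusivities (mm^2/s) feeding the ALPS formula, one hemisphere."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float

    def __post_init__(self) -> None:
        vals = (self.dxx_proj, self.dxx_assoc, self.dyy_proj, self.dzz_assoc)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError(f"all ALPS input diffusivities must be positive, got {vals}")


@dataclass
class ALPSResult:
    """Per-subject ALPS indices with the ROI means retained for audit."""

    subject_id: str
    l_alps: float
    r_alps: float
    bi_alps: float
    inputs: dict[str, ALPSInputs]  # keyed by hemisphere
    roi_voxel_counts: dict[str, int]  # keyed by "<label>_<hemisphere>"
    fa_mean: float | None = None  # mean FA over the four ROIs (classifier feature)

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "L_ALPS": self.l_alps,
            "R_ALPS": self.r_alps,
            "Bi_ALPS": self.bi_alps,
        }
        if self.fa_mean is not None:
            row["FA_mean"] = self.fa_mean
        for hemi, inp in sorted(self.inputs.items()):
            row[f"Dxx_proj_{hemi}"] = inp.dxx_proj
            row[f"Dxx_assoc_{hemi}"] = inp.dxx_assoc
            row[f"Dyy_proj_{hemi}"] = inp.dyy_proj
            row[f"Dzz_assoc_{hemi}"] = inp.dzz_assoc
        for key, cnt in sorted(self.roi_voxel_counts.items()):
            row[f"nvox_{key}"] = cnt
        return row


def sphere_mask(roi: ROISpec, affine: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean volume of voxels whose centers lie within the ROI sphere.

    Voxel centers are mapped through ``affine`` to world mm; a voxel is in
    the mask iff its center is within ``radius_mm`` of the ROI center
    (voxel-center rule, no partial-volume weighting).
    """
    affine = np.asarray(affine, dtype=float)
    center = np.asarray(roi.center_mm)
    inv = np.linalg.inv(affine)
    center_vox = inv[:3, :3] @ center + inv[:3, 3]
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(shape) - 0.5):
        raise ValueError(
            f"ROI center {roi.center_mm} maps to voxel {tuple(np.round(center_vox, 2))}, "
            f"outside grid of shape {shape}"
        )
    idx = np.indices(shape).reshape(3, -1)
    world = (affine[:3, :3] @ idx + affine[:3, 3:4]).T
    d2 = ((world - center) ** 2).sum(axis=1)
    mask = (d2 <= roi.radius_mm**2).reshape(shape)
    if not mask.any():
        raise ValueError(f"ROI {roi.label}/{roi.hemisphere} produced an empty mask")
    return mask


def average_roi_centers(rois: list[ROISpec]) -> ROISpec:
    """Average per-subject ROI centers into one consensus ROI.

    Mirrors the practice of averaging manually placed ROI coordinates over
    a set of subjects before building a common mask. All inputs must share
    label, hemisphere and radius.
    """
    if not rois:
        raise ValueError("need at least one ROI to average")
    labels = {r.label for r in rois}
    hemis = {r.hemisphere for r in rois}
    radii = {r.radius_mm for r in rois}
    if len(labels) > 1 or len(hemis) > 1:
        raise ValueError("cannot average ROIs with mixed labels or hemispheres")
    if len(radii) > 1:
        raise ValueError("cannot average ROIs with mixed radii")
    centers = np.array([r.center_mm for r in rois])
    return ROISpec(
        label=rois[0].label,
        hemisphere=rois[0].hemisphere,
        center_mm=tuple(centers.mean(axis=0)),
        radius_mm=rois[0].radius_mm,
    )


def _roi_mean(map_: np.ndarray, mask: np.ndarray) -> float:
    return float(map_[mask].mean())


def extract_alps_inputs(maps, rois: list[ROISpec]) -> dict[str, ALPSInputs]:
    """Extract ROI-mean directional diffusivities per hemisphere.

    ``maps`` is a :class:`~dtialps.tensor.TensorMaps`. For each hemisphere
    with both a projection and an association ROI:
    Dxx_proj / Dyy_proj over the projection mask, Dxx_assoc / Dzz_assoc
    over the association mask.
    """
    by_key = {}
    for roi in rois:
        key = (roi.label, roi.hemisphere)
        if key in by_key:
            raise ValueError(f"duplicate ROI for {key}")
        by_key[key] = roi

    out: dict[str, ALPSInputs] = {}
    for hemi in HEMISPHERES:
        proj = by_key.get(("projection", hemi))
        assoc = by_key.get(("association", hemi))
        if proj is None and assoc is None:
            continue
        if proj is None or assoc is None:
            raise ValueError(f"hemisphere {hemi}: need both projection and association ROIs")
        m_proj = sphere_mask(proj, maps.affine, maps.dxx.shape)
        m_assoc = sphere_mask(assoc, maps.affine, maps.dxx.shape)
        try:
            out[hemi] = ALPSInputs(
                dxx_proj=_roi_mean(maps.dxx, m_proj),
                dxx_assoc=_roi_mean(maps.dxx, m_assoc),
                dyy_proj=_roi_mean(maps.dyy, m_proj),
                dzz_assoc=_roi_mean(maps.dzz, m_assoc),
            )
        except ValueError as exc:
            raise ValueError(f"hemisphere {hemi}: degenerate ROI diffusivities ({exc})") from exc
    if not out:
        raise ValueError("no complete hemisphere ROI pair supplied")
    return out


def alps_index(inputs: ALPSInputs) -> float:
    """mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    num = 0.5 * (inputs.dxx_proj + inputs.dxx_assoc)
    den = 0.5 * (inputs.dyy_proj + inputs.dzz_assoc)
    return num / den


def bilateral_alps(l_alps: float, r_alps: float) -> float:
    """Unweighted mean of the two hemispheric indices."""
    if l_alps is None or r_alps is None:
        raise ValueError("both hemispheres required for the bilateral index")
    if l_alps <= 0 or r_alps <= 0:
        raise ValueError("ALPS indices must be positive")
    return 0.5 * (l_alps + r_alps)


def compute_alps(maps, rois: list[ROISpec], subject_id: str = "subject") -> ALPSResult:
    """Full per-subject ALPS computation from tensor maps and four ROIs.

    Also records per-ROI voxel counts and the mean FA over all ROIs (the
    summary FA feature later fed to the classifier).
    """
    inputs = extract_alps_inputs(maps, rois)
    if set(inputs) != set(HEMISPHERES):
        raise ValueError("compute_alps needs ROIs for both hemispheres")
    l_alps = alps_index(inputs["L"])
    r_alps = alps_index(inputs["R"])

    counts: dict[str, int] = {}
    fa_vals = []
    for roi in rois:
        m = sphere_mask(roi, maps.affine, maps.dxx.shape)
        counts[f"{roi.label}_{roi.hemisphere}"] = int(m.sum())
        fa_vals.append(maps.fa[m])
    fa_mean = float(np.concatenate(fa_vals).mean())

    return ALPSResult(
        subject_id=subject_id,
        l_alps=l_alps,
        r_alps=r_alps,
        bi_alps=bilateral_alps(l_alps, r_alps),
        inputs=inputs,
        roi_voxel_counts=counts,
        fa_mean=fa_mean,
    )
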