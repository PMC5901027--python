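"""Cylindrical ablation-zone modelling and per-ROI volumetrics.

The expected ablation cavity is modelled as a finite, flat-capped cylinder
dilated around the trajectory (default diameter 15 mm, the conservative
maximum of a 5–20 mm capable device).  By default the cylinder runs from
the target forward... strictly: the distal cap sits at the target and the
proximal cap at the trajectory's crossing of the tectal coronal plane, since
only hippocampus anterior to the tectal plate is considered for ablation.
Volumetrics intersect the voxelized zone with each ROI and report absolute
and percentage ablation, the residual unablated depth of the mesial
hippocampal head (MHH), and the grey-matter fraction of the cavity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .anatomy import RoiMask
from .geometry import box_slices, subgrid_world, unit
from .metrics import Trajectory

__all__ = [
    "AblationZone",
    "AblationReport",
    "ablation_zone",
    "roi_overlap_volumes",
    "residual_mhh_depth",
    "achieved_cavity_report",
    "supersampled_zone_volume",
]

DIAMETER_RANGE = (5.0, 20.0)  # mm, device capability
DEFAULT_DIAMETER = 15.0       # mm, conservative model diameter

#: ROI order of the volumetric report; AHC = amygdala + (truncated) hippocampus.
REPORT_ROLES = ("amygdala", "hippocampus", "entorhinal_cortex", "parahippocampal_gyrus")


@dataclass
class AblationZone:
    """A finite flat-capped cylinder around a trajectory, voxelized."""

    axis: Trajectory
    diameter: float
    proximal_limit: np.ndarray
    distal_limit: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = DIAMETER_RANGE
        if not lo <= self.diameter <= hi:
            raise ValueError(f"ablation diameter must lie in [{lo}, {hi}] mm")
        if np.allclose(self.proximal_limit, self.distal_limit):
            raise ValueError("proximal and distal limits coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal_limit - self.proximal_limit))

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * float(abs(np.linalg.det(self.affine[:3, :3])))


def _cylinder_predicate(x, y, z, proximal, distal, radius):
    u = unit(distal - proximal)
    span = float(np.linalg.norm(distal - proximal))
    dx, dy, dz = x - proximal[0], y - proximal[1], z - proximal[2]
    axial = dx * u[0] + dy * u[1] + dz * u[2]
    r2 = dx * dx + dy * dy + dz * dz - axial * axial
    return (axial >= 0.0) & (axial <= span) & (r2 <= radius * radius + 1e-9)


def ablation_zone(traj: Trajectory, volume_like, diameter: float = DEFAULT_DIAMETER,
                  extent: str = "tectal", tectal_plane_y: Optional[float] = None,
                  length: Optional[float] = None) -> AblationZone:
    """Voxelize the expected ablation cylinder on the model grid.

    ``volume_like`` supplies the grid (anything with ``.data``/``.mask`` and
    ``.affine``).  ``extent="tectal"`` places the proximal cap where the
    trajectory crosses the coronal tectal plane (``tectal_plane_y``);
    ``extent="length"`` places it ``length`` mm behind the target.  A voxel
    belongs to the zone iff its centre is within ``diameter/2`` of the axis
    and between the two flat cap planes.
    """
    lo, hi = DIAMETER_RANGE
    if not lo <= diameter <= hi:
        raise ValueError(f"ablation diameter must lie in [{lo}, {hi}] mm")

    affine = np.asarray(volume_like.affine, dtype=float)
    grid = getattr(volume_like, "data", None)
    if grid is None:
        grid = volume_like.mask
    shape = grid.shape

    target = np.asarray(traj.target, dtype=float)
    d = traj.direction
    if extent == "tectal":
        if tectal_plane_y is None:
            raise ValueError("extent='tectal' requires tectal_plane_y")
        if abs(d[1]) < 1e-9:
            raise ValueError(
                "trajectory runs parallel to the tectal plane; use extent='length'")
        # arc length from target, moving back toward the entry, to reach the plane
        t_back = (target[1] - float(tectal_plane_y)) / d[1]
        if t_back <= 0:
            raise ValueError(
                "trajectory does not cross the tectal plane behind the target; "
                "use extent='length'")
        proximal = target - d * t_back
    elif extent == "length":
        if length is None or length <= 0:
            raise ValueError("extent='length' requires a positive length")
        proximal = target - d * float(length)
    else:
        raise ValueError("extent must be 'tectal' or 'length'")

    radius = diameter / 2.0
    lo_w = np.minimum(proximal, target) - radius
    hi_w = np.maximum(proximal, target) + radius
    slc = box_slices(shape, affine, lo_w, hi_w, margin=1.0)
    mask = np.zeros(shape, dtype=bool)
    if all(s.stop > s.start for s in slc):
        x, y, z = subgrid_world(affine, slc)
        mask[slc] = _cylinder_predicate(x, y, z, proximal, target, radius)

    return AblationZone(axis=traj, diameter=float(diameter), proximal_limit=proximal,
                        distal_limit=target, mask=mask, affine=affine)


def supersampled_zone_volume(zone: AblationZone, n: int = 5) -> float:
    """Zone volume with each voxel split into ``n``^3 subsamples (test oracle)."""
    affine = zone.affine
    spacing_signs = affine[:3, :3]
    radius = zone.diameter / 2.0
    lo_w = np.minimum(zone.proximal_limit, zone.distal_limit) - radius
    hi_w = np.maximum(zone.proximal_limit, zone.distal_limit) + radius
    slc = box_slices(zone.mask.shape, affine, lo_w, hi_w, margin=1.0)
    x, y, z = subgrid_world(affine, slc)
    offsets = (np.arange(n) + 0.5) / n - 0.5
    count = 0
    for oi in offsets:
        for oj in offsets:
            for ok in offsets:
                dx = spacing_signs[0, 0] * oi + spacing_signs[0, 1] * oj + spacing_signs[0, 2] * ok
                dy = spacing_signs[1, 0] * oi + spacing_signs[1, 1] * oj + spacing_signs[1, 2] * ok
                dz = spacing_signs[2, 0] * oi + spacing_signs[2, 1] * oj + spacing_signs[2, 2] * ok
                count += int(_cylinder_predicate(x + dx, y + dy, z + dz,
                                                 zone.proximal_limit, zone.distal_limit,
                                                 radius).sum())
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    return count * voxel_volume / n**3


@dataclass
class AblationReport:
    """Per-ROI expected/achieved ablation volumetrics.

    ``table`` rows follow the conventional layout: amygdala, hippocampus
    (tectal-truncated), AHC, entorhinal cortex, parahippocampal gyrus, then
    a total over the four individual structures.
    """

    table: pd.DataFrame
    ablation_zone_volume_mm3: float
    gray_fraction: Optional[float] = None
    residual_mhh_depth_mm: Optional[float] = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.2f")

    def row(self, role: str) -> pd.Series:
        hit = self.table[self.table["role"] == role]
        if hit.empty:
            raise KeyError(f"no row for role {role!r}")
        return hit.iloc[0]


def _overlap_report(cavity_mask: np.ndarray, cavity_affine: np.ndarray,
                    rois: dict[str, RoiMask]) -> AblationReport:
    voxel_volume = float(abs(np.linalg.det(np.asarray(cavity_affine)[:3, :3])))
    rows = []
    for role in REPORT_ROLES:
        roi = rois.get(role)
        if roi is None:
            continue
        if roi.mask.shape != cavity_mask.shape or not np.allclose(roi.affine, cavity_affine):
            raise ValueError(f"ROI {role!r} is not on the ablation-zone grid")
        ablated = float((roi.mask & cavity_mask).sum()) * voxel_volume
        anatomical = roi.volume_mm3
        pct = 100.0 * ablated / anatomical if anatomical > 0 else 0.0
        rows.append({"role": role, "anatomical_volume_mm3": anatomical,
                     "ablated_volume_mm3": ablated, "percent_ablated": pct})
    extra = {r: m for r, m in rois.items() if r not in REPORT_ROLES}
    for role, roi in extra.items():
        ablated = float((roi.mask & cavity_mask).sum()) * voxel_volume
        pct = 100.0 * ablated / roi.volume_mm3 if roi.volume_mm3 > 0 else 0.0
        rows.append({"role": role, "anatomical_volume_mm3": roi.volume_mm3,
                     "ablated_volume_mm3": ablated, "percent_ablated": pct})

    df = pd.DataFrame(rows)
    by_role = {r["role"]: r for r in rows}
    ordered = []
    for role in ("amygdala", "hippocampus"):
        if role in by_role:
            ordered.append(by_role[role])
    if "amygdala" in by_role and "hippocampus" in by_role:
        anat = by_role["amygdala"]["anatomical_volume_mm3"] + by_role["hippocampus"]["anatomical_volume_mm3"]
        abl = by_role["amygdala"]["ablated_volume_mm3"] + by_role["hippocampus"]["ablated_volume_mm3"]
        ordered.append({"role": "ahc", "anatomical_volume_mm3": anat,
                        "ablated_volume_mm3": abl,
                        "percent_ablated": 100.0 * abl / anat if anat > 0 else 0.0})
    for role in df["role"]:
        if role not in ("amygdala", "hippocampus"):
            ordered.append(by_role[role])
    individual = [by_role[r] for r in REPORT_ROLES if r in by_role]
    anat_tot = sum(r["anatomical_volume_mm3"] for r in individual)
    abl_tot = sum(r["ablated_volume_mm3"] for r in individual)
    ordered.append({"role": "total", "anatomical_volume_mm3": anat_tot,
                    "ablated_volume_mm3": abl_tot,
                    "percent_ablated": 100.0 * abl_tot / anat_tot if anat_tot > 0 else 0.0})

    cavity_volume = float(cavity_mask.sum()) * voxel_volume
    gray = abl_tot / cavity_volume if cavity_volume > 0 else 0.0
    return AblationReport(table=pd.DataFrame(ordered),
                          ablation_zone_volume_mm3=cavity_volume,
                          gray_fraction=gray)


def roi_overlap_volumes(zone: AblationZone, rois: dict[str, RoiMask]) -> AblationReport:
    """Per-ROI volume inside the modelled cylinder (pass the truncated hippocampus)."""
    return _overlap_report(zone.mask, zone.affine, rois)


def achieved_cavity_report(cavity: RoiMask, rois: dict[str, RoiMask]) -> AblationReport:
    """Same volumetrics against a manually segmented (achieved) cavity mask.

    Also reports the grey-matter fraction: total ROI volume inside the
    cavity over the cavity volume.
    """
    if not cavity.mask.any():
        warnings.warn("achieved cavity mask is empty; report is all zeros", stacklevel=2)
    return _overlap_report(cavity.mask, cavity.affine, rois)


def residual_mhh_depth(head: RoiMask, zone: AblationZone, side: str) -> float:
    """Maximum unablated medial depth of the mesial hippocampal head (mm).

    For every coronal slice intersecting the head: start at the medial-most
    head voxel and walk laterally along x until the first ablated head
    voxel; the slice residual is the walked distance (0 when the medial-most
    voxel is ablated, the full medial–lateral extent when nothing in the
    slice is ablated).  The reported depth is the maximum slice residual.
    Requires an axis-aligned affine.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not head.mask.any():
        raise ValueError("hippocampal head mask is empty")
    aff = np.asarray(head.affine, dtype=float)
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0.0, atol=1e-6):
        raise NotImplementedError("residual_mhh_depth requires an axis-aligned affine")
    dx = aff[0, 0]

    def world_x(i):
        return aff[0, 0] * i + aff[0, 3]

    ablated = head.mask & zone.mask
    worst = 0.0
    for j in np.unique(np.argwhere(head.mask)[:, 1]):
        cols = np.unique(np.argwhere(head.mask[:, j, :])[:, 0])
        xs = world_x(cols.astype(float))
        # medial = toward x=0: max world x on the left, min on the right
        medial_first = np.argsort(-xs) if side == "left" else np.argsort(xs)
        cols_m = cols[medial_first]
        xs_m = xs[medial_first]
        abl_cols = set(np.unique(np.argwhere(ablated[:, j, :])[:, 0]).tolist())
        residual = None
        for c, x in zip(cols_m, xs_m):
            if int(c) in abl_cols:
                residual = abs(xs_m[0] - x)
                break
        if residual is None:
            residual = abs(xs_m[0] - xs_m[-1]) + abs(dx)
        worst = max(worst, float(residual))
    return worst
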