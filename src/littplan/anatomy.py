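"""Anatomical substrate: label volumes, ROI masks, distance fields, skull model.

A :class:`LabelVolume` is a 3D integer parcellation plus a voxel→world affine
and a *role map* assigning anatomical roles (``"amygdala"``, ``"critical"``,
...) to sets of label IDs.  Everything downstream — safety metrics, planning,
ablation volumetrics — consumes role masks and Euclidean distance fields
derived from it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import (
    spacing_from_affine,
    subgrid_world,
    unit,
    voxel_to_world,
    world_to_voxel,
)

log = logging.getLogger(__name__)

#: Roles that must be present (and non-empty) for planning to be possible.
REQUIRED_ROLES = ("amygdala", "hippocampus", "ventricles", "critical", "skull", "brain")

#: Entry-gyrus roles in the default fallback priority order.
ENTRY_ROLES = ("inferior_occipital", "middle_occipital", "posterior_middle_temporal")


class LoadError(ValueError):
    """Raised when a label volume or its role map cannot be used."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class LabelVolume:
    """3D integer label grid with a RAS+ affine and a role map.

    ``role_map`` maps role strings to disjoint sets of label IDs; a role may
    map to several labels (e.g. two sulcal labels both filling the
    ``"critical"`` role).
    """

    data: np.ndarray
    affine: np.ndarray
    role_map: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integer label IDs")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise LoadError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise LoadError("voxel spacing must be positive on all axes")
        self.role_map = {r: frozenset(int(v) for v in ids) for r, ids in self.role_map.items()}
        seen: set[int] = set()
        for role, ids in self.role_map.items():
            if seen & ids:
                raise LoadError(f"role {role!r} shares label IDs with another role")
            seen |= ids

    @property
    def spacing(self) -> np.ndarray:
        return spacing_from_affine(self.affine)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mask(self, role: str) -> np.ndarray:
        if role not in self.role_map:
            raise KeyError(f"unknown role {role!r}")
        ids = sorted(self.role_map[role])
        if not ids:
            return np.zeros(self.data.shape, dtype=bool)
        return np.isin(self.data, ids)

    def world_y(self) -> np.ndarray:
        """World y (anterior) coordinate of every voxel centre."""
        _, y, _ = subgrid_world(self.affine, tuple(slice(0, n) for n in self.data.shape))
        return y

    def intracranial_mask(self) -> np.ndarray:
        """All labelled tissue except the skull (brain + structures + patches)."""
        skull = self.role_map.get("skull", frozenset())
        ids = sorted(set().union(*self.role_map.values()) - skull)
        return np.isin(self.data, ids)


@dataclass
class RoiMask:
    """Boolean mask of one anatomical role on a label-volume grid."""

    role: str
    mask: np.ndarray
    affine: np.ndarray
    volume_mm3: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        self.volume_mm3 = float(self.mask.sum()) * float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def spacing(self) -> np.ndarray:
        return spacing_from_affine(self.affine)

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of all true voxels, shape ``(n, 3)``."""
        return voxel_to_world(self.affine, np.argwhere(self.mask))

    def centroid_world(self) -> np.ndarray:
        if not self.mask.any():
            raise ValueError(f"role {self.role!r} has an empty mask")
        return self.voxel_centers_world().mean(axis=0)

    def with_mask(self, mask: np.ndarray, role: Optional[str] = None) -> "RoiMask":
        return RoiMask(role or self.role, mask, self.affine)


@dataclass
class DistanceField:
    """Euclidean distance (mm) from each voxel centre to a source structure.

    The field is the anisotropy-aware exact Euclidean distance transform of
    the source complement; it is zero exactly on source voxels and
    1-Lipschitz with respect to world distance.  :meth:`at` samples it at
    arbitrary world points by trilinear interpolation.
    """

    source_role: str
    field: np.ndarray
    affine: np.ndarray

    def at(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        ijk = world_to_voxel(self.affine, pts)
        vals = ndimage.map_coordinates(self.field, ijk.T, order=1, mode="nearest")
        return vals if np.asarray(points_world).ndim > 1 else float(vals[0])


class SkullModel:
    """Inner/outer skull surfaces as signed distance functions.

    ``sd_inner``/``sd_outer`` are negative inside the respective surface and
    positive outside.  The outward surface normal is the normalized
    finite-difference gradient of the signed distance.  Two backends exist:
    a voxel backend built from skull/brain masks and an analytic sphere
    (the synthetic phantom's skull), which makes closed-form checks of
    intracerebral length and drilling angle exact.
    """

    def __init__(self, sd_inner, sd_outer, inner_mask=None, outer_mask=None,
                 normal_step: float = 0.5):
        self._sd_inner = sd_inner
        self._sd_outer = sd_outer
        self.inner_mask = inner_mask
        self.outer_mask = outer_mask
        self._h = float(normal_step)

    # -- constructors -------------------------------------------------

    @classmethod
    def sphere(cls, center, inner_radius: float, outer_radius: float) -> "SkullModel":
        if not 0 < inner_radius < outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        c = np.asarray(center, dtype=float)

        def make(radius):
            def sd(points):
                pts = np.atleast_2d(np.asarray(points, dtype=float))
                vals = np.linalg.norm(pts - c, axis=-1) - radius
                return vals if np.asarray(points).ndim > 1 else float(vals[0])
            return sd

        return cls(make(inner_radius), make(outer_radius))

    @classmethod
    def from_masks(cls, inner_solid: np.ndarray, outer_solid: np.ndarray,
                   affine: np.ndarray) -> "SkullModel":
        """Build from filled solids: intracranial cavity and skull-enclosed head."""
        spacing = spacing_from_affine(affine)

        def signed(solid):
            solid = np.asarray(solid, dtype=bool)
            outside = ndimage.distance_transform_edt(~solid, sampling=spacing)
            inside = ndimage.distance_transform_edt(solid, sampling=spacing)
            sd_grid = outside - inside

            def sd(points):
                pts = np.atleast_2d(np.asarray(points, dtype=float))
                ijk = world_to_voxel(affine, pts)
                vals = ndimage.map_coordinates(sd_grid, ijk.T, order=1, mode="nearest")
                return vals if np.asarray(points).ndim > 1 else float(vals[0])
            return sd

        return cls(signed(inner_solid), signed(outer_solid),
                   inner_mask=np.asarray(inner_solid, bool),
                   outer_mask=np.asarray(outer_solid, bool))

    # -- queries ------------------------------------------------------

    def sd_inner(self, points):
        return self._sd_inner(points)

    def sd_outer(self, points):
        return self._sd_outer(points)

    def outer_normal(self, point) -> np.ndarray:
        """Outward unit normal of the outer surface near ``point``."""
        p = np.asarray(point, dtype=float)
        h = self._h
        grad = np.empty(3)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[ax] = (float(self._sd_outer(p + e)) - float(self._sd_outer(p - e))) / (2 * h)
        return unit(grad)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def load_label_volume(image_path, labelmap_path) -> LabelVolume:
    """Read a NIfTI label image and its ``{label_int: role}`` JSON map.

    Raises :class:`LoadError` for non-integral voxel data, a singular affine,
    or a required role that is missing from the map; roles mapped to zero
    voxels are logged but tolerated.
    """
    img = nib.load(str(image_path))
    raw = np.asanyarray(img.dataobj)
    rounded = np.rint(raw)
    if not np.allclose(raw, rounded, atol=1e-6):
        raise LoadError(f"{image_path}: voxel values are not integral label IDs")
    data = rounded.astype(np.int32)

    with open(labelmap_path) as fh:
        label_to_role = json.load(fh)
    role_map: dict[str, set[int]] = {}
    for label, role in label_to_role.items():
        role_map.setdefault(str(role), set()).add(int(label))

    for role in REQUIRED_ROLES:
        if role not in role_map:
            raise LoadError(f"label map {labelmap_path} is missing required role {role!r}")

    vol = LabelVolume(data, img.affine, {r: frozenset(s) for r, s in role_map.items()})
    present = set(np.unique(data).tolist())
    for role, ids in vol.role_map.items():
        if not ids & present:
            log.warning("role %r maps to zero voxels in %s", role, image_path)
    return vol


def save_label_volume(volume: LabelVolume, image_path, labelmap_path) -> None:
    """Write the NIfTI image and the ``{label_int: role}`` JSON map."""
    img = nib.Nifti1Image(volume.data.astype(np.int16), volume.affine)
    nib.save(img, str(image_path))
    label_to_role = {str(label): role for role, ids in volume.role_map.items() for label in ids}
    Path(labelmap_path).write_text(json.dumps(label_to_role, indent=1, sort_keys=True))


def extract_roi(volume: LabelVolume, role: str) -> RoiMask:
    """Union of voxels whose label belongs to ``role``."""
    if role not in volume.role_map:
        raise ValueError(f"unknown role {role!r}; known: {sorted(volume.role_map)}")
    return RoiMask(role, volume.mask(role), volume.affine)


def distance_field(mask: RoiMask, volume: Optional[LabelVolume] = None) -> DistanceField:
    """Exact Euclidean distance transform (mm) from ``mask``.

    ``volume`` is accepted for interface symmetry; the grid geometry comes
    from the mask's own affine.
    """
    if not mask.mask.any():
        raise ValueError(f"distance field undefined for empty mask {mask.role!r}")
    fld = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
    return DistanceField(mask.role, fld, mask.affine)


def truncate_hippocampus(hipp: RoiMask, tectal_plane_y: float) -> RoiMask:
    """Keep only hippocampus voxels strictly anterior to the tectal plane.

    The tectal plate is supplied as a coronal world-y coordinate; anterior
    means greater y in RAS+.  May return an empty mask (with a warning) if
    the plane lies anterior to the whole structure.
    """
    idx = np.argwhere(hipp.mask)
    out = np.zeros_like(hipp.mask)
    if idx.size:
        y = voxel_to_world(hipp.affine, idx)[:, 1]
        keep = idx[y > float(tectal_plane_y)]
        out[tuple(keep.T)] = True
    if not out.any():
        warnings.warn(
            f"tectal plane y={tectal_plane_y} truncates the whole hippocampus", stacklevel=2
        )
    return hipp.with_mask(out)


def hippocampal_head(hipp: RoiMask, amygdala: RoiMask) -> RoiMask:
    """Hippocampal-head region used for the residual-depth metric.

    Defined as hippocampus voxels anterior to (or at) the coronal plane
    through the posterior border of the amygdala, i.e. world
    ``y >= min(y over amygdala voxels)``.
    """
    if not hipp.mask.any() or not amygdala.mask.any():
        raise ValueError("hippocampal_head needs non-empty hippocampus and amygdala")
    y_min = float(amygdala.voxel_centers_world()[:, 1].min())
    idx = np.argwhere(hipp.mask)
    y = voxel_to_world(hipp.affine, idx)[:, 1]
    out = np.zeros_like(hipp.mask)
    keep = idx[y >= y_min]
    out[tuple(keep.T)] = True
    if not out.any():
        warnings.warn("hippocampal head is empty (amygdala entirely anterior)", stacklevel=2)
    return hipp.with_mask(out, role="mesial_hippocampal_head")


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------


@dataclass
class HeadModel:
    """Everything the metric/planner/ablation layers need about one head.

    Optional fields may be ``None`` when the corresponding role is absent
    (e.g. the planar slab phantom has no amygdala); operations that need a
    missing component report a per-metric error instead of failing globally.
    """

    volume: LabelVolume
    skull: SkullModel
    side: str = "left"
    tectal_plane_y: Optional[float] = None
    amygdala: Optional[RoiMask] = None
    hippocampus_full: Optional[RoiMask] = None
    hippocampus: Optional[RoiMask] = None  # tectal-truncated; used everywhere
    ahc: Optional[RoiMask] = None
    mhh_head: Optional[RoiMask] = None
    ventricles: Optional[RoiMask] = None
    entorhinal: Optional[RoiMask] = None
    parahippocampal: Optional[RoiMask] = None
    critical_field: Optional[DistanceField] = None
    brainstem_field: Optional[DistanceField] = None
    intracranial: Optional[RoiMask] = None
    ahc_geom: object = None  # lazily attached by the metrics layer

    @classmethod
    def from_label_volume(cls, volume: LabelVolume, tectal_plane_y: Optional[float] = None,
                          side: Optional[str] = None,
                          skull: Optional[SkullModel] = None) -> "HeadModel":
        def roi(role):
            if role in volume.role_map and volume.mask(role).any():
                return extract_roi(volume, role)
            return None

        amygdala = roi("amygdala")
        hipp_full = roi("hippocampus")
        ventricles = roi("ventricles")
        critical = roi("critical")
        entorhinal = roi("entorhinal_cortex")
        phg = roi("parahippocampal_gyrus")
        brainstem = roi("brainstem")

        intracranial = RoiMask("intracranial", volume.intracranial_mask(), volume.affine)
        if skull is None:
            skull_mask = volume.mask("skull") if "skull" in volume.role_map else np.zeros_like(
                volume.data, dtype=bool)
            inner_solid = ndimage.binary_fill_holes(intracranial.mask)
            outer_solid = ndimage.binary_fill_holes(inner_solid | skull_mask)
            skull = SkullModel.from_masks(inner_solid, outer_solid, volume.affine)

        if side is None:
            if amygdala is None:
                raise ValueError("cannot infer side without an amygdala; pass side=")
            side = "right" if amygdala.centroid_world()[0] > 0 else "left"

        hipp_trunc = None
        if hipp_full is not None:
            if tectal_plane_y is not None:
                hipp_trunc = truncate_hippocampus(hipp_full, tectal_plane_y)
            else:
                hipp_trunc = hipp_full

        ahc = None
        if amygdala is not None and hipp_trunc is not None:
            ahc = RoiMask("ahc", amygdala.mask | hipp_trunc.mask, volume.affine)

        mhh = None
        if hipp_full is not None and amygdala is not None and hipp_full.mask.any():
            mhh = hippocampal_head(hipp_full, amygdala)

        return cls(
            volume=volume,
            skull=skull,
            side=side,
            tectal_plane_y=tectal_plane_y,
            amygdala=amygdala,
            hippocampus_full=hipp_full,
            hippocampus=hipp_trunc,
            ahc=ahc,
            mhh_head=mhh,
            ventricles=ventricles,
            entorhinal=entorhinal,
            parahippocampal=phg,
            critical_field=distance_field(critical) if critical is not None else None,
            brainstem_field=distance_field(brainstem) if brainstem is not None else None,
            intracranial=intracranial,
        )

    @classmethod
    def from_phantom(cls, volume: LabelVolume, ground_truth: dict) -> "HeadModel":
        """Bundle a synthetic phantom using its analytic skull geometry."""
        gt_skull = ground_truth["skull"]
        skull = SkullModel.sphere(gt_skull["center"], gt_skull["inner_radius"],
                                  gt_skull["outer_radius"])
        return cls.from_label_volume(
            volume,
            tectal_plane_y=ground_truth["tectal_plane_y"],
            side=ground_truth["side"],
            skull=skull,
        )

    def report_rois(self) -> dict[str, RoiMask]:
        """ROIs for ablation volumetrics (hippocampus tectal-truncated)."""
        rois = {}
        for name, roi in (
            ("amygdala", self.amygdala),
            ("hippocampus", self.hippocampus),
            ("entorhinal_cortex", self.entorhinal),
            ("parahippocampal_gyrus", self.parahippocampal),
        ):
            if roi is not None:
                rois[name] = roi
        return rois
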