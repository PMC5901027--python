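"""Synthetic parcellated head phantoms with analytic ground truth.

The phantom substitutes fully parametric geometry for a whole-brain MRI
parcellation: a spherical two-surface skull, an ellipsoidal amygdala, tube
(capsule-chain) models of the hippocampus, temporal/occipital ventricular
horn and parahippocampal gyrus, thin planar sheets standing in for sulci
(the critical-structure proxies for vasculature), a cylindrical brainstem,
and three angular surface patches representing the entry gyri (inferior
occipital, middle occipital, posterior middle temporal).

Geometry is expressed in RAS+ millimetres for a LEFT-sided pathology and
mirrored across the mid-sagittal plane for ``side="right"``.  The default
layout realizes the "posteroinferior corridor": a window between the
occipital horn of the lateral ventricle (above) and the collateral-sulcus
sheet (below) through which a straight path from the inferior occipital
gyrus can cannulate the long axis of the amygdalohippocampal complex.
Anatomical variants close this corridor by construction — a deep collateral
sulcus raises the sheet's dorsal edge; an enlarged occipital horn inflates
and lowers the posterior ventricle — forcing entry-gyrus fallback.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .anatomy import LabelVolume, SkullModel, save_label_volume
from .geometry import box_slices, segment_point_distance, subgrid_world, unit

__all__ = [
    "SheetSpec",
    "PatchSpec",
    "PhantomParams",
    "PhantomError",
    "generate_phantom",
    "generate_variant",
    "planar_risk_phantom",
    "write_phantom",
    "LABELS",
    "VARIANTS",
]


class PhantomError(ValueError):
    """Raised for degenerate phantom geometry, naming the offending structure."""


# label IDs -> anatomical roles (two sulcal sheets both fill "critical")
LABELS: dict[int, str] = {
    1: "brain",
    2: "skull",
    3: "amygdala",
    4: "hippocampus",
    5: "ventricles",
    6: "critical",
    7: "brainstem",
    8: "entorhinal_cortex",
    9: "parahippocampal_gyrus",
    10: "inferior_occipital",
    11: "middle_occipital",
    12: "posterior_middle_temporal",
    13: "critical",
}

VARIANTS = ("deep_collateral_sulcus", "enlarged_occipital_horn")


@dataclass(frozen=True)
class SheetSpec:
    """Thin sagittally oriented sheet: |x - x_center| <= thickness/2 in a y/z box."""

    name: str
    x_center: float
    y_range: tuple[float, float]
    z_range: tuple[float, float]
    thickness: float = 1.0


@dataclass(frozen=True)
class PatchSpec:
    """Angular sector of the brain surface representing an entry gyrus."""

    role: str
    direction: tuple[float, float, float]
    half_angle_deg: float = 5.0


def _default_sulci() -> list[SheetSpec]:
    return [
        SheetSpec("collateral_sulcus", -26.0, (-70.0, -25.0), (-60.0, -19.0)),
        SheetSpec("occipitotemporal_sulcus", -56.0, (-20.0, 10.0), (-35.0, 5.0)),
    ]


def _default_patches() -> list[PatchSpec]:
    return [
        PatchSpec("inferior_occipital", (-36.7, -72.6, -1.8)),
        PatchSpec("middle_occipital", (-52.0, -60.0, 12.0)),
        PatchSpec("posterior_middle_temporal", (-68.0, -42.0, -6.0)),
    ]


@dataclass(frozen=True)
class PhantomParams:
    """Full parametric description of the phantom (left-sided convention).

    All world coordinates are RAS+ millimetres for a left-sided pathology;
    ``side="right"`` mirrors every x coordinate at generation time.
    ``jitter_mm`` applies a seeded uniform perturbation to the soft-tissue
    centrelines and the amygdala centre, producing a family of distinct but
    reproducible subjects; it is off (0.0) by default.
    """

    grid_shape: tuple[int, int, int] = (192, 192, 192)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    side: str = "left"
    skull_outer_radius: float = 88.0
    skull_inner_radius: float = 82.0
    amygdala_center: tuple[float, float, float] = (-26.0, 8.0, -18.0)
    amygdala_radii: tuple[float, float, float] = (8.0, 7.0, 7.0)
    hippocampus_curve: tuple[tuple[float, float, float], ...] = (
        (-25.0, 3.0, -21.0), (-27.0, -12.0, -18.0), (-29.0, -25.0, -15.0),
        (-31.0, -38.0, -11.0), (-33.0, -50.0, -7.0),
    )
    hippocampus_radius: float = 5.0
    ventricle_curve: tuple[tuple[float, float, float], ...] = (
        (-29.0, -6.0, -8.0), (-30.0, -22.0, -9.0), (-33.0, -45.0, -2.0),
        (-35.0, -62.0, 4.0),
    )
    ventricle_radius: tuple[float, ...] = (3.5, 3.5, 3.5, 3.5)  # per curve node
    entorhinal_center: tuple[float, float, float] = (-19.0, 0.0, -26.0)
    entorhinal_radii: tuple[float, float, float] = (5.0, 9.0, 4.0)
    parahippocampal_curve: tuple[tuple[float, float, float], ...] = (
        (-24.0, 0.0, -30.0), (-27.0, -18.0, -26.0), (-30.0, -36.0, -22.0),
    )
    parahippocampal_radius: float = 5.0
    sulci_planes: tuple[SheetSpec, ...] = field(default_factory=lambda: tuple(_default_sulci()))
    brainstem_axis: tuple[tuple[float, float, float], ...] = ((0.0, -20.0, -48.0), (0.0, -16.0, -2.0))
    brainstem_radius: float = 8.0
    entry_patch_specs: tuple[PatchSpec, ...] = field(default_factory=lambda: tuple(_default_patches()))
    tectal_plane_y: float = -26.0
    seed: int = 0
    jitter_mm: float = 0.0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise PhantomError("side must be 'left' or 'right'")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError("voxel_spacing must be positive on all axes")
        if not 0 < self.skull_inner_radius < self.skull_outer_radius:
            raise PhantomError("need 0 < skull_inner_radius < skull_outer_radius")
        half = float(self.skull_outer_radius)
        extent = min(n * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_spacing))
        if half >= extent:
            raise PhantomError("skull does not fit inside the grid")

        def inside(name, points, reach):
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            r = np.linalg.norm(pts, axis=1) + reach
            if np.any(r >= self.skull_inner_radius):
                raise PhantomError(f"structure {name!r} is not strictly inside the inner skull")

        inside("amygdala", self.amygdala_center, max(self.amygdala_radii))
        inside("hippocampus", self.hippocampus_curve, self.hippocampus_radius)
        inside("ventricles", self.ventricle_curve, max(self.ventricle_radius))
        inside("entorhinal_cortex", self.entorhinal_center, max(self.entorhinal_radii))
        inside("parahippocampal_gyrus", self.parahippocampal_curve, self.parahippocampal_radius)
        inside("brainstem", self.brainstem_axis, self.brainstem_radius)
        if len(self.ventricle_radius) != len(self.ventricle_curve):
            raise PhantomError("ventricle_radius must give one radius per curve node")

        dirs = [unit(p.direction) for p in self.entry_patch_specs]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                ang = math.degrees(math.acos(float(np.clip(dirs[i] @ dirs[j], -1, 1))))
                lim = self.entry_patch_specs[i].half_angle_deg + self.entry_patch_specs[j].half_angle_deg
                if ang <= lim:
                    raise PhantomError(
                        f"entry patches {self.entry_patch_specs[i].role!r} and "
                        f"{self.entry_patch_specs[j].role!r} overlap")


# ---------------------------------------------------------------------------
# painting primitives
# ---------------------------------------------------------------------------


def _mirror(p, flip: bool):
    p = np.asarray(p, dtype=float)
    if flip:
        p = p * np.array([-1.0, 1.0, 1.0])
    return p


def _paint_capsules(data, affine, nodes, radii, label, clip=None):
    nodes = np.asarray(nodes, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(nodes),))
    for (a, b), (ra, rb) in zip(zip(nodes[:-1], nodes[1:]), zip(radii[:-1], radii[1:])):
        rmax = max(ra, rb)
        slc = box_slices(data.shape, affine, np.minimum(a, b) - rmax,
                         np.maximum(a, b) + rmax)
        if not all(s.stop > s.start for s in slc):
            continue
        x, y, z = subgrid_world(affine, slc)
        pts = np.stack([x, y, z], axis=-1)
        dist, t = segment_point_distance(pts, a, b)
        hit = dist <= (1 - t) * ra + t * rb
        if clip is not None:
            hit &= clip[slc]
        data[slc][hit] = label


def _paint_ellipsoid(data, affine, center, radii, label, clip=None):
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    slc = box_slices(data.shape, affine, center - radii, center + radii)
    x, y, z = subgrid_world(affine, slc)
    q = (((x - center[0]) / radii[0]) ** 2 + ((y - center[1]) / radii[1]) ** 2
         + ((z - center[2]) / radii[2]) ** 2)
    hit = q <= 1.0
    if clip is not None:
        hit &= clip[slc]
    data[slc][hit] = label


def _paint_sheet(data, affine, sheet: SheetSpec, flip: bool, label, clip=None):
    xc = -sheet.x_center if flip else sheet.x_center
    y0, y1 = sheet.y_range
    z0, z1 = sheet.z_range
    # a sheet thinner than one voxel still rasterizes to a one-voxel lamina
    dx = float(np.linalg.norm(affine[:3, 0]))
    half = max(sheet.thickness, dx) / 2.0
    lo = (xc - half, y0, z0)
    hi = (xc + half, y1, z1)
    slc = box_slices(data.shape, affine, lo, hi)
    if not all(s.stop > s.start for s in slc):
        return
    x, y, z = subgrid_world(affine, slc)
    hit = (np.abs(x - xc) <= half) & (y >= y0) & (y <= y1) & (z >= z0) & (z <= z1)
    if clip is not None:
        hit &= clip[slc]
    data[slc][hit] = label


def _capsule_chain_volume(nodes, radii) -> float:
    """Analytic volume of a chain of capsules (cylinders + end hemispheres).

    Exact for a straight chain of constant radius; for gently curved chains
    the junction error is small relative to the 5% agreement band.
    """
    nodes = np.asarray(nodes, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(nodes),))
    vol = 0.0
    for (a, b), (ra, rb) in zip(zip(nodes[:-1], nodes[1:]), zip(radii[:-1], radii[1:])):
        h = float(np.linalg.norm(b - a))
        r = 0.5 * (ra + rb)  # conical frustum approximated at mean radius
        vol += math.pi * r * r * h
    vol += (2.0 / 3.0) * math.pi * radii[0] ** 3 + (2.0 / 3.0) * math.pi * radii[-1] ** 3
    return vol


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _phantom_affine(params: PhantomParams) -> np.ndarray:
    shape = np.asarray(params.grid_shape, dtype=float)
    spacing = np.asarray(params.voxel_spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing  # head centred on the world origin
    return affine


def _jittered(params: PhantomParams):
    """Seeded perturbation of soft-tissue geometry; identity when jitter is 0."""
    rng = np.random.default_rng(params.seed)

    def wob(points):
        pts = np.asarray(points, dtype=float)
        if params.jitter_mm > 0:
            pts = pts + rng.uniform(-params.jitter_mm, params.jitter_mm, size=pts.shape)
        return pts

    return {
        "amygdala_center": wob(params.amygdala_center),
        "hippocampus_curve": wob(params.hippocampus_curve),
        "ventricle_curve": wob(params.ventricle_curve),
        "parahippocampal_curve": wob(params.parahippocampal_curve),
    }


def generate_phantom(params: PhantomParams = PhantomParams()) -> tuple[LabelVolume, dict]:
    """Generate the label volume and its analytic ground truth.

    Deterministic for fixed parameters and seed.  Later structures take
    precedence where geometry overlaps (the amygdala is painted after the
    hippocampal head it abuts, so its voxel volume stays analytic; sulcal
    sheets are painted last among tissue so the critical-structure geometry
    is never eroded by neighbours).
    """
    params.validate()
    flip = params.side == "right"
    affine = _phantom_affine(params)
    shape = tuple(int(n) for n in params.grid_shape)
    jit = _jittered(params)

    x, y, z = subgrid_world(affine, tuple(slice(0, n) for n in shape))
    r = np.sqrt(x * x + y * y + z * z)

    data = np.zeros(shape, dtype=np.int16)
    brain = r < params.skull_inner_radius
    data[brain] = 1

    _paint_capsules(data, affine, [_mirror(p, flip) for p in jit["parahippocampal_curve"]],
                    params.parahippocampal_radius, 9, clip=brain)
    _paint_ellipsoid(data, affine, _mirror(params.entorhinal_center, flip),
                     params.entorhinal_radii, 8, clip=brain)
    _paint_capsules(data, affine, [_mirror(p, flip) for p in jit["hippocampus_curve"]],
                    params.hippocampus_radius, 4, clip=brain)
    _paint_capsules(data, affine, [_mirror(p, flip) for p in jit["ventricle_curve"]],
                    params.ventricle_radius, 5, clip=brain)
    amy_center = _mirror(jit["amygdala_center"], flip)
    _paint_ellipsoid(data, affine, amy_center, params.amygdala_radii, 3, clip=brain)
    _paint_capsules(data, affine, [_mirror(p, flip) for p in params.brainstem_axis],
                    params.brainstem_radius, 7, clip=brain)

    # entry patches on the outermost brain shell
    shell = brain & (r >= params.skull_inner_radius - 1.6)
    rn = np.where(r > 0, r, 1.0)
    for spec, label in zip(params.entry_patch_specs, (10, 11, 12)):
        d = unit(_mirror(spec.direction, flip))
        cosang = (x * d[0] + y * d[1] + z * d[2]) / rn
        patch = shell & (cosang >= math.cos(math.radians(spec.half_angle_deg)))
        if not patch.any():
            raise PhantomError(f"entry patch {spec.role!r} is empty")
        data[patch] = label

    # sulcal sheets last among tissue: critical geometry must not be eroded
    for i, spec in enumerate(params.sulci_planes):
        _paint_sheet(data, affine, spec, flip, 6 if i == 0 else 13, clip=brain)

    skull = (~brain) & (r <= params.skull_outer_radius)
    data[skull] = 2

    role_map: dict[str, set[int]] = {}
    for label, role in LABELS.items():
        role_map.setdefault(role, set()).add(label)
    volume = LabelVolume(data, affine, {r_: frozenset(s) for r_, s in role_map.items()})

    present = set(int(v) for v in np.unique(data))
    for role, labels in volume.role_map.items():
        if not labels & present:
            raise PhantomError(f"structure {role!r} is empty")

    voxvol = volume.voxel_volume
    voxel_volumes = {LABELS[lab]: 0.0 for lab in LABELS}
    for lab in present - {0}:
        voxel_volumes[LABELS[int(lab)]] += float((data == lab).sum()) * voxvol

    tectal_y = params.tectal_plane_y
    ground_truth = {
        "side": params.side,
        "seed": params.seed,
        "jitter_mm": params.jitter_mm,
        "tectal_plane_y": tectal_y,
        "skull": {"center": [0.0, 0.0, 0.0],
                  "inner_radius": params.skull_inner_radius,
                  "outer_radius": params.skull_outer_radius},
        "amygdala": {
            "center": [float(v) for v in amy_center],
            "radii": list(params.amygdala_radii),
            "analytic_volume_mm3": 4.0 / 3.0 * math.pi * float(np.prod(params.amygdala_radii)),
        },
        "analytic_volumes_mm3": {
            "amygdala": 4.0 / 3.0 * math.pi * float(np.prod(params.amygdala_radii)),
            "ventricles": _capsule_chain_volume(jit["ventricle_curve"], params.ventricle_radius),
            "brainstem": _capsule_chain_volume(params.brainstem_axis, params.brainstem_radius),
        },
        "voxel_volumes_mm3": voxel_volumes,
        "hippocampus_curve": [[float(v) for v in _mirror(p, flip)]
                              for p in jit["hippocampus_curve"]],
        "hippocampus_radius": params.hippocampus_radius,
        "ventricle_curve": [[float(v) for v in _mirror(p, flip)]
                            for p in jit["ventricle_curve"]],
    }
    return volume, ground_truth


def generate_variant(params: PhantomParams, variant: str,
                     severity: float = 1.0) -> tuple[LabelVolume, dict]:
    """Generate an anatomical variant closing the posteroinferior corridor.

    ``severity`` scales the deviation from the base anatomy; 0 reproduces
    the base phantom exactly, 1 is the default fully blocking variant.
    """
    if variant not in VARIANTS:
        raise PhantomError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    s = float(severity)
    if s < 0:
        raise PhantomError("severity must be non-negative")

    if variant == "deep_collateral_sulcus":
        sheets = []
        for spec in params.sulci_planes:
            if spec.name == "collateral_sulcus":
                z0, z1 = spec.z_range
                y0, y1 = spec.y_range
                sheets.append(replace(spec, z_range=(z0, z1 + 17.0 * s),
                                      y_range=(y0, y1 + 17.0 * s)))
            else:
                sheets.append(spec)
        new = replace(params, sulci_planes=tuple(sheets))
    else:  # enlarged_occipital_horn
        radii = list(params.ventricle_radius)
        curve = [list(p) for p in params.ventricle_curve]
        for i in (-2, -1):  # posterior (occipital-horn) nodes
            radii[i] = radii[i] + 5.5 * s
            curve[i][2] -= 6.0 * s
        new = replace(params, ventricle_radius=tuple(radii),
                      ventricle_curve=tuple(tuple(p) for p in curve))

    volume, gt = generate_phantom(new)
    gt["variant"] = {"name": variant, "severity": s}
    return volume, gt


# ---------------------------------------------------------------------------
# planar slab phantom (single critical sheet)
# ---------------------------------------------------------------------------


def planar_risk_phantom(grid: int = 161, inner_radius: float = 70.0,
                        outer_radius: float = 76.0,
                        spacing: float = 1.0) -> tuple[LabelVolume, SkullModel]:
    """Spherical head with exactly one planar critical structure at x = 0.

    Voxel centres sit on integer millimetres (odd grid), so the distance
    field of the mid-sagittal sheet is exact under trilinear interpolation —
    the geometry of choice for measuring threshold behaviour of the
    feasibility filter.  A small ventricular blob is parked far from the
    mid-plane so the exclusion check is exercised but never triggered near
    the sheet.
    """
    if grid % 2 == 0:
        raise ValueError("grid must be odd so voxel centres land on integers")
    shape = (grid, grid, grid)
    affine = np.eye(4)
    affine[:3, :3] = np.diag([spacing] * 3)
    affine[:3, 3] = -(grid - 1) / 2.0 * spacing

    x, y, z = subgrid_world(affine, tuple(slice(0, n) for n in shape))
    r = np.sqrt(x * x + y * y + z * z)

    data = np.zeros(shape, dtype=np.int16)
    brain = r < inner_radius
    data[brain] = 1
    sheet = brain & (np.abs(x) < spacing / 2.0)
    data[sheet] = 6
    blob = brain & (np.sqrt(x * x + (y - 40) ** 2 + (z - 40) ** 2) <= 4.0)
    data[blob] = 5
    skull = (~brain) & (r <= outer_radius)
    data[skull] = 2

    role_map = {"brain": frozenset({1}), "skull": frozenset({2}),
                "critical": frozenset({6}), "ventricles": frozenset({5})}
    volume = LabelVolume(data, affine, role_map)
    skull_model = SkullModel.sphere((0.0, 0.0, 0.0), inner_radius, outer_radius)
    return volume, skull_model


def write_phantom(outdir, volume: LabelVolume, ground_truth: dict) -> dict[str, Path]:
    """Write NIfTI image, label map and ground truth JSONs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / "phantom.nii.gz",
        "labelmap": outdir / "labelmap.json",
        "ground_truth": outdir / "ground_truth.json",
    }
    save_label_volume(volume, paths["image"], paths["labelmap"])
    paths["ground_truth"].write_text(json.dumps(ground_truth, indent=1))
    return paths
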