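"""Safety metrics for straight stereotactic trajectories.

The bundle computed here mirrors what an automated laser-trajectory planner
reports for each candidate path: intracerebral length (from the inner skull
crossing to the target), drilling angle against the outer skull normal,
minimum distance from critical structures (sulci standing in for
vasculature), a cumulative risk integral, contact with the centre of the
amygdalohippocampal complex (AHC), distance from the brainstem, and whether
the path violates the ventricular exclusion zone.

Risk model: a point at distance ``d`` from the nearest critical structure
carries risk 1 when ``d <= d_lo`` (default 3 mm), risk 0 when ``d >= d_hi``
(default 10 mm) and ramps linearly in between.  The overall risk of a
trajectory is the path integral of this pointwise risk along the
intracerebral segment, divided by a fixed normalization length (10 mm), so
values above 1 are possible for long, close passages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .anatomy import DistanceField, HeadModel, RoiMask, SkullModel
from .geometry import unit, world_to_voxel

__all__ = [
    "Trajectory",
    "RiskParams",
    "TrajectoryMetrics",
    "intracerebral_length",
    "drilling_angle",
    "pointwise_risk",
    "overall_risk",
    "min_critical_distance",
    "ahc_center_proportion",
    "brainstem_distance",
    "compute_metrics",
    "AhcGeometry",
]


@dataclass(frozen=True)
class Trajectory:
    """Straight path from a scalp-side entry point to an intracerebral target."""

    entry: tuple[float, float, float]
    target: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.entry, dtype=float)
        t = np.asarray(self.target, dtype=float)
        if e.shape != (3,) or t.shape != (3,):
            raise ValueError("entry and target must be 3-vectors")
        if np.allclose(e, t):
            raise ValueError("entry and target coincide")
        object.__setattr__(self, "entry", tuple(float(v) for v in e))
        object.__setattr__(self, "target", tuple(float(v) for v in t))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector pointing from entry toward target."""
        return unit(np.asarray(self.target) - np.asarray(self.entry))

    def point_at(self, dist_from_entry: float) -> np.ndarray:
        return np.asarray(self.entry) + self.direction * float(dist_from_entry)


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the risk ramp and trajectory sampling."""

    d_lo: float = 3.0          # mm; at or below this a point has risk 1
    d_hi: float = 10.0         # mm; at or above this a point has risk 0
    sample_step: float = 1.0   # mm between samples along the trajectory
    norm_length: float = 10.0  # mm; overall risk = integral / norm_length
    safety_margin: float = 3.0  # mm planning clearance from critical structures

    def __post_init__(self) -> None:
        if not 0 < self.d_lo < self.d_hi:
            raise ValueError("need 0 < d_lo < d_hi")
        if self.sample_step <= 0 or self.norm_length <= 0:
            raise ValueError("sample_step and norm_length must be positive")


@dataclass
class TrajectoryMetrics:
    """Safety-metric bundle for one trajectory; None marks a failed metric."""

    intracerebral_length: Optional[float] = None
    drilling_angle: Optional[float] = None
    min_critical_distance: Optional[float] = None
    overall_risk: Optional[float] = None
    ahc_center_proportion: Optional[float] = None
    brainstem_distance: Optional[float] = None
    ventricle_hit: Optional[bool] = None
    errors: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# skull crossings
# ---------------------------------------------------------------------------

_BISECT_TOL = 0.01  # mm


def _first_crossing(sd, origin: np.ndarray, direction: np.ndarray,
                    t_max: float, step: float = 1.0) -> float:
    """Arc length of the first outside→inside crossing of ``sd`` along a ray.

    ``sd`` must be positive at ``origin``; the crossing is refined by
    bisection to 0.01 mm.  Raises if no sign change occurs before ``t_max``.
    """
    t_prev, v_prev = 0.0, float(sd(origin))
    if v_prev <= 0:
        raise ValueError("ray origin is not outside the surface")
    t = step
    while t <= t_max + step:
        v = float(sd(origin + direction * min(t, t_max)))
        if v <= 0:
            lo, hi = t_prev, min(t, t_max)
            while hi - lo > _BISECT_TOL:
                mid = 0.5 * (lo + hi)
                if float(sd(origin + direction * mid)) <= 0:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)
        t_prev, v_prev = min(t, t_max), v
        t += step
    raise ValueError("ray does not cross the surface")


def _backed_off_origin(sd, traj: Trajectory, clearance: float = 2.0) -> tuple[np.ndarray, float]:
    """A point on the trajectory line, behind the entry, safely outside ``sd``."""
    d = traj.direction
    entry = np.asarray(traj.entry, dtype=float)
    back = 0.0
    while back <= 600.0:
        p = entry - d * back
        if float(sd(p)) > clearance:
            t_max = back + float(np.linalg.norm(np.asarray(traj.target) - entry)) + 1.0
            return p, t_max
        back += 5.0
    raise ValueError("could not find a point outside the skull on the trajectory line")


def inner_crossing_point(traj: Trajectory, skull: SkullModel) -> np.ndarray:
    """First crossing of the inner skull surface along the entry→target ray."""
    if float(skull.sd_inner(np.asarray(traj.target))) >= 0:
        raise ValueError("target lies outside the inner skull surface")
    origin, t_max = _backed_off_origin(skull.sd_inner, traj)
    t = _first_crossing(skull.sd_inner, origin, traj.direction, t_max)
    return origin + traj.direction * t


def intracerebral_length(traj: Trajectory, skull: SkullModel) -> float:
    """Distance (mm) from the inner-skull crossing to the target."""
    p_in = inner_crossing_point(traj, skull)
    return float(np.linalg.norm(np.asarray(traj.target) - p_in))


def drilling_angle(traj: Trajectory, skull: SkullModel) -> float:
    """Angle (degrees) between the trajectory and the outer skull normal.

    0 deg corresponds to orthogonal drilling; the result is folded into
    [0, 90].
    """
    origin, t_max = _backed_off_origin(skull.sd_outer, traj)
    t = _first_crossing(skull.sd_outer, origin, traj.direction, t_max)
    n = skull.outer_normal(origin + traj.direction * t)
    cosang = abs(float(np.dot(traj.direction, n)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# risk
# ---------------------------------------------------------------------------


def pointwise_risk(d, params: RiskParams = RiskParams()):
    """Risk of a single sample point at distance ``d`` mm from critical tissue.

    1 for ``d <= d_lo``, 0 for ``d >= d_hi``, linear in between.  Accepts
    scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    ramp = (params.d_hi - d) / (params.d_hi - params.d_lo)
    out = np.clip(ramp, 0.0, 1.0)
    return out if out.ndim else float(out)


def _segment_samples(traj: Trajectory, skull: SkullModel, step: float):
    """Midpoint samples and spacing along the intracerebral segment."""
    p_in = inner_crossing_point(traj, skull)
    target = np.asarray(traj.target, dtype=float)
    length = float(np.linalg.norm(target - p_in))
    n = max(1, int(np.ceil(length / step)))
    ds = length / n
    s = (np.arange(n) + 0.5) * ds
    pts = p_in + np.outer(s, traj.direction)
    return p_in, pts, s, ds, length


def overall_risk(traj: Trajectory, critical: DistanceField, skull: SkullModel,
                 params: RiskParams = RiskParams()) -> float:
    """Path integral of pointwise risk over the intracerebral segment / norm_length."""
    _, pts, _, ds, _ = _segment_samples(traj, skull, params.sample_step)
    risks = pointwise_risk(critical.at(pts), params)
    return float(np.sum(risks) * ds / params.norm_length)


def _refined_min(field: DistanceField, traj: Trajectory, p_in: np.ndarray,
                 s: np.ndarray, ds: float, length: float) -> float:
    """Golden-section refinement of the minimal sampled field value."""
    def f(arc):
        return float(field.at(p_in + traj.direction * arc))

    vals = field.at(p_in + np.outer(s, traj.direction))
    i = int(np.argmin(vals))
    lo = max(0.0, s[i] - ds)
    hi = min(length, s[i] + ds)
    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": _BISECT_TOL})
    return float(min(res.fun, vals[i], f(0.0), f(length)))


def min_critical_distance(traj: Trajectory, critical: DistanceField, skull: SkullModel,
                          params: RiskParams = RiskParams()) -> float:
    """Minimum interpolated critical-structure distance along the segment."""
    p_in, _, s, ds, length = _segment_samples(traj, skull, params.sample_step)
    return _refined_min(critical, traj, p_in, s, ds, length)


def brainstem_distance(traj: Trajectory, brainstem: DistanceField, skull: SkullModel,
                       params: RiskParams = RiskParams(), mode: str = "min") -> float:
    """Minimum (or trajectory-midpoint) distance from the brainstem.

    ``mode="midpoint"`` evaluates the field at the centre of the
    intracerebral segment only, an alternative reading of "distance of the
    centre of the trajectory from the brainstem".
    """
    p_in, _, s, ds, length = _segment_samples(traj, skull, params.sample_step)
    if mode == "midpoint":
        return float(brainstem.at(p_in + traj.direction * (length / 2.0)))
    if mode != "min":
        raise ValueError("mode must be 'min' or 'midpoint'")
    return _refined_min(brainstem, traj, p_in, s, ds, length)


# ---------------------------------------------------------------------------
# AHC contact
# ---------------------------------------------------------------------------


@dataclass
class AhcGeometry:
    """Precomputed core mask and principal axis of the AHC.

    The "centre" of the AHC is operationalized as the voxels at least
    ``core_margin`` mm from the structure boundary; the contact measure is
    the trajectory arc length inside that core divided by the AHC extent
    along its first principal axis, clipped to [0, 1].
    """

    core_mask: np.ndarray
    affine: np.ndarray
    extent: float
    core_margin: float

    @classmethod
    def build(cls, ahc: RoiMask, core_margin: float = 1.5) -> "AhcGeometry":
        if not ahc.mask.any():
            raise ValueError("AHC mask is empty")
        pts = ahc.voxel_centers_world()
        centred = pts - pts.mean(axis=0)
        cov = centred.T @ centred / len(pts)
        w, v = np.linalg.eigh(cov)
        axis = v[:, int(np.argmax(w))]
        proj = centred @ axis
        extent = float(proj.max() - proj.min())

        # erode within a cropped bounding box to keep the EDT cheap
        idx = np.argwhere(ahc.mask)
        lo = np.maximum(idx.min(axis=0) - 1, 0)
        hi = np.minimum(idx.max(axis=0) + 2, ahc.mask.shape)
        sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        inside = ndimage.distance_transform_edt(ahc.mask[sub], sampling=ahc.spacing)
        core = np.zeros_like(ahc.mask)
        core[sub] = inside >= core_margin
        if not core.any():
            warnings.warn("AHC core empty after erosion; using the full mask", stacklevel=2)
            core = ahc.mask.copy()
        return cls(core, np.asarray(ahc.affine, float), extent, core_margin)

    def proportion(self, traj: Trajectory, step: float = 0.1) -> float:
        entry = np.asarray(traj.entry, dtype=float)
        target = np.asarray(traj.target, dtype=float)
        length = float(np.linalg.norm(target - entry))
        n = max(2, int(np.ceil(length / step)))
        ds = length / n
        pts = entry + np.outer((np.arange(n) + 0.5) * ds, traj.direction)
        ijk = np.rint(world_to_voxel(self.affine, pts)).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.asarray(self.core_mask.shape)), axis=1)
        inside = np.zeros(n, dtype=bool)
        inside[ok] = self.core_mask[tuple(ijk[ok].T)]
        arc = float(inside.sum()) * ds
        return float(np.clip(arc / self.extent, 0.0, 1.0))


def ahc_center_proportion(traj: Trajectory, ahc: RoiMask, core_margin: float = 1.5) -> float:
    """Fraction of the AHC principal-axis extent cannulated through its core."""
    return AhcGeometry.build(ahc, core_margin).proportion(traj)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _ventricle_hit(traj: Trajectory, ventricles: RoiMask, skull: SkullModel,
                   step: float = 0.25) -> bool:
    p_in, pts, _, _, _ = _segment_samples(traj, skull, step)
    ijk = np.rint(world_to_voxel(ventricles.affine, pts)).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.asarray(ventricles.mask.shape)), axis=1)
    return bool(ventricles.mask[tuple(ijk[ok].T)].any())


def compute_metrics(traj: Trajectory, model: HeadModel,
                    params: RiskParams = RiskParams(),
                    core_margin: float = 1.5,
                    brainstem_mode: str = "min") -> TrajectoryMetrics:
    """Compute the full safety bundle, collecting per-metric errors.

    Individual failures (e.g. a missing brainstem on a minimal model) are
    recorded in ``metrics.errors`` and leave the other fields intact.
    """
    m = TrajectoryMetrics()

    def attempt(name, fn):
        try:
            setattr(m, name, fn())
        except Exception as exc:  # noqa: BLE001 - reported per metric
            m.errors[name] = str(exc)

    attempt("intracerebral_length", lambda: intracerebral_length(traj, model.skull))
    attempt("drilling_angle", lambda: drilling_angle(traj, model.skull))

    if model.critical_field is not None:
        attempt("min_critical_distance",
                lambda: min_critical_distance(traj, model.critical_field, model.skull, params))
        attempt("overall_risk",
                lambda: overall_risk(traj, model.critical_field, model.skull, params))
    else:
        m.errors["min_critical_distance"] = "no critical structures in model"
        m.errors["overall_risk"] = "no critical structures in model"

    if model.ahc is not None:
        def ahc_prop():
            if model.ahc_geom is None or getattr(model.ahc_geom, "core_margin", None) != core_margin:
                model.ahc_geom = AhcGeometry.build(model.ahc, core_margin)
            return model.ahc_geom.proportion(traj)
        attempt("ahc_center_proportion", ahc_prop)
    else:
        m.errors["ahc_center_proportion"] = "no AHC in model"

    if model.brainstem_field is not None:
        attempt("brainstem_distance",
                lambda: brainstem_distance(traj, model.brainstem_field, model.skull,
                                           params, mode=brainstem_mode))
    else:
        m.errors["brainstem_distance"] = "no brainstem in model"

    if model.ventricles is not None:
        attempt("ventricle_hit", lambda: _ventricle_hit(traj, model.ventricles, model.skull))
    else:
        m.errors["ventricle_hit"] = "no ventricles in model"

    return m
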