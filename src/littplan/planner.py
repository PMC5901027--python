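"""Automated trajectory generation: target, candidates, feasibility, ranking.

The target is the amygdala centroid displaced 3 mm medially, 3 mm anteriorly
and 3 mm inferiorly; entry candidates are enumerated on prioritized entry
gyri (inferior occipital, then middle occipital, then posterior middle
temporal).  Candidates are filtered for feasibility — ventricular exclusion,
the 3 mm planning safety margin from critical structures, a maximum drilling
angle — and the surviving set is ranked by a weighted objective favouring
low cumulative risk, high contact with the AHC core, short intracerebral
length and near-orthogonal drilling.  The first entry role with any feasible
candidate wins; later roles are not evaluated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .anatomy import ENTRY_ROLES, HeadModel, RoiMask, extract_roi
from .metrics import RiskParams, Trajectory, TrajectoryMetrics, compute_metrics

log = logging.getLogger(__name__)

#: Normalizers that bring length and angle onto the ~[0, 1] scale of the
#: risk and AHC-contact terms.
LENGTH_NORM_MM = 150.0
ANGLE_NORM_DEG = 90.0


@dataclass
class PlanConfig:
    """Configuration of the automated planner."""

    target_offset: tuple[float, float, float] = (3.0, 3.0, 3.0)  # medial, anterior, inferior mm
    entry_roles: tuple[str, ...] = ENTRY_ROLES
    entry_spacing: float = 2.0        # mm pitch between candidate entry points
    max_drilling_angle: float = 45.0  # degrees
    enforce_safety_margin: bool = True
    weights: tuple[float, float, float, float] = (1.0, 1.0, 0.25, 0.25)  # risk, ahc, len, angle
    risk_params: RiskParams = field(default_factory=RiskParams)
    core_margin: float = 1.5
    top_k: int = 5

    def __post_init__(self) -> None:
        if not self.entry_roles:
            raise ValueError("entry_roles must be non-empty")
        if self.entry_spacing <= 0:
            raise ValueError("entry_spacing must be positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")


@dataclass
class PlanResult:
    """Outcome of :func:`plan`; infeasibility is a result, not an exception."""

    trajectory: Optional[Trajectory]
    metrics: Optional[TrajectoryMetrics]
    entry_role_used: Optional[str]
    score: Optional[float]
    n_candidates_evaluated: int
    n_feasible: int
    rejection_tally: dict[str, int]
    ranked_alternatives: list[tuple[Trajectory, TrajectoryMetrics, float]]

    @property
    def feasible(self) -> bool:
        return self.trajectory is not None


def make_target(amygdala: RoiMask, side: str, offset=(3.0, 3.0, 3.0)) -> np.ndarray:
    """Amygdala centroid displaced medially/anteriorly/inferiorly.

    Medial is toward the mid-sagittal plane: +x for a left-sided, -x for a
    right-sided structure in RAS+.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    medial, anterior, inferior = (float(v) for v in offset)
    c = amygdala.centroid_world()
    dx = medial if side == "left" else -medial
    return c + np.array([dx, anterior, -inferior])


def candidate_entries(entry_patch: RoiMask, brain: RoiMask, spacing: float) -> list[np.ndarray]:
    """Deterministic surface entry points on an entry-gyrus patch.

    Surface voxels are patch voxels with at least one face neighbour outside
    the intracranial mask; they are ordered lexicographically by world
    (z, y, x) and then subsampled on an absolute world grid of the given
    pitch (first point per occupied grid cell wins).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not entry_patch.mask.any():
        log.warning("entry patch %r is empty", entry_patch.role)
        return []
    interior = ndimage.binary_erosion(
        brain.mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surface = entry_patch.mask & ~interior
    if not surface.any():
        log.warning("entry patch %r has no surface voxels", entry_patch.role)
        return []
    pts = RoiMask(entry_patch.role, surface, entry_patch.affine).voxel_centers_world()
    order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))  # primary z, then y, then x
    pts = pts[order]
    origin = pts.min(axis=0)  # anchor the subsampling grid on the patch itself
    seen: set[tuple[int, int, int]] = set()
    kept: list[np.ndarray] = []
    for p in pts:
        cell = tuple(int(v) for v in np.floor((p - origin) / spacing))
        if cell not in seen:
            seen.add(cell)
            kept.append(p)
    return kept


def feasible_from_metrics(m: TrajectoryMetrics, config: PlanConfig) -> tuple[bool, str]:
    """First failing constraint, in exclusion → margin → angle order."""
    needed = (m.ventricle_hit, m.min_critical_distance, m.drilling_angle)
    if any(v is None for v in needed):
        return False, "metric_error"
    if m.ventricle_hit:
        return False, "ventricle"
    if config.enforce_safety_margin and \
            m.min_critical_distance < config.risk_params.safety_margin:
        return False, "safety_margin"
    if m.drilling_angle > config.max_drilling_angle:
        return False, "drilling_angle"
    return True, ""


def feasible(traj: Trajectory, model: HeadModel,
             config: Optional[PlanConfig] = None) -> tuple[bool, str]:
    """Evaluate the feasibility filter for one trajectory."""
    config = config or PlanConfig()
    m = compute_metrics(traj, model, config.risk_params, config.core_margin)
    return feasible_from_metrics(m, config)


def score(metrics: TrajectoryMetrics, config: Optional[PlanConfig] = None) -> float:
    """Weighted objective; lower is better.

    ``w_risk * risk - w_ahc * ahc + w_len * len/150 + w_angle * angle/90``.
    """
    config = config or PlanConfig()
    w_risk, w_ahc, w_len, w_angle = config.weights
    ahc = metrics.ahc_center_proportion if metrics.ahc_center_proportion is not None else 0.0
    return (
        w_risk * metrics.overall_risk
        - w_ahc * ahc
        + w_len * metrics.intracerebral_length / LENGTH_NORM_MM
        + w_angle * metrics.drilling_angle / ANGLE_NORM_DEG
    )


def plan(model: HeadModel, config: Optional[PlanConfig] = None) -> PlanResult:
    """Plan the optimal trajectory to the transformed amygdala target.

    Entry roles are tried in priority order; within the first role offering
    at least one feasible candidate the minimum-score candidate is returned
    (ties broken by lower overall risk, then shorter intracerebral length,
    then enumeration order).  If no role yields a feasible candidate an
    infeasible :class:`PlanResult` with the full rejection tally is returned.
    """
    config = config or PlanConfig()
    if model.amygdala is None:
        raise ValueError("model has no amygdala; cannot derive a target")
    target = make_target(model.amygdala, model.side, config.target_offset)

    tally: Counter[str] = Counter()
    n_eval = 0

    for role in config.entry_roles:
        if role not in model.volume.role_map:
            log.warning("entry role %r absent from the label volume; skipping", role)
            tally["missing_patch"] += 0
            continue
        patch = extract_roi(model.volume, role)
        entries = candidate_entries(patch, model.intracranial, config.entry_spacing)
        feas: list[tuple[float, float, float, int, Trajectory, TrajectoryMetrics]] = []
        for idx, entry in enumerate(entries):
            traj = Trajectory(tuple(entry), tuple(target), label="cap")
            m = compute_metrics(traj, model, config.risk_params, config.core_margin)
            n_eval += 1
            ok, reason = feasible_from_metrics(m, config)
            if not ok:
                tally[reason] += 1
                continue
            feas.append((score(m, config), m.overall_risk, m.intracerebral_length,
                         idx, traj, m))
        if feas:
            feas.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
            best = feas[0]
            alts = [(t[4], t[5], t[0]) for t in feas[: config.top_k]]
            return PlanResult(
                trajectory=best[4],
                metrics=best[5],
                entry_role_used=role,
                score=best[0],
                n_candidates_evaluated=n_eval,
                n_feasible=len(feas),
                rejection_tally=dict(tally),
                ranked_alternatives=alts,
            )

    return PlanResult(
        trajectory=None,
        metrics=None,
        entry_role_used=None,
        score=None,
        n_candidates_evaluated=n_eval,
        n_feasible=0,
        rejection_tally=dict(tally),
        ranked_alternatives=[],
    )
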