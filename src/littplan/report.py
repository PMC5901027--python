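"""Cohort comparison tables and nonparametric statistics.

Manual and automatically planned trajectories are compared arm-wise with
unpaired two-sided Mann-Whitney U tests (exact by full enumeration for small
samples, tie- and continuity-corrected normal approximation otherwise),
Kruskal-Wallis for more than two groups, and Pearson correlation with a
Fisher-z 95% confidence interval for expected-versus-achieved ablation
volumes.  The cylinder-model estimation error is reported per ROI as a
signed percentage of the baseline anatomical volume.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .ablation import AblationReport

__all__ = [
    "mann_whitney_u",
    "kruskal_wallis",
    "pearson_ci",
    "estimation_error",
    "cohort_compare",
    "validate_cohort_table",
]

EXACT_LIMIT = 12  # pooled size at or below which the exact null is enumerated


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group A: pairs with a > b count 1, ties count 1/2."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(group_a, group_b) -> dict:
    """Two-sided Mann-Whitney U test.

    For pooled sizes up to 12 the p-value is exact, obtained by enumerating
    every assignment of the pooled values to the two groups (valid under
    ties; the permutation distribution of U is symmetric about
    ``n_a n_b / 2``).  Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    n_a, n_b = a.size, b.size

    if n_a + n_b <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        idx = np.arange(pooled.size)
        mid = n_a * n_b / 2.0
        extreme = 0
        total = comb(pooled.size, n_a)
        for chosen in combinations(idx, n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(chosen)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mid) >= abs(u - mid) - 1e-12:
                extreme += 1
        return {"U": u, "p_two_sided": extreme / total, "method": "exact"}

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return {"U": u, "p_two_sided": float(res.pvalue), "method": "asymptotic"}


def kruskal_wallis(groups) -> dict:
    """Rank-based Kruskal-Wallis H with tie correction, chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0}
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p)}


def pearson_ci(x, y, confidence: float = 0.95) -> dict:
    """Pearson r with Fisher-z confidence interval, R^2 and t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    r = float(res.statistic)
    return {"r": r, "ci95_lo": float(ci.low), "ci95_hi": float(ci.high),
            "R2": r * r, "p": float(res.pvalue)}


def estimation_error(expected: AblationReport, achieved: AblationReport) -> pd.DataFrame:
    """Signed per-ROI error of the cylinder model, % of anatomical volume.

    Positive values mean the cylinder overestimates the achieved ablation.
    """
    exp = expected.table.set_index("role")
    ach = achieved.table.set_index("role")
    if set(exp.index) != set(ach.index):
        raise ValueError("reports cover different ROI sets")
    if not np.allclose(exp["anatomical_volume_mm3"], ach.loc[exp.index, "anatomical_volume_mm3"],
                       rtol=1e-6, atol=1e-6):
        raise ValueError("reports disagree on anatomical volumes")
    rows = []
    for role in exp.index:
        anat = float(exp.loc[role, "anatomical_volume_mm3"])
        delta = float(exp.loc[role, "ablated_volume_mm3"]) - float(
            ach.loc[role, "ablated_volume_mm3"])
        rows.append({"role": role,
                     "estimation_error_pct": 100.0 * delta / anat if anat > 0 else 0.0})
    return pd.DataFrame(rows)


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Check the long-format cohort table: one row per case per arm."""
    required = {"case_id", "arm"}
    if not required <= set(table.columns):
        raise ValueError("cohort table needs 'case_id' and 'arm' columns")
    arms = set(table["arm"].unique())
    if not arms <= {"manual", "cap"}:
        raise ValueError(f"unknown arm labels: {sorted(arms - {'manual', 'cap'})}")
    if len(arms) < 2:
        raise ValueError("cohort table contains a single arm; nothing to compare")
    dup = table.groupby(["case_id", "arm"]).size()
    if (dup > 1).any():
        raise ValueError("a case_id appears more than once within an arm")
    both = table.pivot_table(index="case_id", columns="arm", aggfunc="size").dropna()
    if len(both) < 2:
        raise ValueError("need at least two cases present in both arms")


def cohort_compare(table: pd.DataFrame, metrics=None, holm: bool = False,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Arm-wise mean ± SD and Mann-Whitney p per metric.

    ``metrics`` defaults to every numeric column other than the identifiers.
    ``holm=True`` additionally applies a Holm step-down correction (off by
    default).
    """
    validate_cohort_table(table)
    if metrics is None:
        metrics = [c for c in table.columns
                   if c not in ("case_id", "arm") and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for metric in metrics:
        manual = table.loc[table["arm"] == "manual", metric].dropna().to_numpy()
        cap = table.loc[table["arm"] == "cap", metric].dropna().to_numpy()
        mw = mann_whitney_u(manual, cap)
        rows.append({
            "metric": metric,
            "manual_mean": float(np.mean(manual)),
            "manual_sd": float(np.std(manual, ddof=1)) if manual.size > 1 else 0.0,
            "cap_mean": float(np.mean(cap)),
            "cap_sd": float(np.std(cap, ddof=1)) if cap.size > 1 else 0.0,
            "p_value": mw["p_two_sided"],
        })
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
        out["significant"] = out["p_holm"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out
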