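"""Group learning curves and an exact Mann-Whitney U test.

Per-mouse session CR% values are averaged into group curves (mean +/- SEM per
session, SEM = sample SD / sqrt(n)); endpoint comparisons (e.g. last training
session between genotypes, T7 vs E4 within a group) use an exact
Mann-Whitney U test, enumerated over the permutation distribution for small
samples and normally approximated (with tie correction) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .paradigm import session_sort_key

__all__ = ["MWUResult", "aggregate_group", "exact_mann_whitney"]


@dataclass(frozen=True)
class MWUResult:
    """U counts pairs with x_i > y_j (ties half); p-values from the
    permutation distribution of U (or its normal approximation)."""

    u_statistic: float
    p_one_sided: float
    p_two_sided: float
    n_x: int
    n_y: int
    method: str  # "exact" or "normal"


def aggregate_group(
    results: pd.DataFrame, group_key: str = "group"
) -> pd.DataFrame:
    """Aggregate per-mouse session CR% into group learning curves.

    ``results`` needs columns ``[group_key, mouse_id, session_label,
    cr_percent]``; rows with undefined CR% (NaN) are excluded from that
    session's n.  Returns tidy rows ``(group, session_label,
    mean_cr_percent, sem, n)`` in conventional session order.
    """
    required = {group_key, "mouse_id", "session_label", "cr_percent"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns {sorted(missing)}")
    if len(results) == 0:
        raise ValueError("empty results table")
    dup = results.duplicated([group_key, "mouse_id", "session_label"])
    if dup.any():
        raise ValueError("a mouse contributes more than one result per session")

    rows = []
    for (group, label), sub in results.groupby([group_key, "session_label"]):
        vals = sub["cr_percent"].dropna().to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            continue
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "group": group,
                "session_label": label,
                "mean_cr_percent": mean,
                "sem": sem,
                "n": n,
            }
        )
    if not rows:
        raise ValueError("no defined CR% values to aggregate")
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["group", "session_label"],
        key=lambda col: (
            col.map(session_sort_key) if col.name == "session_label" else col
        ),
        kind="stable",
    ).reset_index(drop=True)
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via pooled ranks."""
    n_x = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n_x].sum()
    return float(r_x - n_x * (n_x + 1) / 2.0)


def exact_mann_whitney(
    x, y, exact_limit: int = 20
) -> MWUResult:
    """Mann-Whitney U test with exact small-sample p-values.

    For ``n_x + n_y <= exact_limit`` the p-value is computed by complete
    enumeration of all C(n, n_x) assignments of the pooled observations to
    the two groups; beyond that a normal approximation with tie correction
    and continuity correction is used.  One-sided p is the smaller tail;
    two-sided p doubles it, capped at 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    u_obs = _u_statistic(x, y)

    if n <= exact_limit:
        pooled = np.concatenate([x, y])
        eps = 1e-9
        n_total = math.comb(n, n_x)
        n_le = 0
        n_ge = 0
        idx_all = frozenset(range(n))
        for comb in combinations(range(n), n_x):
            xs = pooled[list(comb)]
            ys = pooled[list(idx_all - set(comb))]
            u = _u_statistic(xs, ys)
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p_lower = n_le / n_total
        p_upper = n_ge / n_total
        p_one = min(p_lower, p_upper)
        p_two = min(1.0, 2.0 * p_one)
        return MWUResult(u_obs, p_one, p_two, n_x, n_y, "exact")

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    mu = n_x * n_y / 2.0
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return MWUResult(u_obs, 0.5, 1.0, n_x, n_y, "normal")
    # continuity correction toward the mean
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / math.sqrt(var)
    p_one = float(sps.norm.sf(abs(z)))
    p_two = min(1.0, 2.0 * p_one)
    return MWUResult(u_obs, p_one, p_two, n_x, n_y, "normal")
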