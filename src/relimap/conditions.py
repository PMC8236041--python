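"""Cross-condition spatial correlation and difference-score reliability.

The reliability of a difference contrast (e.g. food minus neutral) is
bounded by the correlation between its constituent conditions: subtracting
two positively correlated measures removes shared true-score variance
while their measurement errors add. The classical closed form for the
reliability of D = X - Y is

    r_DD = (r_xx sd_x^2 + r_yy sd_y^2 - 2 r_xy sd_x sd_y)
           / (sd_x^2 + sd_y^2 - 2 r_xy sd_x sd_y)

with r_xx, r_yy the test-retest reliabilities of the constituents and
r_xy their cross-correlation. This module provides that closed form plus
the empirical side: per-subject Spearman correlations between condition
maps, summarised as mean, SD and R^2 (squared mean rho — the fraction of
variance the conditions share).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import MapStack

logger = logging.getLogger(__name__)


def spatial_rank_correlation(
    map_a: np.ndarray, map_b: np.ndarray
) -> float:
    """Spearman rank correlation across voxels finite in both maps.

    Ties receive average ranks. Requires at least 3 common finite voxels.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps differ in length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} common finite voxels (need >= 3)")
    return float(stats.spearmanr(a[ok], b[ok]).statistic)


def condition_correlation_summary(
    stack: MapStack,
    food_conditions: list[str],
    neutral_condition: str,
    sessions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject spatial rho of each food-category map vs the neutral map.

    Per subject, rho is computed in every requested session and averaged
    (one value per subject per pair) before taking the across-subject mean
    and SD; R^2 is the squared mean rho. A per-session breakdown is kept in
    the returned frame's ``rho_by_session`` column. Subjects missing a cell
    for a (session, condition) are excluded from that pair and logged.
    """
    if sessions is None:
        sessions = list(stack.sessions)
    rows = []
    for food in food_conditions:
        per_subject: list[float] = []
        by_session: dict[str, list[float]] = {s: [] for s in sessions}
        used_subjects = []
        for subj in stack.subjects:
            rhos = []
            for sess in sessions:
                if stack.is_present(subj, sess, food) and stack.is_present(
                    subj, sess, neutral_condition
                ):
                    rho = spatial_rank_correlation(
                        stack.get(subj, sess, food),
                        stack.get(subj, sess, neutral_condition),
                    )
                    rhos.append(rho)
                    by_session[sess].append(rho)
            if rhos:
                per_subject.append(float(np.mean(rhos)))
                used_subjects.append(subj)
            else:
                logger.info(
                    "subject %s has no complete (%s, %s) session; excluded",
                    subj, food, neutral_condition,
                )
        vals = np.asarray(per_subject)
        mean_rho = float(vals.mean())
        rows.append(
            {
                "pair": f"{food}-{neutral_condition}",
                "n_subjects": len(vals),
                "mean_rho": mean_rho,
                "sd_rho": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "r_squared": mean_rho ** 2,
                "rho_per_subject": vals,
                "rho_by_session": {
                    s: float(np.mean(v)) if v else float("nan")
                    for s, v in by_session.items()
                },
            }
        )
    return pd.DataFrame(rows)


def difference_reliability(
    r_xx: float, r_yy: float, r_xy: float, sd_x: float, sd_y: float
) -> float:
    """Closed-form reliability of the difference score X - Y.

    With equal SDs and r_xy = 0 the constituents' reliability is preserved;
    as r_xy approaches the constituent reliabilities the difference score's
    reliability collapses toward zero. NaN when the difference score has
    zero variance (denominator 0).
    """
    for name, r in (("r_xx", r_xx), ("r_yy", r_yy), ("r_xy", r_xy)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
    for name, sd in (("sd_x", sd_x), ("sd_y", sd_y)):
        if not sd > 0:
            raise ValueError(f"{name} must be positive, got {sd}")
    num = r_xx * sd_x**2 + r_yy * sd_y**2 - 2 * r_xy * sd_x * sd_y
    den = sd_x**2 + sd_y**2 - 2 * r_xy * sd_x * sd_y
    if den == 0:
        return float("nan")
    return num / den
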