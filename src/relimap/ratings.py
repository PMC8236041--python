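"""Reliability and time course of in-scanner craving ratings.

The behavioural analogue of the imaging difference contrast: per subject
and session, the craving contrast is mean(food-block ratings) minus
mean(neutral-block ratings). Its test-retest reliability uses the same
two-way mixed-model consistency ICC as the voxel maps (one shared
implementation — no drift between modules), and the session time course
is tested with a one-way repeated-measures ANOVA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .icc import icc_f_test, _two_way_mean_squares
from .io import RatingsTable

logger = logging.getLogger(__name__)


def craving_contrast(table: RatingsTable) -> pd.DataFrame:
    """Subjects x sessions matrix of mean food minus mean neutral ratings.

    Subjects missing either condition in any session are excluded listwise
    (logged): the ICC and RM-ANOVA downstream both need complete rows.
    """
    frame = table.frame
    means = (
        frame.groupby(["subject", "session", "condition"])["rating"]
        .mean()
        .unstack("condition")
    )
    contrast = (means["food"] - means["neutral"]).unstack("session")
    complete = contrast.dropna(axis=0, how="any")
    dropped = sorted(set(contrast.index) - set(complete.index))
    if dropped:
        logger.info(
            "excluding %d subject(s) with incomplete ratings: %s",
            len(dropped), dropped,
        )
    if complete.empty:
        raise ValueError("no subject has complete food and neutral ratings")
    return complete


def ratings_icc(matrix: pd.DataFrame | np.ndarray, average_measure: bool = False):
    """Consistency ICC of the craving-contrast matrix with its F test.

    Single-measure ICC(3,1) by default; ``average_measure=True`` returns
    the average-measure variant ICC(3,k) = (BMS - EMS)/BMS instead.
    Returns (icc, F, df1, df2, p); ICC is NaN for degenerate variance.
    """
    m = np.asarray(matrix, dtype=float)
    icc, f, df1, df2, p = icc_f_test(m)
    if average_measure:
        bms, ems = _two_way_mean_squares(m[:, :, None])
        icc = float("nan") if bms[0] == 0 else float((bms[0] - ems[0]) / bms[0])
    if not np.isfinite(icc):
        logger.warning("degenerate variance: ICC undefined")
    return icc, f, df1, df2, p


def ratings_time_anova(matrix: pd.DataFrame | np.ndarray) -> dict:
    """One-way repeated-measures ANOVA of the session factor.

    For n complete subjects and k sessions the session effect is tested
    against the subject-by-session residual with (k-1, (n-1)(k-1)) df.
    Also reports per-session means and SDs.
    """
    from scipy import stats

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 sessions")
    if not np.isfinite(m).all():
        raise ValueError("matrix must be complete; exclude incomplete subjects first")
    n, k = m.shape
    grand = m.mean()
    ss_sess = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((m - grand) ** 2).sum() - ss_sess - ss_subj
    ss_err = max(ss_err, 0.0)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_sess = ss_sess / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = np.inf if ms_sess > 0 else 0.0
        p = 0.0 if ms_sess > 0 else 1.0
    else:
        f = ms_sess / ms_err
        p = float(stats.f.sf(f, df1, df2))
    sessions = (
        list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(k))
    )
    return {
        "F": float(f),
        "df1": df1,
        "df2": df2,
        "p": p,
        "n": n,
        "session_means": {str(s): float(m[:, i].mean()) for i, s in enumerate(sessions)},
        "session_sds": {
            str(s): float(m[:, i].std(ddof=1)) for i, s in enumerate(sessions)
        },
    }
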