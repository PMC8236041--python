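"""Thresholded-activation overlap between sessions: Jaccard and Dice.

A statistic map is binarized at a voxel-wise significance threshold
(default p < 0.001, uncorrected, one-sided positive — the convention for
activation contrasts). For the super-threshold voxel sets A and B of the
same subject in two sessions,

    Jaccard(A, B) = |A n B| / |A u B|
    Dice(A, B)    = 2 |A n B| / (|A| + |B|)

Both lie in [0, 1]; Dice = 2J/(1+J) identically. When the union is empty
the coefficient is undefined and reported as NaN (and tallied), rather than
forced to 0 or 1 — either convention would bias the across-subject means.

The per-subject table over session pairs and contrasts feeds a classical
two-way repeated-measures ANOVA (factors: contrast, session pair) with
Bonferroni-corrected paired post-hoc tests of the difference contrast
against each constituent condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BrainMask, MapStack

logger = logging.getLogger(__name__)


@dataclass
class BinaryMap:
    """Set of "active" voxels over an analysis mask."""

    mask: BrainMask
    active: np.ndarray  # bool per in-mask voxel

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (self.mask.n_voxels,):
            raise ValueError("active flags do not match mask size")

    @property
    def size(self) -> int:
        return int(self.active.sum())


def critical_t(df: float, p_threshold: float, direction: str = "positive") -> float:
    """Critical t for a voxel-wise significance threshold."""
    if not np.isfinite(df) or df < 1:
        raise ValueError(f"df must be a finite number >= 1, got {df}")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    alpha = p_threshold / 2 if direction == "two_sided" else p_threshold
    return float(stats.t.isf(alpha, df))


def binarize(
    stat_map: np.ndarray,
    mask: BrainMask,
    df: float | None = None,
    p_threshold: float = 0.001,
    direction: str = "positive",
    t_threshold: float | None = None,
) -> BinaryMap:
    """Threshold a t-map into a BinaryMap of super-threshold voxels.

    Either give (df, p_threshold) and the critical t is computed, or give
    a direct ``t_threshold`` for maps without a known df. NaN voxels are
    inactive. Directions: positive (activation), negative, two_sided.
    """
    if direction not in ("positive", "negative", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    t = np.asarray(stat_map, dtype=float)
    if t.shape != (mask.n_voxels,):
        raise ValueError("stat map length does not match mask size")
    if t_threshold is None:
        if df is None:
            raise ValueError("need df with p_threshold, or a direct t_threshold")
        t_threshold = critical_t(df, p_threshold, direction)
    with np.errstate(invalid="ignore"):
        if direction == "positive":
            active = t > t_threshold
        elif direction == "negative":
            active = t < -t_threshold
        else:
            active = np.abs(t) > t_threshold
    active &= np.isfinite(t)
    return BinaryMap(mask, active)


def _check_pair(a: BinaryMap, b: BinaryMap) -> None:
    if not a.mask.same_mask(b.mask):
        raise ValueError("binary maps live on different masks")


def overlap_counts(a: BinaryMap, b: BinaryMap) -> tuple[int, int, int]:
    """(|A|, |B|, |A n B|) for two binary maps on one mask."""
    _check_pair(a, b)
    return a.size, b.size, int((a.active & b.active).sum())


def jaccard(a: BinaryMap, b: BinaryMap) -> float:
    """|A n B| / |A u B|; NaN (logged) when the union is empty."""
    na, nb, ni = overlap_counts(a, b)
    union = na + nb - ni
    if union == 0:
        logger.warning("jaccard undefined: empty union")
        return float("nan")
    return ni / union


def dice(a: BinaryMap, b: BinaryMap) -> float:
    """2 |A n B| / (|A| + |B|); NaN when both sets are empty."""
    na, nb, ni = overlap_counts(a, b)
    if na + nb == 0:
        logger.warning("dice undefined: both sets empty")
        return float("nan")
    return 2 * ni / (na + nb)


def overlap_table(
    stack: MapStack,
    contrasts: list[str],
    session_pairs: list[tuple[str, str]],
    df: float | None = None,
    p_threshold: float = 0.001,
    direction: str = "positive",
    t_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-subject Jaccard/Dice for every session pair x contrast.

    Returns the long table with one row per (subject, pair, contrast):
    columns subject, pair, contrast, n_a, n_b, n_intersect, jaccard, dice.
    Use :func:`overlap_summary` for the pair-x-contrast mean/SD block.
    """
    rows = []
    n_undefined = 0
    for contrast in contrasts:
        for sa, sb in session_pairs:
            subjects = stack.complete_subjects([sa, sb], contrast)
            if len(subjects) < 2:
                raise ValueError(
                    f"fewer than 2 subjects with complete pair ({sa}, {sb}) "
                    f"for contrast {contrast!r}"
                )
            for subj in subjects:
                a = binarize(
                    stack.get(subj, sa, contrast), stack.mask,
                    df=df, p_threshold=p_threshold,
                    direction=direction, t_threshold=t_threshold,
                )
                b = binarize(
                    stack.get(subj, sb, contrast), stack.mask,
                    df=df, p_threshold=p_threshold,
                    direction=direction, t_threshold=t_threshold,
                )
                na, nb, ni = overlap_counts(a, b)
                j = jaccard(a, b)
                d = dice(a, b)
                if not np.isfinite(j):
                    n_undefined += 1
                rows.append(
                    {
                        "subject": subj,
                        "pair": f"{sa}:{sb}",
                        "contrast": contrast,
                        "n_a": na,
                        "n_b": nb,
                        "n_intersect": ni,
                        "jaccard": j,
                        "dice": d,
                    }
                )
    if n_undefined:
        logger.warning("%d pair(s) had an undefined overlap coefficient", n_undefined)
    return pd.DataFrame(rows)


def overlap_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of both coefficients per session pair x contrast."""
    return (
        table.groupby(["pair", "contrast"], sort=False)
        .agg(
            n=("subject", "size"),
            mean_jaccard=("jaccard", "mean"),
            sd_jaccard=("jaccard", "std"),
            mean_dice=("dice", "mean"),
            sd_dice=("dice", "std"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA on the overlap coefficients


def _gg_epsilon(cell_matrix: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of cell scores."""
    s = np.cov(cell_matrix, rowvar=False, ddof=1)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((s ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * grand ** 2)
    if den == 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def rm_anova_overlap(
    table: pd.DataFrame,
    measure: str = "dice",
    difference_contrast: str | None = None,
    gg_correction: bool = False,
) -> dict:
    """Two-way repeated-measures ANOVA on overlap coefficients.

    Factors are contrast and session pair (sphericity assumed; optional
    Greenhouse-Geisser correction). Requires a complete within-subject
    design. When ``difference_contrast`` is given, paired post-hoc t-tests
    compare it against each other contrast, Bonferroni-corrected.
    """
    from statsmodels.stats.anova import AnovaRM

    if measure not in ("dice", "jaccard"):
        raise ValueError(f"measure must be dice or jaccard, got {measure!r}")
    data = table[["subject", "pair", "contrast", measure]].copy()
    if data[measure].isna().any():
        bad = data.loc[data[measure].isna(), ["subject", "pair", "contrast"]]
        raise ValueError(f"undefined coefficients in design cells:\n{bad}")
    counts = data.groupby("subject").size()
    n_cells = data["pair"].nunique() * data["contrast"].nunique()
    incomplete = counts[counts != n_cells]
    if len(incomplete):
        raise ValueError(
            f"incomplete within-subject design; offending subjects: "
            f"{incomplete.index.tolist()}"
        )

    n_subj = data["subject"].nunique()
    degenerate = np.ptp(data[measure].to_numpy()) == 0.0
    if not degenerate:
        fit = AnovaRM(
            data, depvar=measure, subject="subject", within=["contrast", "pair"]
        ).fit()
        anova = fit.anova_table  # index: contrast, pair, contrast:pair

    results: dict = {"measure": measure, "factors": {}}
    factor_cells = {"contrast": "contrast", "pair": "pair"}
    for factor in ("contrast", "pair"):
        if degenerate:  # no variance anywhere: zero effect, not 0/0 noise
            n_lev = data[factor].nunique()
            f_val, p = 0.0, 1.0
            df1 = float(n_lev - 1)
            df2 = float((n_subj - 1) * (n_lev - 1))
        else:
            row = anova.loc[factor]
            f_val = float(row["F Value"])
            df1, df2 = float(row["Num DF"]), float(row["Den DF"])
            p = float(row["Pr > F"])
        entry = {"F": f_val, "df1": df1, "df2": df2, "p": p}
        if gg_correction:
            cells = (
                data.groupby(["subject", factor_cells[factor]], sort=False)[measure]
                .mean()
                .unstack()
                .to_numpy()
            )
            eps = _gg_epsilon(cells)
            entry["gg_epsilon"] = eps
            entry["p_gg"] = float(stats.f.sf(f_val, df1 * eps, df2 * eps))
        results["factors"][factor] = entry

    if difference_contrast is not None:
        others = [c for c in data["contrast"].unique() if c != difference_contrast]
        per_subj = (
            data.groupby(["subject", "contrast"], sort=False)[measure].mean().unstack()
        )
        posthoc = []
        for other in others:
            t, p = stats.ttest_rel(per_subj[difference_contrast], per_subj[other])
            posthoc.append(
                {
                    "comparison": f"{difference_contrast} vs {other}",
                    "t": float(t),
                    "p_uncorrected": float(p),
                    "p_bonferroni": float(min(1.0, p * len(others))),
                }
            )
        results["posthoc"] = posthoc
    return results
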