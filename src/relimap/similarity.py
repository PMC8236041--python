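"""Within-/between-subject map similarity and subject re-identification.

For two sessions A and B, S[i, j] is the spatial correlation (Pearson by
default, Spearman optionally) between subject i's map in session A and
subject j's map in session B, computed over in-mask voxels finite in both.
The diagonal holds within-subject similarity; off-diagonal entries are
between-subject similarity. Because the two axes are different sessions,
S is not symmetric in general.

Subject i is re-identified when their within-subject similarity strictly
exceeds every between-subject similarity in their row (S[i, i] > S[i, j]
for all j != i); ties count as failures. The identification rate is the
percentage of scored subjects so identified — a threshold-free complement
to overlap- and ICC-based reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import MapStack

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Subject x subject cross-session correlation matrix."""

    values: np.ndarray  # (n, n)
    subjects: list[str]
    session_a: str
    session_b: str
    method: str

    def __post_init__(self):
        n = len(self.subjects)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match subject count")


@dataclass
class FingerprintResult:
    """Re-identification outcome for one session pair."""

    within: np.ndarray          # diagonal values, one per scored subject
    between: np.ndarray         # off-diagonal values
    rate: float                 # percent of scored subjects identified
    n_scored: int
    n_identified: int
    identified: list[str]
    mean_within: float
    mean_between: float
    session_a: str = ""
    session_b: str = ""


def _pairwise_correlation(x: np.ndarray, y: np.ndarray, method: str) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def similarity_matrix(
    stack: MapStack,
    contrast: str,
    session_a: str,
    session_b: str,
    method: str = "pearson",
) -> SimilarityMatrix:
    """All-pairs spatial correlation between two sessions' maps.

    Subjects must be present in both sessions; constant maps produce NaN
    entries (logged) rather than an arbitrary value.
    """
    subjects = stack.complete_subjects([session_a, session_b], contrast)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects present in both sessions")
    maps_a = [stack.get(s, session_a, contrast) for s in subjects]
    maps_b = [stack.get(s, session_b, contrast) for s in subjects]
    n = len(subjects)
    s = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            s[i, j] = _pairwise_correlation(maps_a[i], maps_b[j], method)
    if np.isnan(s).any():
        logger.warning(
            "%d NaN similarity entries (constant or too-short maps)",
            int(np.isnan(s).sum()),
        )
    return SimilarityMatrix(s, subjects, session_a, session_b, method)


def reidentification(sim: SimilarityMatrix) -> FingerprintResult:
    """Row-wise strict-maximum re-identification over a similarity matrix.

    Rows containing NaN are excluded from scoring (logged); the rate is
    100 x identified / scored.
    """
    s = sim.values
    n = s.shape[0]
    row_ok = np.isfinite(s).all(axis=1)
    if not row_ok.any():
        raise ValueError("all rows contain NaN; nothing to score")
    if not row_ok.all():
        dropped = [sim.subjects[i] for i in np.flatnonzero(~row_ok)]
        logger.warning("excluding rows with NaN similarity: %s", dropped)
    identified = []
    for i in np.flatnonzero(row_ok):
        off = np.delete(s[i], i)
        if s[i, i] > off.max():  # strict: ties are failures
            identified.append(sim.subjects[i])
    scored = int(row_ok.sum())
    within = np.array([s[i, i] for i in np.flatnonzero(row_ok)])
    between = s[row_ok][~np.eye(n, dtype=bool)[row_ok]]
    return FingerprintResult(
        within=within,
        between=between,
        rate=100.0 * len(identified) / scored,
        n_scored=scored,
        n_identified=len(identified),
        identified=identified,
        mean_within=float(np.nanmean(within)),
        mean_between=float(np.nanmean(between)),
        session_a=sim.session_a,
        session_b=sim.session_b,
    )


def within_between_test(result: FingerprintResult) -> tuple[float, float, float]:
    """Welch two-sample t of within- vs between-subject similarity.

    Positive t means within-subject similarity exceeds between-subject.
    Welch's variant is used because the group sizes (n vs n^2 - n) and
    variances differ by construction. Returns (t, df, p).
    """
    w = result.within[np.isfinite(result.within)]
    b = result.between[np.isfinite(result.between)]
    if w.size < 2 or b.size < 2:
        raise ValueError("need >= 2 finite values in each group")
    if np.var(w, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate: zero variance in both groups")
    res = stats.ttest_ind(w, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def similarity_ecdf(result: FingerprintResult) -> dict[str, np.ndarray]:
    """Right-continuous ECDF curves of within and between similarity.

    Returns ``{"within": (values, fractions), "between": ...}`` with values
    sorted ascending and fractions = ECDF evaluated at each value. With a
    genuine within > between separation the within curve sits to the right
    (pointwise below) of the between curve.
    """
    out = {}
    for name, vals in (("within", result.within), ("between", result.between)):
        v = np.sort(vals[np.isfinite(vals)])
        if v.size == 0:
            raise ValueError(f"empty group {name!r}")
        frac = np.arange(1, v.size + 1) / v.size
        out[name] = (v, frac)
    return out
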