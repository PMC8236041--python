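"""Intraclass correlation ICC(3,1): scalar, voxel-wise maps, and atlas summaries.

The consistency ICC from the two-way mixed model (subjects random, sessions
fixed, single measurement) is

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

with BMS the between-subject mean square and EMS the residual mean square
after removing subject and session main effects. For k = 2 sessions this is
algebraically the familiar variance-ratio form
(sigma2_between - sigma2_within) / (sigma2_between + sigma2_within).
Constant session shifts (e.g. a scanner-wide offset at retest) do not affect
it, which is what makes it the appropriate variant for longitudinal designs.

Negative estimates are reported as-is; truncating them at zero would bias
region averages upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AtlasLabels, BrainMask, MapStack

logger = logging.getLogger(__name__)

# Fleiss benchmarks for single-measure ICC
BANDS = (
    (0.4, "poor"),       # ICC < 0.4
    (0.6, "fair"),       # 0.4 <= ICC < 0.6
    (0.75, "good"),      # 0.6 <= ICC <= 0.75
    (np.inf, "excellent"),  # ICC > 0.75
)


def reliability_band(icc: float) -> str:
    """Map an ICC value to the Fleiss qualitative band."""
    if not np.isfinite(icc):
        return "undefined"
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "fair"
    if icc <= 0.75:
        return "good"
    return "excellent"


def _two_way_mean_squares(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-way (subject x session) ANOVA mean squares.

    ``data`` has shape (n, k, ...); BMS and EMS are returned with the
    trailing shape. No missing values allowed.
    """
    n, k = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)  # (n, ...)
    sess = data.mean(axis=0)  # (k, ...)
    ss_subj = k * ((subj - grand) ** 2).sum(axis=0)
    ss_sess = n * ((sess - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_tot - ss_subj - ss_sess
    # guard tiny negative rounding in the residual
    ss_err = np.maximum(ss_err, 0.0)
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return bms, ems


def icc_consistency(matrix: np.ndarray) -> float:
    """ICC(3,1) for an n-subjects x k-sessions measurement matrix.

    Requires n >= 2, k >= 2 and a complete matrix (exclude incomplete
    subjects first). Returns NaN when both variance components vanish.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need an n>=2 x k>=2 matrix, got shape {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("matrix contains non-finite cells; exclude them first")
    k = m.shape[1]
    bms, ems = _two_way_mean_squares(m[:, :, None])
    denom = bms[0] + (k - 1) * ems[0]
    if denom == 0.0:
        return float("nan")
    return float((bms[0] - ems[0]) / denom)


def icc_f_test(matrix: np.ndarray) -> tuple[float, float, int, int, float]:
    """ICC(3,1) plus the F = BMS/EMS test against ICC = 0.

    Returns (icc, F, df1, df2, p) with df1 = n-1, df2 = (n-1)(k-1).
    """
    from scipy import stats

    m = np.asarray(matrix, dtype=float)
    icc = icc_consistency(m)
    n, k = m.shape
    bms, ems = _two_way_mean_squares(m[:, :, None])
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ems[0] == 0.0:
        f = np.inf if bms[0] > 0 else np.nan
        p = 0.0 if bms[0] > 0 else np.nan
    else:
        f = float(bms[0] / ems[0])
        p = float(stats.f.sf(f, df1, df2))
    return icc, f, df1, df2, p


@dataclass
class ICCMap:
    """Voxel-wise ICC values over a mask, with the sessions they came from."""

    mask: BrainMask
    values: np.ndarray  # (n_voxels,), NaN where undefined
    sessions: list[str]
    n_subjects: int

    @property
    def k(self) -> int:
        return len(self.sessions)


def voxelwise_icc(
    stack: MapStack,
    contrast: str,
    sessions: list[str] | None = None,
) -> ICCMap:
    """Voxel-wise ICC(3,1) of one contrast over a session subset.

    Subjects missing any requested session are excluded listwise (logged).
    Voxels where any retained subject/session value is non-finite get NaN;
    exclusion is per voxel, not listwise over the brain.
    """
    if sessions is None:
        sessions = list(stack.sessions)
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for ICC")
    subjects = stack.complete_subjects(sessions, contrast)
    if len(subjects) < 2:
        raise ValueError(
            f"fewer than 2 subjects complete on sessions {sessions} for {contrast!r}"
        )
    data = stack.subset_array(subjects, sessions, contrast)  # (n, k, V)
    n, k, _ = data.shape
    finite = np.isfinite(data).all(axis=(0, 1))
    out = np.full(data.shape[2], np.nan)
    if finite.any():
        bms, ems = _two_way_mean_squares(data[:, :, finite])
        denom = bms + (k - 1) * ems
        vals = np.full(bms.shape, np.nan)
        nz = denom > 0
        vals[nz] = (bms[nz] - ems[nz]) / denom[nz]
        out[finite] = vals
    return ICCMap(stack.mask, out, list(sessions), n)


def threshold_icc(icc_map: ICCMap, cutoff: float = 0.75):
    """Binary map of voxels with ICC strictly above *cutoff* (NaN -> inactive)."""
    from .overlap import BinaryMap

    if not -1.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (-1, 1), got {cutoff}")
    with np.errstate(invalid="ignore"):
        active = icc_map.values > cutoff
    return BinaryMap(icc_map.mask, active)


def atlas_summary(icc_map: ICCMap, atlas: AtlasLabels) -> pd.DataFrame:
    """Per-region mean ICC with Fleiss reliability bands.

    Regions are averaged over in-mask voxels with finite ICC; a region with
    no finite voxel is reported with NaN mean and band "undefined".
    """
    if not atlas.grid.matches(icc_map.mask.grid):
        raise ValueError("atlas grid does not match the ICC map grid")
    region_of_voxel = atlas.labels.ravel()[icc_map.mask.indices]
    if not (region_of_voxel > 0).any():
        raise ValueError("atlas has no labelled voxel inside the mask")
    rows = []
    for label in sorted(atlas.lookup):
        in_region = region_of_voxel == label
        vals = icc_map.values[in_region]
        finite = vals[np.isfinite(vals)]
        mean = float(finite.mean()) if finite.size else float("nan")
        rows.append(
            {
                "label": label,
                "region": atlas.lookup[label],
                "n_voxels": int(in_region.sum()),
                "n_finite": int(finite.size),
                "mean_icc": mean,
                "band": reliability_band(mean),
            }
        )
    return pd.DataFrame(rows)
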