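"""Reading and writing of brain-map volumes, masks, atlases, and ratings tables.

All volumes in one analysis must live on a single grid (shape + affine).
Brain maps are held in memory as a :class:`MapStack`: a dense
``subject x session x condition x voxel`` array restricted to the analysis
mask, with an explicit presence flag per cell so that missing scans are
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AFFINE_ATOL = 1e-4

MANIFEST_COLUMNS = ("subject", "session", "condition", "path")
RATINGS_COLUMNS = ("subject", "session", "condition", "rating")
RATING_CONDITIONS = ("food", "neutral")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D sampling grid: voxel array shape plus voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    def matches(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )


@dataclass(frozen=True)
class BrainMask:
    """Analysis mask: the sorted flat indices of in-mask voxels on a grid."""

    grid: VolumeGrid
    indices: np.ndarray  # sorted flat (C-order) voxel indices

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("mask must contain at least one voxel")
        nvox = int(np.prod(self.grid.shape))
        if idx.min() < 0 or idx.max() >= nvox:
            raise ValueError("mask indices outside the grid")
        idx = np.unique(idx)  # sorted, deterministic ordering
        object.__setattr__(self, "indices", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def same_mask(self, other: "BrainMask") -> bool:
        return self.grid.matches(other.grid) and np.array_equal(self.indices, other.indices)

    def unmask(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter an in-mask vector back into a full 3-D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        vol = np.full(int(np.prod(self.grid.shape)), fill, dtype=float)
        vol[self.indices] = values
        return vol.reshape(self.grid.shape)


@dataclass
class MapStack:
    """Masked voxel values indexed by subject x session x condition.

    ``values`` has shape ``(n_subjects, n_sessions, n_conditions, n_voxels)``;
    ``present`` flags whether the cell's volume was actually supplied.
    Voxel-level NaN is allowed inside present cells.
    """

    mask: BrainMask
    subjects: list[str]
    sessions: list[str]
    conditions: list[str]
    values: np.ndarray
    present: np.ndarray

    def __post_init__(self):
        for name, ids in (
            ("subjects", self.subjects),
            ("sessions", self.sessions),
            ("conditions", self.conditions),
        ):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers: {ids}")
        expected = (
            len(self.subjects),
            len(self.sessions),
            len(self.conditions),
            self.mask.n_voxels,
        )
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.present.shape != expected[:3]:
            raise ValueError("present flags shape mismatch")

    @property
    def grid(self) -> VolumeGrid:
        return self.mask.grid

    def _index(self, kind: str, ids: list[str], key: str) -> int:
        try:
            return ids.index(key)
        except ValueError:
            raise KeyError(f"unknown {kind} {key!r}; have {ids}") from None

    def get(self, subject: str, session: str, condition: str) -> np.ndarray:
        """Return the in-mask voxel vector of one cell (must be present)."""
        i = self._index("subject", self.subjects, subject)
        s = self._index("session", self.sessions, session)
        c = self._index("condition", self.conditions, condition)
        if not self.present[i, s, c]:
            raise KeyError(f"cell ({subject}, {session}, {condition}) is missing")
        return self.values[i, s, c]

    def is_present(self, subject: str, session: str, condition: str) -> bool:
        i = self._index("subject", self.subjects, subject)
        s = self._index("session", self.sessions, session)
        c = self._index("condition", self.conditions, condition)
        return bool(self.present[i, s, c])

    def complete_subjects(self, sessions: list[str], condition: str) -> list[str]:
        """Subjects with a present cell for *condition* in every listed session.

        Exclusion is pairwise per analysis: a subject missing one requested
        session is dropped here (and logged) without affecting other analyses.
        """
        c = self._index("condition", self.conditions, condition)
        s_idx = [self._index("session", self.sessions, s) for s in sessions]
        keep = [
            subj
            for i, subj in enumerate(self.subjects)
            if all(self.present[i, s, c] for s in s_idx)
        ]
        dropped = sorted(set(self.subjects) - set(keep))
        if dropped:
            logger.info(
                "excluding %d subject(s) missing %s/%s cells: %s",
                len(dropped), sessions, condition, dropped,
            )
        return keep

    def subset_array(
        self, subjects: list[str], sessions: list[str], condition: str
    ) -> np.ndarray:
        """Dense (n_subjects, n_sessions, n_voxels) array for one condition."""
        c = self._index("condition", self.conditions, condition)
        i_idx = [self._index("subject", self.subjects, s) for s in subjects]
        s_idx = [self._index("session", self.sessions, s) for s in sessions]
        return self.values[np.ix_(i_idx, s_idx, [c])][:, :, 0, :]


@dataclass(frozen=True)
class AtlasLabels:
    """Integer-labelled parcellation on the analysis grid (0 = background)."""

    grid: VolumeGrid
    labels: np.ndarray  # 3-D int array
    lookup: dict[int, str]  # label -> region name

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.shape:
            raise ValueError("atlas volume shape does not match grid")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if lab.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        missing = set(np.unique(lab[lab > 0]).tolist()) - set(self.lookup)
        if missing:
            raise ValueError(f"labels present in volume but absent from lookup: {sorted(missing)}")


class RatingsTable:
    """Validated in-scanner craving ratings: subject, session, condition, rating.

    Ratings come from a 0-100 visual-analogue scale; conditions are the two
    block types ``food`` and ``neutral``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(RATINGS_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"ratings table missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise ValueError("ratings table has no rows")
        frame = frame.loc[:, list(RATINGS_COLUMNS)].copy()
        frame["subject"] = frame["subject"].astype(str)
        frame["session"] = frame["session"].astype(str)
        frame["condition"] = frame["condition"].astype(str)
        frame["rating"] = pd.to_numeric(frame["rating"])
        bad_cond = ~frame["condition"].isin(RATING_CONDITIONS)
        if bad_cond.any():
            row = int(np.flatnonzero(bad_cond.to_numpy())[0])
            raise ValueError(
                f"unknown block condition {frame['condition'].iloc[row]!r} at row {row}"
            )
        out = (frame["rating"] < 0) | (frame["rating"] > 100) | frame["rating"].isna()
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise ValueError(
                f"rating outside [0, 100] at row {row}: {frame['rating'].iloc[row]}"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    @property
    def sessions(self) -> list[str]:
        return sorted(self.frame["session"].unique())


# ---------------------------------------------------------------------------
# Volume I/O


def _load_volume(path: str | Path) -> tuple[VolumeGrid, np.ndarray]:
    img = nib.load(str(path))
    if len(img.shape) == 4 and img.shape[3] == 1:
        data = np.asarray(img.dataobj, dtype=np.float64)[..., 0]
    elif len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a single 3-D volume, got shape {img.shape}"
        )
    else:
        data = np.asarray(img.dataobj, dtype=np.float64)
    grid = VolumeGrid(tuple(int(s) for s in data.shape), np.asarray(img.affine))
    return grid, data


def load_mask(path: str | Path) -> BrainMask:
    """Load a binary analysis mask; nonzero finite voxels are in-mask."""
    grid, data = _load_volume(path)
    flat = data.ravel()
    idx = np.flatnonzero(np.isfinite(flat) & (flat != 0))
    if idx.size == 0:
        raise ValueError(f"{path}: mask is empty")
    return BrainMask(grid, idx)


def write_map(values: np.ndarray, mask: BrainMask, out_path: str | Path) -> Path:
    """Write an in-mask voxel vector as a NIfTI volume; out-of-mask voxels are NaN.

    A round trip through :func:`load_map_values` reproduces finite values
    bit-exactly (data are stored as float64 with an identity scaling).
    """
    vol = mask.unmask(np.asarray(values, dtype=np.float64))
    img = nib.Nifti1Image(vol, mask.grid.affine)
    img.header.set_data_dtype(np.float64)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(out_path))
    return out_path


def load_map_values(path: str | Path, mask: BrainMask) -> np.ndarray:
    """Load one volume and return its in-mask voxel vector."""
    grid, data = _load_volume(path)
    if not grid.matches(mask.grid):
        raise ValueError(
            f"{path}: grid (shape {grid.shape}) does not match the mask grid "
            f"(shape {mask.grid.shape})"
        )
    return data.ravel()[mask.indices]


def load_stack(manifest_path: str | Path, mask_path: str | Path) -> MapStack:
    """Assemble a MapStack from a manifest TSV/CSV of per-cell volume paths.

    Manifest columns: subject, session, condition, path. Identifier order
    follows first appearance in the manifest; permuting rows yields an
    identical stack up to that ordering of first appearance. Cells absent
    from the manifest are flagged missing, never silently dropped.
    """
    manifest_path = Path(manifest_path)
    sep = "\t" if manifest_path.suffix.lower() in (".tsv", ".txt") else ","
    man = pd.read_csv(manifest_path, sep=sep)
    missing = set(MANIFEST_COLUMNS) - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    for col in ("subject", "session", "condition"):
        man[col] = man[col].astype(str)
    dup = man.duplicated(subset=["subject", "session", "condition"])
    if dup.any():
        rows = man.loc[dup, ["subject", "session", "condition"]].iloc[0].tolist()
        raise ValueError(f"duplicate manifest cell: {tuple(rows)}")

    mask = load_mask(mask_path)
    subjects = list(dict.fromkeys(man["subject"]))
    sessions = list(dict.fromkeys(man["session"]))
    conditions = list(dict.fromkeys(man["condition"]))

    # identifier-keyed ordering makes the stack independent of row order
    subjects, sessions, conditions = (sorted(x) for x in (subjects, sessions, conditions))
    shape = (len(subjects), len(sessions), len(conditions), mask.n_voxels)
    values = np.full(shape, np.nan, dtype=np.float64)
    present = np.zeros(shape[:3], dtype=bool)
    for rec in man.itertuples(index=False):
        i = subjects.index(rec.subject)
        s = sessions.index(rec.session)
        c = conditions.index(rec.condition)
        values[i, s, c] = load_map_values(rec.path, mask)
        present[i, s, c] = True
    n_missing = present.size - int(present.sum())
    if n_missing:
        logger.warning("manifest leaves %d cell(s) missing", n_missing)
    return MapStack(mask, subjects, sessions, conditions, values, present)


def load_atlas(path: str | Path, lut_path: str | Path) -> AtlasLabels:
    """Load an integer atlas volume with a (label, name) lookup table."""
    grid, data = _load_volume(path)
    labels = np.rint(data).astype(np.int64)
    if not np.allclose(data, labels, atol=1e-6, equal_nan=False):
        raise ValueError(f"{path}: atlas volume holds non-integer labels")
    lut_path = Path(lut_path)
    sep = "\t" if lut_path.suffix.lower() in (".tsv", ".txt") else ","
    lut = pd.read_csv(lut_path, sep=sep)
    if not {"label", "name"} <= set(lut.columns):
        raise ValueError("atlas lookup table needs columns: label, name")
    lookup = {int(l): str(n) for l, n in zip(lut["label"], lut["name"])}
    return AtlasLabels(grid, labels, lookup)


def load_ratings(path: str | Path) -> RatingsTable:
    """Load and validate a craving-ratings table (TSV or CSV with header)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no rows") from None
    if len(frame) == 0:
        raise ValueError(f"{path}: no rows")
    return RatingsTable(frame)
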