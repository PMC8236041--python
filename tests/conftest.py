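import numpy as np
import pytest

from relimap import BrainMask, MapStack, VolumeGrid


@pytest.fixture
def small_mask():
    """An 8-voxel mask on a 2x2x2 grid with identity affine."""
    grid = VolumeGrid((2, 2, 2), np.eye(4))
    return BrainMask(grid, np.arange(8))


def make_stack(values_by_cell, mask, subjects, sessions, conditions):
    """Build a MapStack from a {(subject, session, condition): vector} dict.

    Cells absent from the dict are flagged missing.
    """
    shape = (len(subjects), len(sessions), len(conditions), mask.n_voxels)
    values = np.full(shape, np.nan)
    present = np.zeros(shape[:3], dtype=bool)
    for (subj, sess, cond), vec in values_by_cell.items():
        i, s, c = subjects.index(subj), sessions.index(sess), conditions.index(cond)
        values[i, s, c] = np.asarray(vec, dtype=float)
        present[i, s, c] = True
    return MapStack(mask, list(subjects), list(sessions), list(conditions),
                    values, present)


@pytest.fixture
def make_noise_stack():
    """Factory: n subjects x k sessions of i.i.d. N(0,1) maps, one condition."""

    def _make(n_subjects, n_sessions, n_voxels, seed=0, condition="food"):
        rng = np.random.default_rng(seed)
        side = int(np.ceil(n_voxels ** (1 / 3)))
        grid = VolumeGrid((side, side, max(1, -(-n_voxels // side**2))), np.eye(4))
        total = int(np.prod(grid.shape))
        mask = BrainMask(grid, np.arange(n_voxels) if n_voxels <= total else np.arange(total))
        subjects = [f"s{i}" for i in range(n_subjects)]
        sessions = [f"T{i}" for i in range(n_sessions)]
        values = rng.standard_normal((n_subjects, n_sessions, 1, mask.n_voxels))
        present = np.ones((n_subjects, n_sessions, 1), dtype=bool)
        return MapStack(mask, subjects, sessions, [condition], values, present)

    return _make
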