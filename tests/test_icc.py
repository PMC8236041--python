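import numpy as np
import pytest

from relimap import (
    PhantomSpec,
    atlas_summary,
    generate_stack,
    icc_consistency,
    reliability_band,
    threshold_icc,
    voxelwise_icc,
)
from relimap.icc import ICCMap
from relimap.io import AtlasLabels
from conftest import make_stack


def brute_force_icc31(matrix):
    """Independent oracle: explicit two-way ANOVA sums of squares via loops."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    grand = m.mean()
    ss_subj = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_sess = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_subj / (n - 1)
    ems = (ss_tot - ss_subj - ss_sess) / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    return np.nan if denom == 0 else (bms - ems) / denom


class TestIccConsistency:
    def test_perfect_consistency_with_session_shift(self):
        assert icc_consistency([[1, 2], [3, 4], [5, 6]]) == pytest.approx(1.0)

    def test_no_between_subject_variance_is_nan(self):
        assert np.isnan(icc_consistency([[1, 2], [1, 2], [1, 2]]))

    def test_crossed_pair_gives_minus_one(self):
        # hand two-way ANOVA: BMS = 0, EMS = 1 -> (0-1)/(0+1) = -1
        assert icc_consistency([[1, 2], [2, 1]]) == pytest.approx(-1.0)

    def test_nan_cell_raises(self):
        with pytest.raises(ValueError):
            icc_consistency([[1, np.nan], [2, 1]])

    def test_too_small_matrix_raises(self):
        with pytest.raises(ValueError):
            icc_consistency([[1, 2]])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.standard_normal((8, 3)) * rng.uniform(0.5, 5)
            assert icc_consistency(m) == pytest.approx(
                brute_force_icc31(m), abs=1e-8
            )

    def test_agrees_with_pingouin(self):
        """Cross-check against an independent published implementation."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        m = rng.standard_normal((10, 3)) + rng.standard_normal((10, 1)) * 2
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "session": np.tile(np.arange(3), 10),
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            long, targets="subject", raters="session", ratings="y"
        )
        # consistency, single measurement: labelled ICC3 or ICC(C,1) by version
        row = ref["Type"].isin(["ICC3", "ICC(C,1)"])
        icc3 = ref.loc[row, "ICC"].iloc[0]
        assert icc_consistency(m) == pytest.approx(icc3, abs=1e-8)

    def test_invariant_to_session_constants(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((7, 3))
        shifted = m + np.array([10.0, -3.5, 100.0])
        assert abs(icc_consistency(m) - icc_consistency(shifted)) < 1e-10

    def test_invariant_to_location_and_positive_scale(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((6, 4))
        assert icc_consistency(3.7 * m + 11.0) == pytest.approx(
            icc_consistency(m), abs=1e-10
        )

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            v = icc_consistency(rng.standard_normal((5, 3)))
            if np.isfinite(v):
                assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestVoxelwiseIcc:
    def test_cloned_session_gives_unit_icc(self, small_mask):
        rng = np.random.default_rng(1)
        maps = {f"s{i}": rng.standard_normal(8) for i in range(4)}
        cells = {(s, t, "c"): maps[s] for s in maps for t in ("T0", "T1")}
        stack = make_stack(cells, small_mask, sorted(maps), ["T0", "T1"], ["c"])
        icc_map = voxelwise_icc(stack, "c")
        assert np.allclose(icc_map.values, 1.0)

    def test_no_subject_signal_gives_near_zero_mean(self):
        spec = PhantomSpec(
            shape=(10, 10, 10), n_subjects=100, sessions=("T0", "T1", "T2"),
            sigma2_between=0.0, sigma2_within=1.0, seed=10,
        )
        stack, _ = generate_stack(spec)
        icc_map = voxelwise_icc(stack, spec.conditions[0])
        assert abs(np.nanmean(icc_map.values)) < 0.05

    def test_nan_is_per_voxel_not_listwise(self, small_mask):
        rng = np.random.default_rng(6)
        cells = {
            (s, t, "c"): rng.standard_normal(8)
            for s in ("s0", "s1", "s2") for t in ("T0", "T1")
        }
        cells[("s1", "T0", "c")] = np.array(
            [np.nan, 1, 2, 0.5, -1, 0.3, 2, 1.0]
        )
        stack = make_stack(cells, small_mask, ["s0", "s1", "s2"], ["T0", "T1"], ["c"])
        icc_map = voxelwise_icc(stack, "c")
        assert np.isnan(icc_map.values[0])
        assert np.isfinite(icc_map.values[1:]).all()

    def test_missing_subject_excluded_listwise(self, small_mask):
        rng = np.random.default_rng(6)
        cells = {
            (s, t, "c"): rng.standard_normal(8)
            for s in ("s0", "s1", "s2") for t in ("T0", "T1")
        }
        del cells[("s2", "T1", "c")]
        stack = make_stack(cells, small_mask, ["s0", "s1", "s2"], ["T0", "T1"], ["c"])
        icc_map = voxelwise_icc(stack, "c", ["T0", "T1"])
        assert icc_map.n_subjects == 2

    def test_fewer_than_two_complete_subjects_raises(self, small_mask):
        cells = {("s0", t, "c"): np.ones(8) for t in ("T0", "T1")}
        cells[("s1", "T0", "c")] = np.ones(8)
        stack = make_stack(cells, small_mask, ["s0", "s1"], ["T0", "T1"], ["c"])
        with pytest.raises(ValueError):
            voxelwise_icc(stack, "c", ["T0", "T1"])


class TestThresholdIcc:
    def _map(self, small_mask, values):
        return ICCMap(small_mask, np.asarray(values, float), ["T0", "T1"], 5)

    def test_above_cutoff_active(self, small_mask):
        assert threshold_icc(self._map(small_mask, [0.8] * 8)).active.all()

    def test_strict_inequality(self, small_mask):
        assert threshold_icc(self._map(small_mask, [0.75] * 8)).size == 0

    def test_nan_inactive(self, small_mask):
        vals = [np.nan, 0.9, np.nan, 0.9, 0.2, 0.9, 0.9, np.nan]
        assert threshold_icc(self._map(small_mask, vals)).size == 4

    def test_cutoff_validation(self, small_mask):
        with pytest.raises(ValueError):
            threshold_icc(self._map(small_mask, [0.5] * 8), cutoff=1.0)


class TestAtlasSummary:
    def _atlas(self, small_mask, labels, lookup):
        return AtlasLabels(
            small_mask.grid, np.asarray(labels).reshape(2, 2, 2), lookup
        )

    def test_single_region_constant_map(self, small_mask):
        icc_map = ICCMap(small_mask, np.full(8, 0.5), ["T0", "T1"], 5)
        atlas = self._atlas(small_mask, np.ones(8, dtype=int), {1: "all"})
        table = atlas_summary(icc_map, atlas)
        assert table.loc[0, "mean_icc"] == pytest.approx(0.5)
        assert table.loc[0, "band"] == "fair"

    def test_region_mean_and_band(self, small_mask):
        vals = np.array([0.5, 1.0, 0.5, 1.0, 0.0, 0.0, 0.0, 0.0])
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        icc_map = ICCMap(small_mask, vals, ["T0", "T1"], 5)
        table = atlas_summary(
            icc_map, self._atlas(small_mask, labels, {1: "roi", 2: "rest"})
        )
        row = table.set_index("label").loc[1]
        assert row["mean_icc"] == pytest.approx(0.75)
        assert row["band"] == "good"

    def test_nan_voxels_excluded_from_mean(self, small_mask):
        vals = np.array([np.nan, 0.9, np.nan, 0.9, np.nan, 0.9, np.nan, 0.9])
        icc_map = ICCMap(small_mask, vals, ["T0", "T1"], 5)
        table = atlas_summary(
            icc_map, self._atlas(small_mask, np.ones(8, int), {1: "all"})
        )
        assert table.loc[0, "mean_icc"] == pytest.approx(0.9)
        assert table.loc[0, "n_finite"] == 4

    def test_unknown_label_raises(self, small_mask):
        with pytest.raises(ValueError, match="lookup"):
            self._atlas(small_mask, np.full(8, 3, dtype=int), {1: "a"})


@pytest.mark.parametrize(
    "icc,band",
    [(-0.2, "poor"), (0.39, "poor"), (0.4, "fair"), (0.6, "good"),
     (0.75, "good"), (0.76, "excellent"), (float("nan"), "undefined")],
)
def test_fleiss_bands(icc, band):
    assert reliability_band(icc) == band
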