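import numpy as np
import pytest

from relimap import BinaryMap, binarize, critical_t, dice, jaccard
from relimap.overlap import overlap_summary, overlap_table, rm_anova_overlap
from conftest import make_stack

# one-sided critical t for df=440, p=0.001, computed with an independent
# quantile routine before the implementation existed
T_CRIT_440_P001 = 3.108857469982983


def bmap(mask, flags):
    return BinaryMap(mask, np.asarray(flags, dtype=bool))


class TestBinarize:
    def test_near_unity_threshold_activates_everything(self, small_mask):
        vec = np.array([-3.0, -1.0, 0.0, 0.5, 1.0, 2.0, 5.0, -0.1])
        b = binarize(vec, small_mask, df=10, p_threshold=0.999999)
        assert b.active.all()

    def test_zero_map_is_empty(self, small_mask):
        b = binarize(np.zeros(8), small_mask, df=440, p_threshold=0.001)
        assert b.size == 0

    def test_critical_t_for_p_001(self, small_mask):
        assert critical_t(440, 0.001) == pytest.approx(T_CRIT_440_P001, abs=1e-9)
        b = binarize(np.full(8, 5.0), small_mask, df=440, p_threshold=0.001)
        assert b.active.all()  # 5.0 exceeds the critical t of ~3.109

    def test_nan_voxels_inactive(self, small_mask):
        vec = np.array([np.nan, 10.0, np.nan, 10.0, 10.0, 10.0, 10.0, 10.0])
        b = binarize(vec, small_mask, df=440, p_threshold=0.001)
        assert b.size == 6

    def test_directions(self, small_mask):
        vec = np.array([-5.0, 5.0, 0.0, -5.0, 5.0, 0.0, 0.0, 0.0])
        pos = binarize(vec, small_mask, df=440, p_threshold=0.001, direction="positive")
        neg = binarize(vec, small_mask, df=440, p_threshold=0.001, direction="negative")
        two = binarize(vec, small_mask, df=440, p_threshold=0.001, direction="two_sided")
        assert pos.size == 2 and neg.size == 2 and two.size == 4

    def test_leniency_is_monotone_in_p(self, small_mask):
        rng = np.random.default_rng(0)
        vec = rng.standard_normal(8) * 3
        sizes = [
            binarize(vec, small_mask, df=30, p_threshold=p).size
            for p in (0.0001, 0.001, 0.01, 0.05, 0.2)
        ]
        assert sizes == sorted(sizes)

    def test_invalid_df_raises(self, small_mask):
        with pytest.raises(ValueError):
            binarize(np.zeros(8), small_mask, df=np.inf, p_threshold=0.001)


class TestJaccardDice:
    def test_hand_enumerated_sets(self, small_mask):
        a = bmap(small_mask, [1, 1, 0, 0, 0, 0, 0, 0])
        b = bmap(small_mask, [0, 1, 1, 0, 0, 0, 0, 0])
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert dice(a, b) == pytest.approx(1 / 2)

    def test_identical_sets_are_perfect(self, small_mask):
        a = bmap(small_mask, [1, 0, 1, 1, 0, 0, 1, 0])
        assert jaccard(a, a) == 1.0 and dice(a, a) == 1.0

    def test_disjoint_sets_are_zero(self, small_mask):
        a = bmap(small_mask, [1, 1, 0, 0, 0, 0, 0, 0])
        b = bmap(small_mask, [0, 0, 1, 1, 0, 0, 0, 0])
        assert jaccard(a, b) == 0.0 and dice(a, b) == 0.0

    def test_empty_union_is_nan(self, small_mask):
        a = bmap(small_mask, np.zeros(8))
        assert np.isnan(jaccard(a, a)) and np.isnan(dice(a, a))

    def test_mask_mismatch_raises(self, small_mask):
        from relimap import BrainMask, VolumeGrid

        other = BrainMask(VolumeGrid((2, 2, 2), np.eye(4)), np.arange(4))
        a = bmap(small_mask, np.ones(8))
        b = BinaryMap(other, np.ones(4, dtype=bool))
        with pytest.raises(ValueError):
            jaccard(a, b)

    def test_identity_symmetry_and_ordering_on_random_pairs(self, small_mask):
        """dice = 2J/(1+J), dice >= jaccard, both symmetric, on random maps."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = bmap(small_mask, rng.random(8) < rng.random())
            b = bmap(small_mask, rng.random(8) < rng.random())
            j, d = jaccard(a, b), dice(a, b)
            assert jaccard(b, a) == j if np.isfinite(j) else np.isnan(jaccard(b, a))
            if np.isnan(j):
                assert np.isnan(d)
                continue
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
            assert d >= j
            assert (d == j) == (j in (0.0, 1.0))


class TestOverlapTable:
    def _identical_stack(self, small_mask, n=3):
        rng = np.random.default_rng(1)
        maps = {f"s{i}": rng.standard_normal(8) * 4 for i in range(n)}
        cells = {
            (s, t, "food"): maps[s] for s in maps for t in ("T0", "T1", "T2")
        }
        return make_stack(cells, small_mask, sorted(maps), ["T0", "T1", "T2"], ["food"])

    def test_identical_sessions_give_unit_means(self, small_mask):
        stack = self._identical_stack(small_mask)
        table = overlap_table(
            stack, ["food"], [("T0", "T1"), ("T1", "T2")], t_threshold=1.0
        )
        summ = overlap_summary(table)
        assert np.allclose(summ["mean_dice"], 1.0)
        assert np.allclose(summ["sd_dice"], 0.0)

    def test_hand_built_counts(self, small_mask):
        cells = {
            ("s0", "T0", "food"): [5, 5, 0, 0, 0, 0, 0, 0],
            ("s0", "T1", "food"): [0, 5, 5, 0, 0, 0, 0, 0],
            ("s1", "T0", "food"): [5, 5, 5, 5, 0, 0, 0, 0],
            ("s1", "T1", "food"): [5, 5, 0, 0, 0, 0, 0, 0],
            ("s2", "T0", "food"): [5, 0, 0, 0, 0, 0, 0, 5],
            ("s2", "T1", "food"): [5, 0, 0, 0, 0, 0, 0, 5],
        }
        stack = make_stack(
            cells, small_mask, ["s0", "s1", "s2"], ["T0", "T1"], ["food"]
        )
        table = overlap_table(stack, ["food"], [("T0", "T1")], t_threshold=1.0)
        by_subj = table.set_index("subject")
        # s0: |A|=2 |B|=2 |A&B|=1 -> J=1/3 D=1/2
        assert by_subj.loc["s0", "jaccard"] == pytest.approx(1 / 3)
        # s1: |A|=4 |B|=2 |A&B|=2 -> J=1/2 D=2/3
        assert by_subj.loc["s1", "dice"] == pytest.approx(2 / 3)
        # s2: identical -> 1.0
        assert by_subj.loc["s2", "jaccard"] == 1.0

    def test_too_few_subjects_raises(self, small_mask):
        cells = {("s0", t, "food"): np.ones(8) for t in ("T0", "T1")}
        stack = make_stack(cells, small_mask, ["s0"], ["T0", "T1"], ["food"])
        with pytest.raises(ValueError, match="fewer than 2"):
            overlap_table(stack, ["food"], [("T0", "T1")], t_threshold=0.5)


class TestRmAnova:
    @staticmethod
    def _table(values):
        """values[subject][pair][contrast] -> long OverlapTable frame."""
        import pandas as pd

        rows = []
        for subj, pairs in values.items():
            for pair, conds in pairs.items():
                for cond, v in conds.items():
                    rows.append(
                        {"subject": subj, "pair": pair, "contrast": cond,
                         "jaccard": v, "dice": v}
                    )
        return pd.DataFrame(rows)

    def test_constant_table_gives_zero_f(self):
        vals = {
            f"s{i}": {p: {c: 0.5 for c in ("f", "n")} for p in ("P1", "P2")}
            for i in range(4)
        }
        res = rm_anova_overlap(self._table(vals))
        assert res["factors"]["contrast"]["F"] == 0.0
        assert res["factors"]["pair"]["F"] == 0.0

    def test_matches_manual_two_way_rm_anova(self):
        """F for each factor equals hand-computed repeated-measures sums of squares."""
        rng = np.random.default_rng(3)
        subj, pairs, conds = 4, ("P1", "P2"), ("f", "n", "d")
        data = rng.random((subj, len(pairs), len(conds)))
        vals = {
            f"s{i}": {
                p: {c: data[i, j, k] for k, c in enumerate(conds)}
                for j, p in enumerate(pairs)
            }
            for i in range(subj)
        }
        res = rm_anova_overlap(self._table(vals))

        # independent oracle: explicit sums of squares for factor "contrast"
        cell = data  # (n, P, C)
        n, P, C = cell.shape
        cond_means = cell.mean(axis=(0, 1))  # per contrast
        subj_cond = cell.mean(axis=1)  # (n, C)
        grand = cell.mean()
        ss_c = n * P * ((cond_means - grand) ** 2).sum()
        ss_subj = P * C * ((cell.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_sc = P * ((subj_cond - grand) ** 2).sum() - ss_c - ss_subj
        f_c = (ss_c / (C - 1)) / (ss_sc / ((n - 1) * (C - 1)))
        assert res["factors"]["contrast"]["F"] == pytest.approx(f_c, rel=1e-10)

        pair_means = cell.mean(axis=(0, 2))
        subj_pair = cell.mean(axis=2)
        ss_p = n * C * ((pair_means - grand) ** 2).sum()
        ss_sp = C * ((subj_pair - grand) ** 2).sum() - ss_p - ss_subj
        f_p = (ss_p / (P - 1)) / (ss_sp / ((n - 1) * (P - 1)))
        assert res["factors"]["pair"]["F"] == pytest.approx(f_p, rel=1e-10)

    def test_large_condition_effect_detected(self):
        rng = np.random.default_rng(9)
        vals = {
            f"s{i}": {
                p: {"f": 0.7 + rng.normal(0, 0.01),
                    "n": 0.7 + rng.normal(0, 0.01),
                    "d": 0.2 + rng.normal(0, 0.01)}
                for p in ("P1", "P2", "P3")
            }
            for i in range(6)
        }
        res = rm_anova_overlap(self._table(vals), difference_contrast="d")
        assert res["factors"]["contrast"]["p"] < 0.001
        assert all(ph["p_bonferroni"] < 0.001 for ph in res["posthoc"])
        assert all(ph["t"] < 0 for ph in res["posthoc"])  # difference is lower

    def test_incomplete_design_raises(self):
        vals = {
            "s0": {"P1": {"f": 0.5, "n": 0.4}},
            "s1": {"P1": {"f": 0.5}},
        }
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_overlap(self._table(vals))
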