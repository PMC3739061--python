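import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modreorg import (
    classify,
    control_gmc,
    group_stats,
    index_a,
    index_b,
    module_gmc,
)
from modreorg.biomarkers import (
    auc_rank,
    build_biomarker_table,
    roc_points,
)
from modreorg.connectivity import ConnectivityMatrix


def _toy_cm(pair_cc, left_cc=0.0, right_cc=0.0, subject_id="s", group=""):
    """4-region matrix for the toy atlas subset 'ab': pairs (1,2), (3,4).

    pair_cc: (cc_12, cc_34); left_cc = cc_13; right_cc = cc_24.
    Regions 5, 6 stay uncorrelated.
    """
    cc = np.eye(6)
    cc[0, 1] = cc[1, 0] = pair_cc[0]
    cc[2, 3] = cc[3, 2] = pair_cc[1]
    cc[0, 2] = cc[2, 0] = left_cc
    cc[1, 3] = cc[3, 1] = right_cc
    return ConnectivityMatrix(subject_id=subject_id, cc=cc, group=group)


class TestIndexA:
    def test_all_ones(self, toy_atlas):
        cm = _toy_cm((1.0, 1.0))
        assert index_a(cm, toy_atlas, "ab") == pytest.approx(1.0)

    def test_arithmetic_mean(self, toy_atlas):
        cm = _toy_cm((0.8, 0.2))
        assert index_a(cm, toy_atlas, "ab") == pytest.approx(0.5)

    def test_four_pair_mean(self, atlas116):
        cc = np.eye(116)
        vals = {11: 0.8, 13: 0.6, 29: 0.4, 73: 0.2}
        subset = (11, 12, 13, 14, 29, 30, 73, 74)
        for left, v in vals.items():
            i, j = atlas116.index_of(left), atlas116.index_of(left + 1)
            cc[i, j] = cc[j, i] = v
        atlas = atlas116
        from dataclasses import replace
        atlas = replace(atlas116, named_subsets={"four": subset})
        cm = ConnectivityMatrix(subject_id="s", cc=cc)
        assert index_a(cm, atlas, "four") == pytest.approx(0.5)

    def test_negative_cc_allowed(self, toy_atlas):
        cm = _toy_cm((-0.4, 0.2))
        assert index_a(cm, toy_atlas, "ab") == pytest.approx(-0.1)

    def test_direct_entry_lookup(self, toy_atlas):
        cm = _toy_cm((0.37, 0.91))
        expected = (cm.cc[0, 1] + cm.cc[2, 3]) / 2
        assert index_a(cm, toy_atlas, "ab") == pytest.approx(expected,
                                                             rel=1e-15)


class TestIndexB:
    def test_constant_unilateral(self, toy_atlas):
        cm = _toy_cm((0.0, 0.0), left_cc=0.3, right_cc=0.3)
        assert index_b(cm, toy_atlas, "ab") == pytest.approx(0.3)

    def test_default_mode_two_pairs(self, toy_atlas):
        cm = _toy_cm((0.0, 0.0), left_cc=0.4, right_cc=0.6)
        assert index_b(cm, toy_atlas, "ab") == pytest.approx(0.5)

    def test_literal_mode_exceeds_one(self, toy_atlas):
        # (0.4 * 2 + 0.6 * 2 + 4 * 1) / 2 = 3.0 -- the printed
        # normalization counts ordered terms and self-correlations
        cm = _toy_cm((0.0, 0.0), left_cc=0.4, right_cc=0.6)
        assert index_b(cm, toy_atlas, "ab",
                       mode="literal") == pytest.approx(3.0)

    def test_single_pair_rejected(self, toy_atlas):
        from dataclasses import replace
        atlas = replace(toy_atlas, named_subsets={"one": (1, 2)})
        with pytest.raises(ValueError, match="at least 2 pairs"):
            index_b(_toy_cm((0.5, 0.5)), atlas, "one")


class TestModuleGmc:
    def _gmc(self, values):
        rows = []
        for sid, vals in values.items():
            rows.append({"subject_id": sid, "group": "CN",
                         **{str(k): v for k, v in vals.items()}})
        return pd.DataFrame(rows)

    def test_constant(self, toy_atlas):
        gmc = self._gmc({"a": {1: 0.5, 2: 0.5, 3: 0.5, 4: 0.5},
                         "b": {1: 0.5, 2: 0.5, 3: 0.5, 4: 0.5}})
        out = module_gmc(gmc, toy_atlas, "ab")
        assert (out == 0.5).all()

    def test_two_region_mean(self, toy_atlas):
        gmc = self._gmc({"a": {1: 0.4, 2: 0.6}})
        out = module_gmc(gmc, toy_atlas, [1, 2])
        assert out["a"] == pytest.approx(0.5)

    def test_missing_cell_named(self, toy_atlas):
        gmc = self._gmc({"a": {1: 0.4, 2: np.nan}})
        with pytest.raises(ValueError, match="subject 'a', region 2"):
            module_gmc(gmc, toy_atlas, [1, 2])

    def test_missing_region_column(self, toy_atlas):
        gmc = self._gmc({"a": {1: 0.4}})
        with pytest.raises(ValueError, match="no column for region 2"):
            module_gmc(gmc, toy_atlas, [1, 2])


class TestControlGmc:
    def _table(self, index_a_vals, gmc_vals, groups=None):
        n = len(index_a_vals)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": groups or ["CN"] * n,
            "index_A": index_a_vals,
            "gmc_module_mean": gmc_vals,
        })

    def test_exact_linear_gives_zero_residuals(self):
        g = np.linspace(0.4, 0.6, 10)
        bt = control_gmc(self._table(2.0 * g + 1.0, g))
        np.testing.assert_allclose(bt["residual_index_A"], 0.0, atol=1e-12)

    def test_residuals_zero_mean(self):
        rng = np.random.default_rng(0)
        bt = control_gmc(self._table(rng.random(20), rng.random(20)))
        assert bt["residual_index_A"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_independent_covariate_keeps_group_gap(self):
        rng = np.random.default_rng(1)
        n = 200
        groups = ["CN"] * n + ["AD"] * n
        ia = np.r_[rng.normal(0.6, 0.05, n), rng.normal(0.2, 0.05, n)]
        gmc = rng.normal(0.5, 0.05, 2 * n)  # independent of index A
        bt = control_gmc(self._table(ia, gmc, groups))
        raw = group_stats(bt, "index_A").means
        res = group_stats(bt, "residual_index_A").means
        assert (raw[0] - raw[1]) == pytest.approx(res[0] - res[1], abs=0.02)

    def test_zero_gmc_variance_centers(self, caplog):
        with caplog.at_level("WARNING"):
            bt = control_gmc(self._table([0.1, 0.2, 0.3], [0.5, 0.5, 0.5]))
        assert "zero GMC variance" in caplog.text
        np.testing.assert_allclose(bt["residual_index_A"],
                                   [-0.1, 0.0, 0.1], atol=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 3"):
            control_gmc(self._table([0.1, 0.2], [0.4, 0.5]))

    def test_confound_removed(self):
        # index A depends on GMC only; the group difference in index A is
        # entirely mediated by the GMC shift, so residuals should not differ
        rejections_raw, rejections_res = 0, 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 30
            gmc = np.r_[rng.normal(0.55, 0.05, n), rng.normal(0.45, 0.05, n)]
            ia = 2.0 * gmc + rng.normal(0, 0.02, 2 * n)
            bt = control_gmc(self._table(
                ia, gmc, ["CN"] * n + ["AD"] * n))
            rejections_raw += group_stats(bt, "index_A").p < 0.05
            rejections_res += group_stats(bt, "residual_index_A").p < 0.05
        assert rejections_raw == 40
        assert rejections_res <= 8  # holds size roughly at alpha


class TestGroupStats:
    def test_identical_groups(self):
        bt = pd.DataFrame({"group": ["CN"] * 3 + ["AD"] * 3,
                           "x": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]})
        st = group_stats(bt, "x")
        assert st.t == pytest.approx(0.0)
        assert st.p == pytest.approx(1.0)

    def test_cohens_d_definition(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.6, 0.2, 30)
        y = rng.normal(0.2, 0.2, 30)
        x = (x - x.mean()) / x.std(ddof=1) * 0.2 + 0.6
        y = (y - y.mean()) / y.std(ddof=1) * 0.2 + 0.2
        bt = pd.DataFrame({"group": ["CN"] * 30 + ["AD"] * 30,
                           "x": np.r_[x, y]})
        assert group_stats(bt, "x").cohens_d == pytest.approx(2.0, abs=1e-10)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 2, 20)
        bt = pd.DataFrame({"group": ["CN"] * 15 + ["AD"] * 20,
                           "x": np.r_[x, y]})
        st = group_stats(bt, "x")
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert st.t == pytest.approx(t)
        assert st.p == pytest.approx(p)

    def test_degenerate_group(self):
        bt = pd.DataFrame({"group": ["CN", "AD", "AD"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match=">= 2 subjects"):
            group_stats(bt, "x")


class TestRocAuc:
    def _bt(self, scores, labels, feature="index_A"):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(scores))],
            "group": ["AD" if y else "CN" for y in labels],
            feature: scores,
        })

    def test_perfect_separation_exact_one(self):
        bt = self._bt([0.1, 0.2, 0.3, 0.8, 0.9, 1.0],
                      [False, False, False, True, True, True])
        assert classify(bt, ("index_A",)).auc == 1.0

    def test_null_feature_near_half(self):
        rng = np.random.default_rng(4)
        n = 1000
        bt = self._bt(rng.random(2 * n), [False] * n + [True] * n)
        res = classify(bt, ("index_A",))
        assert abs(res.auc - 0.5) < 0.05

    def test_rank_equals_trapezoid(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.random(200), 2)  # force ties
        labels = rng.random(200) < 0.4
        fpr, tpr, _ = roc_points(scores, labels)
        area = np.trapezoid(tpr, fpr)
        assert auc_rank(scores, labels) == pytest.approx(area, abs=1e-10)

    def test_roc_is_monotone_step_curve(self):
        rng = np.random.default_rng(6)
        fpr, tpr, _ = roc_points(rng.random(50), rng.random(50) < 0.5)
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    def test_orientation_flip_recorded(self):
        bt = self._bt([1.0, 0.9, 0.8, 0.2, 0.1, 0.0],
                      [False, False, False, True, True, True])
        res = classify(bt, ("index_A",))
        assert res.flipped
        assert res.auc == 1.0

    def test_combined_beats_singles_in_sample(self):
        rng = np.random.default_rng(7)
        n = 100
        labels = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        f1 = rng.normal(0, 1, 2 * n) + labels * 1.0
        f2 = rng.normal(0, 1, 2 * n) + labels * 1.0
        bt = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "group": ["AD" if y else "CN" for y in labels],
            "index_A": f1, "gmc_module_mean": f2,
        })
        both = classify(bt, ("index_A", "gmc_module_mean")).auc
        singles = max(classify(bt, ("index_A",)).auc,
                      classify(bt, ("gmc_module_mean",)).auc)
        assert both >= singles - 0.02

    def test_degenerate_single_class(self):
        bt = self._bt([0.1, 0.2, 0.3, 0.4], [False] * 4)
        with pytest.raises(ValueError, match="two groups|>= 2 subjects"):
            classify(bt, ("index_A",))


class TestBiomarkerTable:
    def test_build_table(self, toy_atlas):
        cms = [_toy_cm((0.8, 0.6), 0.2, 0.4, subject_id="a", group="CN"),
               _toy_cm((0.2, 0.0), 0.1, 0.1, subject_id="b", group="AD")]
        gmc = pd.DataFrame({
            "subject_id": ["a", "b"], "group": ["CN", "AD"],
            **{str(i): [0.5, 0.4] for i in range(1, 7)},
        })
        bt = build_biomarker_table(cms, toy_atlas, gmc=gmc, pairs="ab")
        assert bt.loc[0, "index_A"] == pytest.approx(0.7)
        assert bt.loc[1, "index_A"] == pytest.approx(0.1)
        assert bt.loc[0, "index_B"] == pytest.approx(0.3)
        assert bt.loc[0, "gmc_module_mean"] == pytest.approx(0.5)
        assert abs(bt["index_A"]).max() <= 1.0
        assert abs(bt["index_B"]).max() <= 1.0
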