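"""Unit tests for preprocessing, two-tier split, MANOVA, PCA and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import coralstress as cs
from coralstress.exceptions import DegeneracyError, DesignError, TransformError


def _frame(values_fn, n_per_cell=30, temps=(26, 30), preds=("no_lesion", "lesion"),
           rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for t in temps:
        for p in preds:
            for _ in range(n_per_cell):
                row = {"species": "sp", "temperature": t, "predation": p}
                row.update(values_fn(rng))
                rows.append(row)
    return pd.DataFrame(rows)


class TestPreprocess:
    def test_normal_data_untransformed(self):
        # fixed draw that satisfies both assumptions (at alpha = 0.05 a
        # random normal dataset still trips a gate ~25% of the time)
        df = _frame(lambda r: {"hsp70": r.normal(), "ub": r.normal(),
                               "tac": r.normal()}, n_per_cell=50,
                    rng=np.random.default_rng(1))
        out, report = cs.preprocess(df)
        assert (report.table["transform"] == "none").all()
        pd.testing.assert_frame_equal(out, df)

    def test_lognormal_data_triggers_transform(self):
        # 100 obs/cell of clearly skewed data: the normality gate should
        # fire essentially always; check 20 independent seeds
        triggered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = _frame(
                lambda r: {"hsp70": r.lognormal(0, 0.8), "ub": r.lognormal(0, 0.8),
                           "tac": r.lognormal(0, 0.8)},
                n_per_cell=100, rng=rng,
            )
            _, report = cs.preprocess(df)
            triggered += (report.table["transform"] == "log+autoscale").all()
        assert triggered >= 19

    def test_transformed_columns_are_autoscaled(self):
        rng = np.random.default_rng(1)
        df = _frame(lambda r: {"hsp70": r.lognormal(0, 0.8), "ub": r.lognormal(0, 0.8),
                               "tac": r.lognormal(0, 0.8)}, n_per_cell=100, rng=rng)
        out, report = cs.preprocess(df)
        assert (report.table["transform"] == "log+autoscale").all()
        for b in ("hsp70", "ub", "tac"):
            assert abs(out[b].mean()) < 1e-12
            assert out[b].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_values_fail_loudly(self):
        rng = np.random.default_rng(2)
        df = _frame(lambda r: {"hsp70": r.lognormal(0, 1.0), "ub": 1.0, "tac": 1.0},
                    n_per_cell=60, rng=rng)
        df.loc[3, "hsp70"] = 0.0
        with pytest.raises(TransformError, match="hsp70"):
            cs.preprocess(df)


class TestTwoTierSplit:
    def test_default_synthetic_design(self, biomarker_matrix):
        moderate, severe = cs.two_tier_split(biomarker_matrix)
        assert moderate["species"].nunique() == 7
        assert sorted(moderate["temperature"].unique()) == [26, 30]
        assert severe["species"].nunique() == 3
        assert sorted(severe["temperature"].unique()) == [26, 30, 32]

    def test_all_survivors_means_full_severe_set(self):
        df = _frame(lambda r: {"hsp70": 1.0, "ub": 1.0, "tac": 1.0},
                    n_per_cell=3, temps=(26, 30, 32))
        _, severe = cs.two_tier_split(df)
        pd.testing.assert_frame_equal(severe, df)

    def test_matches_brute_force_missing_cell_scan(self, biomarker_matrix):
        _, severe = cs.two_tier_split(biomarker_matrix)
        temps = set(biomarker_matrix["temperature"].unique())
        keep = {
            sp
            for sp in biomarker_matrix["species"].unique()
            if set(biomarker_matrix.loc[biomarker_matrix["species"] == sp,
                                        "temperature"]) == temps
        }
        assert set(severe["species"].unique()) == keep


class TestFactorialManova:
    def test_single_response_equals_univariate_f(self):
        rng = np.random.default_rng(5)
        df = _frame(lambda r: {"ub": r.normal()}, n_per_cell=10)
        res = cs.factorial_manova(
            df, responses=("ub",), factors=("temperature", "predation")
        )
        # balanced design: Type III F for a main effect equals the
        # classical two-way ANOVA F; oracle via explicit SS decomposition
        ybar = df["ub"].mean()
        cell = df.groupby(["temperature", "predation"])["ub"].mean()
        a = df.groupby("temperature")["ub"].mean()
        ss_a = 20 * ((a - ybar) ** 2).sum()
        merged = df.merge(cell.rename("m"), on=["temperature", "predation"])
        ss_err = ((merged["ub"] - merged["m"]) ** 2).sum()
        f_oracle = (ss_a / 1) / (ss_err / (len(df) - 4))
        got = res.multivariate["temperature"]
        assert got.statistic == pytest.approx(f_oracle, rel=1e-9)
        uni = res.univariate.set_index("term")
        assert uni.loc["temperature", "F"] == pytest.approx(f_oracle, rel=1e-9)

    def test_wilks_invariant_under_affine_rescaling(self, biomarker_matrix):
        moderate, _ = cs.two_tier_split(biomarker_matrix)
        base = cs.factorial_manova(moderate, run_tukey=False)
        scaled = moderate.copy()
        scaled["ub"] = scaled["ub"] * 1000.0 + 5.0
        res = cs.factorial_manova(scaled, run_tukey=False)
        for term, r in base.multivariate.items():
            assert res.multivariate[term].wilks_lambda == pytest.approx(
                r.wilks_lambda, rel=1e-9
            )
            assert res.multivariate[term].statistic == pytest.approx(
                r.statistic, rel=1e-9
            )

    def test_incomplete_design_rejected(self, biomarker_matrix):
        # the full matrix misses thermosensitive 32 degC cells: Type III
        # terms are inestimable and must not be silently reported
        with pytest.raises((DesignError, DegeneracyError)):
            cs.factorial_manova(biomarker_matrix, run_tukey=False)

    def test_tukey_tables_emitted_for_significant_factors(self, biomarker_matrix):
        moderate, _ = cs.two_tier_split(biomarker_matrix)
        res = cs.factorial_manova(moderate)
        # species is 7-level and strongly different under the default model
        assert any(term == "species" for (_, term) in res.tukey)
        for (_, _), tbl in res.tukey.items():
            assert {"group1", "group2", "reject"} <= set(tbl.columns)


class TestPCA:
    def test_perfect_correlation_loads_on_pc1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        df = pd.DataFrame({"hsp70": x, "ub": 2 * x + 3})
        res = cs.pca(df, responses=("hsp70", "ub"))
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_conservation(self, biomarker_matrix):
        res = cs.pca(biomarker_matrix)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert res.scores.shape == (len(biomarker_matrix), 3)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"hsp70": [1.0, 2.0, 3.0], "ub": 1.0, "tac": [3.0, 1.0, 2.0]})
        with pytest.raises(DegeneracyError):
            cs.pca(df)


class TestClusterHeatmap:
    def _groups_frame(self, centers, n=10, spread=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, c in centers.items():
            for _ in range(n):
                rows.append(
                    {"grp": g, "hsp70": c[0] + rng.normal(0, spread),
                     "ub": c[1] + rng.normal(0, spread),
                     "tac": c[2] + rng.normal(0, spread)}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_merge_at_zero(self):
        # two groups with byte-identical observations: group means coincide
        rng = np.random.default_rng(0)
        block = pd.DataFrame(rng.normal(size=(10, 3)),
                             columns=["hsp70", "ub", "tac"])
        df = pd.concat(
            [block.assign(grp="a"), block.assign(grp="b")], ignore_index=True
        )
        res = cs.cluster_heatmap(df, "grp")
        assert res.col_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_group_merges_last(self):
        df = self._groups_frame(
            {"a": (0, 0, 0), "b": (0.1, 0, 0), "far": (5, 5, 5)}
        )
        res = cs.cluster_heatmap(df, "grp")
        # brute-force oracle: the most distant group by pairwise Euclidean
        # distance on group means joins in the final merge
        means = res.group_means
        dists = {
            g: min(
                np.linalg.norm(means.loc[g] - means.loc[h])
                for h in means.index if h != g
            )
            for g in means.index
        }
        outlier = max(dists, key=dists.get)
        assert outlier == "far"
        # the final linkage row merges the outlier's singleton cluster
        assert res.col_linkage[-1, 2] == res.col_linkage[:, 2].max()
        assert res.col_order[0] == "far" or res.col_order[-1] == "far"

    def test_complete_linkage_heights_monotone(self, biomarker_matrix):
        res = cs.cluster_heatmap(biomarker_matrix, "species")
        heights = res.col_linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_single_group_warns_with_trivial_order(self):
        df = self._groups_frame({"only": (1, 2, 3)})
        with pytest.warns(UserWarning, match="single group"):
            res = cs.cluster_heatmap(df, "grp")
        assert res.col_order == ["only"]
        assert res.col_linkage.shape == (0, 4)
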