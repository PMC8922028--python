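"""Unit and property tests for the integrated biomarker response index."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coralstress as cs
from coralstress.exceptions import DegeneracyError, DesignError, GeometryError


def shoelace_star_area(scores):
    """Independent oracle: shoelace polygon area of the star vertices."""
    s = np.asarray(scores, dtype=float)
    n = s.size
    ang = 2 * np.pi * np.arange(n) / n
    x, y = s * np.cos(ang), s * np.sin(ang)
    return 0.5 * abs(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def _matrix_from_means(means: dict[tuple, dict[str, float]], reps=3, noise=0.0,
                       species="sp") -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(0)
    for i, ((temp, pred), vals) in enumerate(means.items()):
        for r in range(reps):
            row = {"fragment_id": f"{i}-{r}", "species": species,
                   "temperature": temp, "predation": pred}
            for b, v in vals.items():
                row[b] = v + (rng.normal(0, noise) if noise else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestConditionMeans:
    def test_equals_brute_force_mean(self):
        m = _matrix_from_means(
            {(26, "no_lesion"): {"hsp70": 1, "ub": 2, "tac": 3},
             (30, "no_lesion"): {"hsp70": 4, "ub": 5, "tac": 6}},
            noise=0.5,
        )
        means = cs.condition_means(m, "sp")
        for cond, row in means.iterrows():
            sub = m[(m["temperature"] == cond[0]) & (m["predation"] == cond[1])]
            for b in ("hsp70", "ub", "tac"):
                assert row[b] == pytest.approx(sum(sub[b]) / len(sub))

    def test_dead_condition_absent(self, biomarker_matrix):
        means = cs.condition_means(biomarker_matrix, "Acropora tenuis")
        assert (32, "no_lesion") not in means.index  # thermosensitive, all dead
        assert len(means) == 4  # 2 temps x 2 predation

    def test_single_condition_rejected(self):
        m = _matrix_from_means({(26, "no_lesion"): {"hsp70": 1, "ub": 1, "tac": 1}})
        with pytest.raises(DesignError, match="standardization"):
            cs.condition_means(m, "sp")


class TestStandardizeScores:
    x123 = pd.DataFrame(
        {"hsp70": [1.0, 2.0, 3.0], "ub": [2.0, 2.5, 3.0], "tac": [0.1, 0.3, 0.2]},
        index=pd.MultiIndex.from_product([[26, 30, 32], ["no_lesion"]]),
    )

    @pytest.mark.parametrize(
        "ddof,y_expected,s_expected",
        [
            # sample SD (default): sd(1,2,3) = 1
            (1, (-1.0, 0.0, 1.0), (0.0, 1.0, 2.0)),
            # population SD: sd = sqrt(2/3), Y = +/- 1.2247
            (0, (-1.224745, 0.0, 1.224745), (0.0, 1.224745, 2.449490)),
        ],
    )
    def test_stimulation_scores(self, ddof, y_expected, s_expected):
        ss = cs.standardize_scores(self.x123, ddof=ddof)
        np.testing.assert_allclose(ss.y["hsp70"], y_expected, atol=1e-6)
        np.testing.assert_allclose(ss.score["hsp70"], s_expected, atol=1e-6)

    def test_inhibition_reverses_scores(self):
        stim = cs.standardize_scores(self.x123)
        inhib = cs.standardize_scores(self.x123, {"hsp70": "inhibition"})
        np.testing.assert_allclose(
            inhib.score["hsp70"].to_numpy(), stim.score["hsp70"].to_numpy()[::-1]
        )

    def test_zero_spread_raises_naming_biomarker(self):
        flat = self.x123.assign(ub=2.0)
        with pytest.raises(DegeneracyError, match="ub"):
            cs.standardize_scores(flat)

    def test_zero_spread_policy_zero(self):
        flat = self.x123.assign(ub=2.0)
        ss = cs.standardize_scores(flat, on_degenerate="zero")
        assert (ss.y["ub"] == 0).all() and (ss.score["ub"] == 0).all()

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0.1, 50)),
            min_size=2, max_size=8, unique=True,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_score_contract(self, xs):
        x = pd.DataFrame(xs, columns=["hsp70", "ub", "tac"])
        if (x.std(ddof=1) == 0).any():
            return
        ss = cs.standardize_scores(x)
        for b in x.columns:
            # S = Z - min(Z) elementwise; min S exactly 0; mean Y exactly 0
            np.testing.assert_allclose(
                ss.score[b], ss.z[b] - ss.z[b].min(), atol=1e-12
            )
            assert ss.score[b].min() == 0.0
            assert abs(ss.y[b].sum()) < 1e-10
            assert (ss.score[b] >= 0).all()


class TestStarArea:
    def test_equilateral_triangle(self):
        res = cs.star_area([1.0, 1.0, 1.0])
        assert res.value == pytest.approx(3 * math.sqrt(3) / 4, abs=1e-9)
        assert res.value == pytest.approx(1.2990, abs=5e-5)

    def test_zero_scores(self):
        assert cs.star_area([0.0, 0.0, 0.0]).value == 0.0

    def test_asymmetric_example(self):
        # 1/2 sin(120 deg) * (2*1 + 1*3 + 3*2) = 4.7631
        res = cs.star_area([2.0, 1.0, 3.0])
        assert res.value == pytest.approx(0.5 * math.sin(2 * math.pi / 3) * 11, abs=1e-9)
        assert res.value == pytest.approx(4.7631, abs=5e-5)

    def test_open_variant_drops_closing_segment(self):
        closed = cs.star_area([2.0, 1.0, 3.0], closed=True)
        open_ = cs.star_area([2.0, 1.0, 3.0], closed=False)
        assert len(open_.areas) == 2
        assert open_.value == pytest.approx(closed.value - closed.areas[-1])

    def test_geometry_errors(self):
        with pytest.raises(GeometryError):
            cs.star_area([1.0, 2.0])
        with pytest.raises(GeometryError):
            cs.star_area([1.0, -0.1, 2.0])

    def test_beta_variant_is_not_the_polygon_area(self):
        # the historical beta-angle expression, kept for audit, does not
        # reproduce the equilateral polygon area (0.3415 per segment sum
        # 1.0245 vs 1.2990)
        res = cs.star_area([1.0, 1.0, 1.0], variant="beta")
        assert res.betas is not None
        assert res.betas[0] == pytest.approx(math.pi / 6)
        assert res.value == pytest.approx(3 * 0.34150635, abs=1e-6)
        assert res.value != pytest.approx(1.2990, abs=1e-3)

    @given(
        st.integers(3, 8).flatmap(
            lambda n: st.lists(st.floats(0, 10), min_size=n, max_size=n)
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_shoelace_oracle(self, scores):
        assert cs.star_area(scores).value == pytest.approx(
            shoelace_star_area(scores), abs=1e-10
        )

    @given(
        st.lists(st.floats(0, 10), min_size=3, max_size=6),
        st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_law(self, scores, c):
        base = cs.star_area(scores).value
        scaled = cs.star_area(np.asarray(scores) * c).value
        assert scaled == pytest.approx(c**2 * base, rel=1e-9, abs=1e-12)

    def test_rotation_and_permutation_invariance(self):
        s = [2.0, 1.0, 3.0]
        base = cs.star_area(s).value
        for k in range(3):
            assert cs.star_area(np.roll(s, k)).value == pytest.approx(base)
        # n = 3: EVERY permutation is a rotation or reflection
        for perm in itertools.permutations(s):
            assert cs.star_area(list(perm)).value == pytest.approx(base)


class TestIBRTable:
    def test_flat_responses_give_zero_index(self):
        m = _matrix_from_means(
            {(26, "no_lesion"): {"hsp70": 1, "ub": 2, "tac": 3},
             (30, "no_lesion"): {"hsp70": 1, "ub": 2, "tac": 3}}
        )
        with pytest.raises(DegeneracyError):
            cs.ibr_table(m)
        table = cs.ibr_table(m, on_degenerate="zero")
        assert (table["ibr"] == 0).all()

    def test_one_row_per_surviving_cell(self, biomarker_matrix):
        table = cs.ibr_table(biomarker_matrix)
        assert len(table) == 34  # 7 x 2 x 2 surviving + 3 x 2 at 32 degC
        missing = table[
            (table["temperature"] == 32)
            & table["species"].isin(
                ["Acropora tenuis", "Echinopora lamellosa",
                 "Montipora capricornis BM", "Montipora capricornis GM"]
            )
        ]
        assert missing.empty

    def test_biomarker_order_irrelevant_for_three(self, biomarker_matrix):
        base = cs.ibr_table(biomarker_matrix).set_index(
            ["species", "temperature", "predation"]
        )["ibr"]
        for order in itertools.permutations(("hsp70", "ub", "tac")):
            perm = cs.ibr_table(biomarker_matrix, biomarkers=order).set_index(
                ["species", "temperature", "predation"]
            )["ibr"]
            pd.testing.assert_series_equal(base, perm, rtol=1e-12)

    def test_replicate_pooling_changes_scale_not_floor(self, biomarker_matrix):
        table, scores = cs.ibr_table(
            biomarker_matrix, pooling="replicates", return_scores=True
        )
        for ss in scores.values():
            for b in ss.biomarkers:
                assert ss.score[b].min() == pytest.approx(0.0, abs=1e-12)


class TestIBRAnova:
    def test_balanced_2x2_matches_hand_computed_ss(self):
        # textbook 2x2 with 2 replicates/cell; SS computed by hand:
        # cells means 10,14 / 12,20 -> A main 4^2? worked out below
        data = pd.DataFrame(
            {
                "temperature": [26] * 4 + [30] * 4,
                "predation": (["no_lesion"] * 2 + ["lesion"] * 2) * 2,
                "ibr": [9.0, 11.0, 13.0, 15.0, 11.0, 13.0, 19.0, 21.0],
            }
        )
        # grand mean 14; cell means 10, 14, 12, 20
        # SS_A (temperature) = 2*2*((12-14)^2 + (16-14)^2) = 32... computed:
        ybar = data["ibr"].mean()
        a_means = data.groupby("temperature")["ibr"].mean()
        b_means = data.groupby("predation")["ibr"].mean()
        cell = data.groupby(["temperature", "predation"])["ibr"].mean()
        ss_a = 4 * ((a_means - ybar) ** 2).sum()
        ss_b = 4 * ((b_means - ybar) ** 2).sum()
        ss_cells = 2 * ((cell - ybar) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ((data["ibr"] - data.merge(
            cell.rename("m"), on=["temperature", "predation"])["m"]) ** 2).sum()
        f_a = (ss_a / 1) / (ss_err / 4)
        f_b = (ss_b / 1) / (ss_err / 4)
        f_ab = (ss_ab / 1) / (ss_err / 4)
        res = cs.ibr_anova(data)
        assert res["temperature"].statistic == pytest.approx(f_a, rel=1e-9)
        assert res["predation"].statistic == pytest.approx(f_b, rel=1e-9)
        assert res["temperature:predation"].statistic == pytest.approx(f_ab, rel=1e-9)

    def test_constant_response_gives_zero_f(self):
        data = pd.DataFrame(
            {"temperature": [26, 26, 30, 30] * 2,
             "predation": ["no_lesion", "lesion"] * 4,
             "ibr": 2.5}
        )
        res = cs.ibr_anova(data)
        assert all(r.statistic == 0.0 and r.pvalue == 1.0 for r in res.values())

    def test_empty_factor_level_rejected(self):
        data = pd.DataFrame(
            {"temperature": [26] * 4, "predation": ["no_lesion", "lesion"] * 2,
             "ibr": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(DesignError, match="temperature"):
            cs.ibr_anova(data)
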