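"""Statistics tests: split-plot ANOVA vs brute-force oracle, GG epsilon,
post hoc t-tests, and the walking-speed analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from gaitersp.stats import (analyze_speed, gg_epsilon, mixed_anova, posthoc_tests)
from tests.anova_oracle import (oracle_total_ss, random_balanced_table,
                                split_plot_oracle)

WITHIN_DESIGNS = [
    {"condition": 3},
    {"condition": 2},
    {"condition": 3, "window": 4},
    {"condition": 2, "window": 4},
    {"condition": 3, "window": 2, "roi": 3},
]


def _compare_with_oracle(seed, within_levels, n_per_group=6):
    rng = np.random.default_rng(seed)
    table, y = random_balanced_table(rng, n_per_group, within_levels)
    res = mixed_anova(table, dv="y", within=list(within_levels), between="group")
    oracle = split_plot_oracle(y, list(within_levels))
    for name, o in oracle.items():
        if name == "G":
            eff = "group"
        elif name.endswith(":G"):
            eff = name[:-2] + ":group"
        else:
            eff = name
        row = res.effect(eff)
        assert row["F"] == pytest.approx(o["F"], abs=1e-8), (name, seed)
        assert row["ss"] == pytest.approx(o["ss"], abs=1e-8)
        assert row["ss_error"] == pytest.approx(o["ss_error"], abs=1e-8)
        assert (row["df1"], row["df2"]) == (o["df1"], o["df2"])
        assert row["np2"] == pytest.approx(o["np2"], abs=1e-8)
    # SS conservation over unique error strata (balanced design)
    strata = res.table.drop_duplicates("stratum")
    total = res.table["ss"].sum() + strata["ss_error"].sum()
    assert total == pytest.approx(res.ss_total, abs=1e-8)


class TestMixedAnovaOracle:
    @pytest.mark.parametrize("within_levels", WITHIN_DESIGNS,
                             ids=lambda d: "x".join(map(str, d.values())))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_decomposition(self, seed, within_levels):
        _compare_with_oracle(seed, within_levels)

    def test_constant_dv_reports_zero_F_unit_p(self):
        rng = np.random.default_rng(0)
        table, _ = random_balanced_table(rng, 4, {"condition": 3})
        table["y"] = 2.5
        res = mixed_anova(table, dv="y", within=["condition"], between="group")
        assert (res.table["F"] == 0).all()
        assert (res.table["p_gg"] == 1).all()
        assert res.table["ss"].abs().max() < 1e-12

    def test_two_level_within_equals_squared_difference_score_t(self):
        """With one 2-level within factor the within F is t^2 of the pooled
        one-sample test of the difference scores against zero."""
        rng = np.random.default_rng(7)
        table, y = random_balanced_table(rng, 8, {"condition": 2})
        res = mixed_anova(table, dv="y", within=["condition"], between="group")
        d = (y[:, :, 1] - y[:, :, 0]).ravel()          # difference scores
        groups = np.repeat([0, 1], 8)
        ss_w = sum(((d[groups == g] - d[groups == g].mean()) ** 2).sum() for g in (0, 1))
        s2 = ss_w / (len(d) - 2)
        t = d.mean() / np.sqrt(s2 / len(d))
        assert res.effect("condition")["F"] == pytest.approx(t**2, abs=1e-8)

    def test_incomplete_design_lists_missing_cells(self):
        rng = np.random.default_rng(1)
        table, _ = random_balanced_table(rng, 4, {"condition": 3})
        table = table[~((table.subject_id == "A0") & (table.condition == "condition1"))]
        with pytest.raises(ValueError, match="missing cells"):
            mixed_anova(table, dv="y", within=["condition"], between="group")

    def test_duplicate_observation_rejected(self):
        rng = np.random.default_rng(1)
        table, _ = random_balanced_table(rng, 4, {"condition": 3})
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            mixed_anova(table, dv="y", within=["condition"], between="group")

    def test_single_subject_group_rejected(self):
        rng = np.random.default_rng(1)
        table, _ = random_balanced_table(rng, 4, {"condition": 3})
        table = table[~((table.group == "B") & (table.subject_id != "B0"))]
        with pytest.raises(ValueError, match="at least 2 subjects"):
            mixed_anova(table, dv="y", within=["condition"], between="group")

    def test_unequal_group_sizes_supported(self):
        rng = np.random.default_rng(3)
        table, _ = random_balanced_table(rng, 17, {"condition": 3})
        drop = [f"A{i}" for i in range(14, 17)]        # 14 vs 17 subjects
        table = table[~table.subject_id.isin(drop)]
        res = mixed_anova(table, dv="y", within=["condition"], between="group")
        assert res.effect("group")["df2"] == 29
        assert res.effect("condition")["df2"] == 58
        assert ((res.table["p_gg"] > 0) & (res.table["p_gg"] <= 1)).all()

    def test_agrees_with_pingouin_on_one_within_design(self):
        """Independent cross-check against a second implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        table, _ = random_balanced_table(rng, 8, {"condition": 3})
        res = mixed_anova(table, dv="y", within=["condition"], between="group")
        ref = pingouin.mixed_anova(data=table, dv="y", within="condition",
                                   subject="subject_id", between="group")
        ref = ref.set_index("Source")
        assert res.effect("group")["F"] == pytest.approx(ref.loc["group", "F"], abs=1e-8)
        assert res.effect("condition")["F"] == pytest.approx(
            ref.loc["condition", "F"], abs=1e-8)
        assert res.effect("condition:group")["F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)

    def test_gg_epsilon_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.standard_normal((12, 4)) @ rng.standard_normal((4, 4))
        ref = float(pingouin.epsilon(pd.DataFrame(data), correction="gg"))
        assert gg_epsilon(data) == pytest.approx(ref, abs=1e-10)


class TestGGEpsilon:
    def test_two_levels_always_one(self, rng):
        data = rng.standard_normal((10, 2)) @ np.array([[1.0, 0.3], [0.2, 2.0]])
        assert gg_epsilon(data) == 1.0

    def test_compound_symmetry_approaches_one(self, rng):
        # exchangeable covariance satisfies sphericity -> eps near 1
        n, k = 200, 4
        subject = rng.standard_normal((n, 1))
        data = subject + rng.standard_normal((n, k))
        assert gg_epsilon(data) > 0.95

    def test_rank_one_attains_lower_bound(self, rng):
        k = 5
        loadings = rng.standard_normal(k)
        data = np.outer(rng.standard_normal(40), loadings)
        assert gg_epsilon(data) == pytest.approx(1 / (k - 1), abs=1e-6)

    def test_bounds_on_random_covariances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            A = rng.standard_normal((k, k))
            data = rng.standard_normal((k + 10, k)) @ A
            eps = gg_epsilon(data)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_fewer_subjects_than_levels_rejected(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            gg_epsilon(rng.standard_normal((3, 4)))


class TestPosthoc:
    def _table(self, a, b):
        rows = [{"subject_id": f"s{i}", "cell": "a", "y": v} for i, v in enumerate(a)]
        rows += [{"subject_id": f"s{i}", "cell": "b", "y": v} for i, v in enumerate(b)]
        return pd.DataFrame(rows)

    def test_textbook_pooled_variance_value(self):
        table = self._table([1, 2, 3], [2, 3, 4])
        out = posthoc_tests(table, [{"label": "ab", "kind": "independent",
                                     "a": {"cell": "a"}, "b": {"cell": "b"}}], dv="y")
        # means 2 and 3, pooled variance 1, se = sqrt(2/3)
        assert out["t"].iloc[0] == pytest.approx(-1 / np.sqrt(2 / 3), abs=1e-10)
        assert out["df"].iloc[0] == 4
        expected_p = 2 * spstats.t.sf(abs(out["t"].iloc[0]), 4)
        assert out["p_raw"].iloc[0] == pytest.approx(expected_p, abs=1e-12)

    def test_identical_samples_give_null_result(self):
        table = self._table([1, 2, 3], [1, 2, 3])
        for kind in ("independent", "paired"):
            out = posthoc_tests(table, [{"label": "ab", "kind": kind,
                                         "a": {"cell": "a"}, "b": {"cell": "b"}}],
                                dv="y")
            assert out["t"].iloc[0] == 0.0
            assert out["p_adjusted"].iloc[0] == 1.0

    def test_single_contrast_family_is_identity(self, rng):
        table = self._table(rng.normal(size=6), rng.normal(size=6))
        out = posthoc_tests(table, [{"label": "ab", "kind": "independent",
                                     "a": {"cell": "a"}, "b": {"cell": "b"}}], dv="y")
        assert out["p_adjusted"].iloc[0] == out["p_raw"].iloc[0]

    def test_bonferroni_dominates_raw_p(self, rng):
        table = self._table(rng.normal(size=8), rng.normal(1.0, size=8))
        contrasts = [{"label": f"c{i}", "kind": k,
                      "a": {"cell": "a"}, "b": {"cell": "b"}}
                     for i, k in enumerate(["independent", "paired", "independent"])]
        out = posthoc_tests(table, contrasts, dv="y")
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_adjusted"] <= 1.0).all()
        assert (out["n_comparisons"] == 3).all()

    def test_unknown_cell_rejected(self):
        table = self._table([1, 2], [3, 4])
        with pytest.raises(ValueError, match="unknown cell"):
            posthoc_tests(table, [{"label": "x", "kind": "independent",
                                   "a": {"cell": "nope"}, "b": {"cell": "b"}}], dv="y")

    def test_paired_test_matches_scipy(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, size=10)
        table = self._table(a, b)
        out = posthoc_tests(table, [{"label": "ab", "kind": "paired",
                                     "a": {"cell": "a"}, "b": {"cell": "b"}}], dv="y")
        t_ref, p_ref = spstats.ttest_rel(a, b)
        assert out["t"].iloc[0] == pytest.approx(t_ref, abs=1e-10)
        assert out["p_raw"].iloc[0] == pytest.approx(p_ref, abs=1e-10)


class TestSpeedAnalysis:
    @staticmethod
    def _speed_table(rng, n_pd=6, n_nc=7, delta=0.0):
        rows = []
        for group, n, base in (("PD", n_pd, 0.81), ("NC", n_nc, 0.81 + delta)):
            for i in range(n):
                for cond in ("no_adjustment", "preset", "online"):
                    rows.append({"subject_id": f"{group}{i}", "group": group,
                                 "condition": cond,
                                 "speed": base + rng.normal(0, 0.12)})
        return pd.DataFrame(rows)

    def test_group_effect_detected_for_large_difference(self, rng):
        table = self._speed_table(rng, delta=0.4)
        anova, tests = analyze_speed(table)
        assert anova.p("group") < 0.001
        assert len(tests) == 3
        assert (tests["n_comparisons"] == 3).all()

    def test_posthoc_covers_all_conditions(self, rng):
        table = self._speed_table(rng, delta=0.3)
        _, tests = analyze_speed(table)
        for cond in ("no_adjustment", "preset", "online"):
            assert any(cond in label for label in tests["contrast"])

    def test_single_subject_group_errors(self, rng):
        table = self._speed_table(rng, n_pd=1)
        with pytest.raises(ValueError, match="at least 2 subjects"):
            analyze_speed(table)
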