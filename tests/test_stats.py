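"""Statistical layer: gating, mixed ANOVA, two-group tests, baseline table."""

import numpy as np
import pandas as pd
import pytest

from swaysim import (
    baseline_table,
    box_m_test,
    format_count,
    levene_test,
    mann_whitney,
    mixed_anova_2x2,
    normality_gate,
    two_group_test,
)
from swaysim.stats import cohens_d


def manual_mixed_anova(y: np.ndarray, g: np.ndarray):
    """Independent sums-of-squares oracle for the 2x2 split-plot design.

    ``y`` is (n_subjects, 2) within-level values; ``g`` the group label per
    subject.  Returns F values computed from first principles.
    """
    groups = sorted(set(g))
    k = 2
    n = len(y)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * sum((g == gr).sum() * (subj_means[g == gr].mean() - grand) ** 2
                       for gr in groups)
    ss_err_b = ss_subj - ss_group
    ss_vision = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_cells = sum((g == gr).sum() * (y[g == gr, j].mean() - grand) ** 2
                   for gr in groups for j in range(k))
    ss_inter = ss_cells - ss_group - ss_vision
    ss_total = ((y - grand) ** 2).sum()
    ss_err_w = ss_total - ss_subj - ss_vision - ss_inter
    dfe = n - 2
    return (ss_group / (ss_err_b / dfe),
            ss_vision / (ss_err_w / dfe),
            ss_inter / (ss_err_w / dfe))


def long_frame(y, g):
    rows = []
    for i, (vals, grp) in enumerate(zip(y, g)):
        for j, v in enumerate(vals):
            rows.append({"subject_id": f"s{i}", "group": grp,
                         "vision": ["EO", "EC"][j], "value": v})
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_normal_data_parametric_rate(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cells = {"a": rng.normal(size=200), "b": rng.normal(size=200)}
            if normality_gate(cells).route == "parametric":
                hits += 1
        assert hits >= 36  # >= 90% of seeds under a true normal

    def test_lognormal_routes_to_log_transform(self):
        rng = np.random.default_rng(1)
        cells = {"a": np.exp(rng.normal(0, 1.5, 300)),
                 "b": np.exp(rng.normal(0, 1.5, 300))}
        assert normality_gate(cells).route == "log_transform"

    def test_zero_blocks_log_transform(self):
        rng = np.random.default_rng(2)
        skewed = np.exp(rng.normal(0, 2, 200))
        skewed[0] = 0.0
        gate = normality_gate({"a": skewed, "b": rng.normal(size=200)})
        assert gate.route == "nonparametric"
        assert "non-positive" in gate.reason

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError):
            normality_gate({"a": np.array([1.0, 2.0])})


class TestMixedAnova:
    def test_balanced_fixture_matches_hand_solution(self):
        y = np.array([[1.0, 2.0], [2.0, 3.5], [1.5, 2.0], [0.5, 1.0],
                      [3.0, 4.0], [2.5, 4.5], [3.5, 4.0], [2.0, 3.0]])
        g = np.array(["c"] * 4 + ["p"] * 4)
        res = mixed_anova_2x2(long_frame(y, g))
        fg, fv, fi = manual_mixed_anova(y, g)
        assert res["group"].statistic == pytest.approx(fg, abs=1e-9)
        assert res["vision"].statistic == pytest.approx(fv, abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(fi, abs=1e-9)

    def test_property_random_instances_match_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n1, n2 = rng.integers(3, 8, size=2)
            y = rng.normal(size=(n1 + n2, 2))
            g = np.array(["c"] * n1 + ["p"] * n2)
            res = mixed_anova_2x2(long_frame(y, g))
            fg, fv, fi = manual_mixed_anova(y, g)
            for key, f in zip(("group", "vision", "interaction"), (fg, fv, fi)):
                assert res[key].statistic == pytest.approx(f, abs=1e-9), seed

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        y = rng.normal(size=(12, 2))
        g = np.array(["c"] * 6 + ["p"] * 6)
        df = long_frame(y, g)
        res = mixed_anova_2x2(df)
        ref = pg.mixed_anova(data=df, dv="value", within="vision",
                             subject="subject_id", between="group")
        ref = ref.set_index("Source")
        assert res["group"].statistic == pytest.approx(
            ref.loc["group", "F"], rel=1e-6)
        assert res["vision"].statistic == pytest.approx(
            ref.loc["vision", "F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)
        assert res["group"].effect_size == pytest.approx(
            ref.loc["group", "np2"], rel=1e-6)

    def test_identical_values_degenerate(self):
        y = np.full((8, 2), 3.0)
        g = np.array(["c"] * 4 + ["p"] * 4)
        res = mixed_anova_2x2(long_frame(y, g))
        assert "degenerate" in res["group"].notes
        assert res["group"].statistic == 0.0

    def test_constant_vision_shift(self):
        """A pure constant within-shift c: vision effect only, interaction 0."""
        rng = np.random.default_rng(4)
        base = rng.normal(size=12)
        y = np.column_stack([base, base + 0.8])
        g = np.array(["c"] * 6 + ["p"] * 6)
        res = mixed_anova_2x2(long_frame(y, g))
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)
        assert res["vision"].p_value == pytest.approx(0.0)  # zero within-error

    def test_partial_eta_sq_range(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(10, 2))
        g = np.array(["c"] * 5 + ["p"] * 5)
        for res in mixed_anova_2x2(long_frame(y, g)).values():
            assert 0.0 <= res.effect_size <= 1.0


class TestMannWhitney:
    def test_enumeration_example(self):
        """x={1,3}, y={2,4}: 3 of 4 (x,y) pairs have x < y."""
        res = mann_whitney(np.array([1.0, 3.0]), np.array([2.0, 4.0]))
        assert res.statistic == 3.0

    def test_identical_groups_null(self):
        x = np.arange(6, dtype=float)
        res = mann_whitney(x, x.copy())
        assert res.statistic == 6 * 6 / 2
        assert res.group_summaries["z"] == 0.0

    def test_u_complement(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=9)
        u1 = mann_whitney(x, y).statistic
        u2 = mann_whitney(y, x).statistic
        assert u1 + u2 == pytest.approx(8 * 9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(0.5, 1.0, size=12)
        a = mann_whitney(x, y)
        b = mann_whitney(np.exp(x), np.exp(y))
        assert a.statistic == b.statistic
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_exact_p_matches_scipy(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=5), rng.normal(size=6)  # tie-free
        res = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestTwoGroupTest:
    def test_power_of_unit_effect(self):
        """d=1 at n=20/20: two-sample t power ~ 0.87 over 1000 draws."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(1000):
            x = rng.normal(0.0, 1.0, 20)
            y = rng.normal(1.0, 1.0, 20)
            if two_group_test(x, y, route="parametric").p_value < 0.05:
                hits += 1
        assert 830 <= hits <= 910

    def test_welch_applied_on_unequal_variances(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 0.5, 40)
        y = rng.normal(0, 4.0, 40)
        res = two_group_test(x, y, route="parametric")
        assert res.test_name == "Welch t"
        assert res.df != pytest.approx(78.0)  # fractional Welch df

    def test_cohens_d_sign_and_affine_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.normal(1.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        d = cohens_d(x, y)
        assert d > 0
        assert cohens_d(y, x) == pytest.approx(-d)
        assert abs(cohens_d(3 * x + 7, 3 * y + 7)) == pytest.approx(abs(d))

    def test_constant_data_degenerate(self):
        res = two_group_test(np.full(5, 2.0), np.full(5, 2.0))
        assert res.test_name == "degenerate"

    def test_log_route(self):
        rng = np.random.default_rng(14)
        x = np.exp(rng.normal(0.0, 1.0, 50))
        y = np.exp(rng.normal(0.8, 1.0, 50))
        res = two_group_test(x, y, route="log_transform")
        assert res.transform_applied
        assert res.p_value < 0.05


class TestDiagnostics:
    def test_levene_on_equal_variances(self):
        rng = np.random.default_rng(15)
        res = levene_test(rng.normal(size=50), rng.normal(size=50))
        assert res.p_value > 0.01

    def test_box_m_on_equal_covariances(self):
        rng = np.random.default_rng(16)
        res = box_m_test(rng.normal(size=(30, 2)), rng.normal(size=(30, 2)))
        assert 0 <= res.p_value <= 1


class TestBaselineTable:
    @pytest.mark.parametrize("k,n,expected", [
        (6, 14, "6 (43%)"),
        (11, 20, "11 (55%)"),
        (9, 20, "9 (45%)"),
        (0, 7, "0 (0%)"),
    ])
    def test_count_formatting(self, k, n, expected):
        assert format_count(k, n) == expected

    def _subjects(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(14):
            rows.append({"id": f"p{i}", "group": "PD", "sex": "F" if i < 6 else "M",
                         "age": rng.normal(69, 5), "height": rng.normal(1.73, 0.06),
                         "mass": rng.normal(72, 8)})
        for i in range(20):
            rows.append({"id": f"c{i}", "group": "control",
                         "sex": "F" if i < 11 else "M",
                         "age": rng.normal(68, 5), "height": rng.normal(1.69, 0.06),
                         "mass": rng.normal(70, 8)})
        return pd.DataFrame(rows)

    def test_full_table(self):
        table = baseline_table(self._subjects())
        assert list(table["characteristic"]) == [
            "Sample size", "Age (years)", "Height (cm)", "Weight (kg)",
            "Number of women (%)"]
        women = table[table["characteristic"] == "Number of women (%)"]
        assert women["PD"].iloc[0] == "6 (43%)"
        assert women["control"].iloc[0] == "11 (55%)"
        for p in table["p_value"].iloc[1:]:
            assert p == "" or 0.0 <= float(p) <= 1.0

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError, match="fields"):
            baseline_table(pd.DataFrame({"group": ["a", "b"]}))
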