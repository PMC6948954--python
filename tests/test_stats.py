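"""Statistical battery: oracle formulas, identities and calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from renolymph.stats import (
    MetricTable,
    check_assumptions,
    compare_groups,
    fold_change,
    load_metric_table,
    one_way_anova,
    posthoc,
    significance_tier,
    two_sample_t,
    welch_anova,
)


def table_from_groups(groups, metric="m"):
    records = []
    kidney = 0
    for name, values in groups.items():
        for v in values:
            records.append((f"k{kidney}", name, metric, float(v)))
            kidney += 1
    return MetricTable.from_records(records)


def brute_force_f(groups):
    """Independent oracle: F from the raw sum-of-squares definitions."""
    values = [np.asarray(v, float) for v in groups]
    grand = np.mean(np.concatenate(values))
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in values)
    ssw = sum(np.sum((v - np.mean(v)) ** 2) for v in values)
    k, n = len(values), sum(len(v) for v in values)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestOneWayAnova:
    def test_hand_case_f_equals_8(self):
        t = table_from_groups({"a": [1, 2], "b": [3, 4]})
        r = one_way_anova(t, "m")
        assert r.statistic == pytest.approx(8.0, abs=1e-12)
        assert r.df == (1.0, 2.0)

    def test_zero_between_group_ss(self):
        t = table_from_groups({"a": [1, 3], "b": [2, 2], "c": [1, 3]})
        r = one_way_anova(t, "m")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_symmetry(self):
        groups = {"a": [1.0, 2.0, 5.0], "b": [2.5, 3.5], "c": [0.5, 4.0, 4.5]}
        base = one_way_anova(table_from_groups(groups), "m").statistic
        for perm in itertools.permutations(groups):
            t = table_from_groups({p: groups[p] for p in perm})
            assert one_way_anova(t, "m").statistic == pytest.approx(base, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 6))
            groups = {
                f"g{i}": rng.normal(rng.normal(0, 2), 1 + rng.random(),
                                    size=int(rng.integers(3, 9)))
                for i in range(k)
            }
            r = one_way_anova(table_from_groups(groups), "m")
            assert r.statistic == pytest.approx(
                brute_force_f(groups.values()), abs=1e-10
            )
            f_ref, p_ref = sps.f_oneway(*groups.values())
            assert r.statistic == pytest.approx(f_ref, abs=1e-10)
            assert r.p_value == pytest.approx(p_ref, abs=1e-12)


class TestWelchAnova:
    def test_equal_means_zero(self):
        t = table_from_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        r = welch_anova(t, "m")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_group_equals_welch_t_squared(self, rng):
        for _ in range(10):
            groups = {
                "a": rng.normal(0, 1, size=6),
                "b": rng.normal(1, 3, size=9),
            }
            t = table_from_groups(groups)
            w = welch_anova(t, "m")
            tt = two_sample_t(t, "m", welch=True)
            assert w.statistic == pytest.approx(tt.statistic ** 2, rel=1e-9)
            assert w.p_value == pytest.approx(tt.p_value, rel=1e-6)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(5):
            groups = {
                f"g{i}": rng.normal(i * 0.5, 1 + i, size=int(rng.integers(4, 9)))
                for i in range(3)
            }
            t = table_from_groups(groups)
            mine = welch_anova(t, "m")
            df = pd.DataFrame(
                [(g, v) for g, vs in groups.items() for v in vs],
                columns=["g", "v"],
            )
            ref = pingouin.welch_anova(data=df, dv="v", between="g")
            assert mine.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
            assert mine.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_zero_variance_group_rejected(self):
        t = table_from_groups({"a": [2.0, 2.0], "b": [1.0, 3.0]})
        with pytest.raises(ValueError):
            welch_anova(t, "m")


class TestTwoSampleT:
    def test_hand_case(self):
        t = table_from_groups({"a": [1, 2, 3], "b": [2, 3, 4]})
        r = two_sample_t(t, "m", welch=False)
        assert r.statistic == pytest.approx(-1.224744871, abs=1e-9)
        assert r.df[1] == 4.0

    def test_identical_groups_null(self):
        t = table_from_groups({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        r = two_sample_t(t, "m")
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_welch_equals_pooled_for_balanced_equal_variance(self, rng):
        a = rng.normal(0, 1, size=8)
        b = a + 0.5  # same spread exactly, balanced n
        t = table_from_groups({"a": a, "b": b})
        pooled = two_sample_t(t, "m", welch=False)
        welch = two_sample_t(t, "m", welch=True)
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-6)

    def test_matches_scipy(self, rng):
        for welch in (False, True):
            a, b = rng.normal(0, 1, 7), rng.normal(0.8, 2, 5)
            t = table_from_groups({"a": a, "b": b})
            mine = two_sample_t(t, "m", welch=welch)
            ref = sps.ttest_ind(a, b, equal_var=not welch)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestPosthoc:
    def test_single_pair_identity(self):
        t = table_from_groups({"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 6.0]})
        out = posthoc(t, "m", "bonferroni")
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_bonferroni_arithmetic(self):
        # construct m = 10 pairwise family (5 groups); check p_adj = min(1, 10 p)
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i * 0.4, 1, 5) for i in range(5)}
        out = posthoc(table_from_groups(groups), "m", "bonferroni")
        assert (out["m"] == 10).all()
        for row in out.itertuples():
            assert row.p_adj == pytest.approx(min(1.0, row.p_raw * 10), abs=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        for method in ("bonferroni", "tamhane_t2"):
            groups = {f"g{i}": rng.normal(rng.normal(), 1 + i, 6) for i in range(4)}
            out = posthoc(table_from_groups(groups), "m", method)
            assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
            ordered = out.sort_values("p_raw")
            assert ordered["p_adj"].is_monotonic_increasing

    def test_tamhane_null_calibration(self):
        """All groups identical in distribution: the familywise error of
        the Tamhane-adjusted comparisons stays near its nominal level."""
        rng = np.random.default_rng(17)
        hits = 0
        reps = 400
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0, 1 + i, 6) for i in range(3)}
            out = posthoc(table_from_groups(groups), "m", "tamhane_t2")
            hits += (out["p_adj"] < 0.05).any()
        assert hits / reps <= 0.07  # conservative procedure, nominal 5%


class TestAssumptions:
    def test_normal_scores_high_w(self):
        q = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        t = table_from_groups({"a": q, "b": q + 1})
        report = check_assumptions(t, "m")
        for w, p in report.shapiro.values():
            assert w > 0.99

    def test_variance_ratio_detected(self, rng):
        detected = 0
        for _ in range(50):
            t = table_from_groups({
                "a": rng.normal(0, 1, 20),
                "b": rng.normal(0, 10, 20),
            })
            report = check_assumptions(t, "m")
            detected += report.brown_forsythe[1] < 0.05
        assert detected >= 45  # ~always at a 100-fold variance ratio

    def test_small_group_skips_shapiro(self):
        t = table_from_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})
        report = check_assumptions(t, "m")
        assert report.shapiro["a"] == (None, None)
        assert any("n=2" in w for w in report.warnings)


class TestFoldChange:
    def test_identity(self):
        t = table_from_groups({"a": [2.0, 4.0], "b": [2.0, 4.0]})
        assert fold_change(t, "m", "a", "b") == pytest.approx(1.0)

    def test_eighteen_fold(self):
        t = table_from_groups({"base": [3.0, 3.0], "late": [54.0, 54.0]})
        assert fold_change(t, "m", "base", "late") == pytest.approx(18.0)

    def test_antisymmetry(self, rng):
        t = table_from_groups({"a": rng.uniform(1, 5, 4), "b": rng.uniform(1, 5, 4)})
        assert fold_change(t, "m", "a", "b") * fold_change(t, "m", "b", "a") == (
            pytest.approx(1.0)
        )

    def test_zero_baseline_rejected(self):
        t = table_from_groups({"a": [0.0, 0.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fold_change(t, "m", "a", "b")


class TestTiersAndDispatch:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.00005, "****"), (0.00015, "***"), (0.001, "**"), (0.02, "*"), (0.04, "ns")],
    )
    def test_tier_mapping(self, p, stars):
        assert significance_tier(p) == stars

    def test_welch_path_selected_under_heteroscedasticity(self):
        local = np.random.default_rng(5)  # independent of test order
        groups = {
            "a": local.normal(0, 0.05, 10),
            "b": local.normal(1, 5.0, 10),
            "c": local.normal(2, 5.0, 10),
        }
        result = compare_groups(table_from_groups(groups), "m")
        assert result.statistic_name == "W"
        assert result.posthoc is not None

    def test_classical_path_for_clean_data(self):
        local = np.random.default_rng(6)
        groups = {f"g{i}": local.normal(i, 1.0, 10) for i in range(3)}
        result = compare_groups(table_from_groups(groups), "m")
        assert result.statistic_name == "F"


class TestTypeIError:
    def test_anova_calibration(self):
        """Normal equal-variance null: rejection rate 0.05 ± 0.01."""
        rng = np.random.default_rng(19)
        reps = 4000
        hits = 0
        for _ in range(reps):
            t = table_from_groups({f"g{i}": rng.normal(0, 1, 5) for i in range(3)})
            hits += one_way_anova(t, "m").p_value < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.01)

    def test_welch_anova_calibration_heteroscedastic(self):
        """Welch's test stays calibrated at a 25-fold variance ratio."""
        rng = np.random.default_rng(23)
        reps = 4000
        hits = 0
        for _ in range(reps):
            t = table_from_groups({
                "a": rng.normal(0, 1, 5),
                "b": rng.normal(0, 5, 5),
                "c": rng.normal(0, 1, 5),
            })
            hits += welch_anova(t, "m").p_value < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.015)


class TestTableIO:
    def test_csv_and_column_map(self, tmp_path, rng):
        import pandas as pd

        df = pd.DataFrame({
            "sample": ["k1", "k2", "k3", "k4"],
            "stage": ["E14.5", "E14.5", "E18.5", "E18.5"],
            "parameter": ["n_branches"] * 4,
            "measurement": [4.0, 6.0, 25.0, 30.0],
        })
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = load_metric_table(path, column_map={
            "sample": "kidney_id", "stage": "group",
            "parameter": "metric", "measurement": "value",
        })
        groups = table.groups("n_branches")
        assert set(groups) == {"E14.5", "E18.5"}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            MetricTable.from_records([("k1", "a", "m", float("nan"))])
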