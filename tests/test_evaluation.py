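import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tumorsim as ts
from tumorsim.evaluation import ConfusionTable, StatsConfig


class TestClopperPearson:
    def test_printed_overall_sensitivity_interval(self):
        lo, hi = ts.clopper_pearson(44, 50)
        assert round(100 * lo, 1) == 75.7
        assert round(100 * hi, 1) == 95.5

    def test_printed_overall_specificity_interval(self):
        lo, hi = ts.clopper_pearson(84, 94)
        assert round(100 * lo, 1) == 81.3
        assert round(100 * hi, 1) == 94.8

    def test_zero_successes_closed_form(self):
        lo, hi = ts.clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_successes_upper_is_one(self):
        lo, hi = ts.clopper_pearson(10, 10)
        assert hi == 1.0 and lo == pytest.approx(0.025 ** (1 / 10))

    @pytest.mark.parametrize("x,n", [(0, 5), (3, 7), (10, 10), (25, 60)])
    def test_interval_contains_point_estimate(self, x, n):
        lo, hi = ts.clopper_pearson(x, n)
        assert lo <= x / n <= hi

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = []
        for n in (10, 40, 160):
            lo, hi = ts.clopper_pearson(n // 2, n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_exhaustive_coverage_at_least_nominal(self):
        """Exact coverage >= 95% for all p on a grid, all n <= 30, by
        brute-force binomial enumeration."""
        level = 0.95
        for n in range(1, 31):
            bounds = [ts.clopper_pearson(x, n, level) for x in range(n + 1)]
            for p in np.linspace(0.01, 0.99, 33):
                pmf = stats.binom.pmf(np.arange(n + 1), n, p)
                covered = sum(pmf[x] for x in range(n + 1)
                              if bounds[x][0] <= p <= bounds[x][1])
                assert covered >= level - 1e-9

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ts.clopper_pearson(5, 3)


class TestConfusionMetrics:
    def test_printed_overall_row(self):
        m = ts.confusion_metrics(ConfusionTable(TP=44, FP=10, FN=6, TN=84))
        assert round(100 * m["sensitivity"]["estimate"], 1) == 88.0
        assert round(100 * m["specificity"]["estimate"], 1) == 89.4
        assert round(100 * m["accuracy"]["estimate"], 1) == 88.9
        assert round(100 * m["accuracy"]["ci"][0], 1) == 82.6
        assert round(100 * m["accuracy"]["ci"][1], 1) == 93.5

    def test_her2_positive_subgroup_counts(self):
        # forced by subgroup constraints: 23 true pCR, 23 predicted, 21 hits
        m = ts.confusion_metrics(ConfusionTable(TP=21, FN=2, TN=24, FP=2))
        assert round(100 * m["sensitivity"]["estimate"], 1) == 91.3
        assert round(100 * m["specificity"]["estimate"], 1) == 92.3
        assert round(100 * m["accuracy"]["estimate"], 1) == 91.8
        assert round(100 * m["sensitivity"]["ci"][0], 1) == 72.0

    def test_all_correct_is_100_with_unit_upper(self):
        m = ts.confusion_metrics(ConfusionTable(TP=5, FP=0, FN=0, TN=5))
        for key in ("sensitivity", "specificity", "accuracy"):
            assert m[key]["estimate"] == 1.0
            assert m[key]["ci"][1] == 1.0

    def test_zero_denominator_flagged(self):
        m = ts.confusion_metrics(ConfusionTable(TP=0, FP=0, FN=0, TN=10))
        assert "sensitivity" not in m
        assert any("sensitivity" in f for f in m["flags"])

    def test_from_predictions(self):
        t = ConfusionTable.from_predictions([1, 1, 0, 0], [1, 0, 1, 0])
        assert (t.TP, t.FP, t.FN, t.TN) == (1, 1, 1, 1)


class TestAuroc:
    def test_perfect_separation(self):
        assert ts.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_exhaustive_pair_count_example(self):
        assert ts.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert ts.auroc([0.5] * 8, [0, 1] * 4) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ts.auroc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_pairs_oracle(self):
        """Mann–Whitney identity: AUROC equals the over-all-pairs statistic
        (ties 1/2) for random instances with n <= 50."""
        rng = np.random.default_rng(12)
        for trial in range(30):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(labels * 0.5, 1.0), 1)  # induce ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            cmpmat = (pos[:, None] > neg[None, :]).sum() \
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert ts.auroc(scores, labels) == pytest.approx(
                cmpmat / (len(pos) * len(neg)))

    def test_bootstrap_ci_reproducible_and_contains_estimate(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 120)
        scores = labels + rng.normal(0, 0.8, 120)
        cfg = StatsConfig(bootstrap_replicates=1000, bootstrap_seed=42)
        ci1 = ts.bootstrap_auroc_ci(scores, labels, cfg)
        ci2 = ts.bootstrap_auroc_ci(scores, labels, cfg)
        assert ci1 == ci2  # bit-exact under a fixed seed
        a = ts.auroc(scores, labels)
        assert ci1[0] <= a <= ci1[1]


class TestCvLogisticComparator:
    @staticmethod
    def _features(n, rng, informative=True):
        signal = rng.normal(0, 1, n)
        labels = (signal + (0 if informative else rng.normal(0, 1e6, n)) >
                  0).astype(int)
        df = pd.DataFrame({
            "age": rng.normal(50, 10, n),
            "feature": signal,
            "subtype": rng.choice(["TNBC", "HR+/HER2-"], n),
        })
        return df, labels

    def test_separable_features_high_auroc(self):
        rng = np.random.default_rng(5)
        df, labels = self._features(90, rng)
        out = ts.cv_logistic_comparator(df, labels, StatsConfig(cv_seed=1))
        assert out["auroc"] >= 0.95

    def test_every_case_scored_once(self):
        rng = np.random.default_rng(6)
        df, labels = self._features(60, rng)
        out = ts.cv_logistic_comparator(df, labels, StatsConfig(cv_seed=2))
        assert np.all(np.isfinite(out["scores"]))
        assert len(out["scores"]) == 60

    def test_null_features_auroc_near_half(self):
        """Label-independent features: mean out-of-fold AUROC ~ 0.5."""
        rng = np.random.default_rng(7)
        aucs = []
        for seed in range(20):
            n = 300
            labels = rng.integers(0, 2, n)
            df = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
            out = ts.cv_logistic_comparator(df, labels, StatsConfig(cv_seed=seed))
            aucs.append(out["auroc"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        df, labels = self._features(50, rng)
        s1 = ts.cv_logistic_comparator(df, labels, StatsConfig(cv_seed=3))["scores"]
        s2 = ts.cv_logistic_comparator(df, labels, StatsConfig(cv_seed=3))["scores"]
        assert np.array_equal(s1, s2)


class TestSurvivalCompare:
    def test_identical_groups_null_result(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 0, 1, 0] * 2)
        g = np.array([0] * 4 + [1] * 4)
        out = ts.survival_compare(t, e, g)
        assert out["logrank_statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_value"] == pytest.approx(1.0)

    def test_hazard_ratio_recovery(self):
        """Exponential arms with hazard 2λ vs λ: HR estimate within 15% of 2."""
        rng = np.random.default_rng(3)
        n = 500
        t0 = rng.exponential(1.0 / 0.4, n)   # hazard 2λ, group 1
        t1 = rng.exponential(1.0 / 0.2, n)   # hazard λ,  group 0
        times = np.concatenate([t1, t0])
        groups = np.array([0] * n + [1] * n)
        events = np.ones(2 * n, dtype=int)
        out = ts.survival_compare(times, events, groups)
        assert out["hazard_ratio"] == pytest.approx(2.0, rel=0.15)
        assert out["p_value"] < 1e-6

    def test_group_without_events_flags_hr(self):
        times = np.array([5.0] * 10 + [1.0, 2.0, 3.0, 5.0, 5.0])
        events = np.array([0] * 10 + [1, 1, 1, 0, 0])
        groups = np.array([1] * 10 + [0] * 5)
        out = ts.survival_compare(times, events, groups,
                                  StatsConfig(survival_horizon_years=4.0))
        assert out["hazard_ratio"] is None
        assert "lack of events" in out["flag"]
        assert out["survival_at_horizon"][1] == pytest.approx(1.0)

    def test_no_events_anywhere_undefined(self):
        out = ts.survival_compare([1.0, 2.0], [0, 0], [0, 1])
        assert "undefined" in out["flag"]


class TestPearsonFisher:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = ts.pearson_fisher(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_closed_form_z_and_p(self):
        """Construct data with r = 0.5 at n = 28 and verify the Fisher z p-value."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(0, 1, 28)
            y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(0, 1, 28)
            r, p = ts.pearson_fisher(x, y)
            z = np.arctanh(r) * np.sqrt(25)
            assert p == pytest.approx(2 * (1 - stats.norm.cdf(abs(z))), rel=1e-9)

    def test_type_one_error_calibration(self):
        """Independent normals: rejection rate at α=0.05 within 0.05 ± 0.02."""
        rng = np.random.default_rng(1)
        rejections = 0
        trials = 200
        for _ in range(trials):
            x = rng.normal(0, 1, 1000)
            y = rng.normal(0, 1, 1000)
            _, p = ts.pearson_fisher(x, y)
            rejections += p < 0.05
        assert abs(rejections / trials - 0.05) <= 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ts.pearson_fisher([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def _designed_cohort(tp=44, fp=10, fn=6, tn=84, seed=0):
    """Cohort whose prediction/truth pairs realize exact designed counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for pred, obs, count in ((True, True, tp), (True, False, fp),
                             (False, True, fn), (False, False, tn)):
        for _ in range(count):
            rows.append({"predicted_pcr": pred, "observed_pcr": obs,
                         "subtype": rng.choice(["TNBC", "HR+/HER2-"]),
                         "regimen_class": "chemo_anthra"})
    return pd.DataFrame(rows)


class TestTable2Report:
    def test_overall_row_reproduces_designed_rates(self):
        report = ts.table2_report(_designed_cohort())
        overall = report[report.group == "Overall"].iloc[0]
        assert overall["n"] == 144 and overall["n_predicted_pcr"] == 54
        assert overall["accuracy_display"].startswith("88.9")
        assert overall["sensitivity_display"].startswith("88.0")
        assert overall["specificity_display"].startswith("89.4")

    def test_single_subgroup_equals_overall(self):
        df = _designed_cohort()
        df["subtype"] = "TNBC"
        report = ts.table2_report(df, subgroup_cols=("subtype",))
        overall = report.iloc[0]
        sub = report[report.group == "subtype=TNBC"].iloc[0]
        for col in ("n", "accuracy", "sensitivity", "specificity"):
            assert overall[col] == sub[col]

    def test_subgroup_totals_sum_to_overall(self):
        report = ts.table2_report(_designed_cohort(), subgroup_cols=("subtype",))
        subs = report[report.group != "Overall"]
        assert subs["n"].sum() == 144
        assert subs["n_predicted_pcr"].sum() == 54

    def test_unknown_subgroup_column_rejected(self):
        with pytest.raises(ValueError, match="unknown subgroup"):
            ts.table2_report(_designed_cohort(), subgroup_cols=("nope",))

    def test_small_subgroup_flagged(self):
        df = _designed_cohort()
        df.loc[df.index[: len(df) - 2], "subtype"] = "TNBC"
        df.loc[df.index[-2:], "subtype"] = "HR+/HER2-"
        report = ts.table2_report(df, subgroup_cols=("subtype",))
        small = report[report.group == "subtype=HR+/HER2-"].iloc[0]
        assert "small-n" in small["flag"]
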