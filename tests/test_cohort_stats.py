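import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from petgeom import (
    InvalidArgumentError,
    InvalidInputError,
    auc_concordance,
    build_report,
    cox_fit,
    dichotomize,
    km_logrank,
    logistic_fit,
    roc_youden,
    simulate_cohort,
    spearman_matrix,
)
from petgeom.cohort_stats import REGRESSION_REPORT_COLUMNS, ROC_REPORT_COLUMNS


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_self_correlation_is_one(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=20)})
        table["b"] = table["a"]
        res = spearman_matrix(table, ["a", "b"])
        assert res.r.loc["a", "a"] == 1.0
        assert res.r.loc["a", "b"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=15)})
        table["b"] = -table["a"]
        res = spearman_matrix(table, ["a", "b"])
        assert res.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        table = pd.DataFrame(
            {"x": rng.normal(size=10), "y": rng.normal(size=10), "z": rng.integers(0, 3, 10)}
        )
        res = spearman_matrix(table, ["x", "y", "z"])
        for a in ("x", "y", "z"):
            for b in ("x", "y", "z"):
                ra = stats.rankdata(table[a])
                rb = stats.rankdata(table[b])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert res.r.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        table = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        res = spearman_matrix(table, ["a", "b", "c"])
        assert np.allclose(res.r.values, res.r.values.T)

    def test_constant_column_reported_missing(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=10), "c": np.ones(10)})
        res = spearman_matrix(table, ["a", "c"])
        assert np.isnan(res.r.loc["a", "c"])
        assert any("constant" in w for w in res.warnings)

    def test_too_few_rows(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(InvalidInputError):
            spearman_matrix(table, ["a", "b"])


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


def auc_pairwise(scores, labels):
    """Exhaustive pair-enumeration oracle (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels, higher):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best_j, best_c, best = -np.inf, None, None
    for c in sorted(set(scores)):
        called = scores >= c if higher else scores <= c
        sens = float((called & (labels == 1)).sum() / (labels == 1).sum())
        spec = float((~called & (labels == 0)).sum() / (labels == 0).sum())
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_c, best = j, c, (sens, spec)
    return best_c, best


class TestROCYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=50, seed=0)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_enumerated_example(self):
        res = roc_youden([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=10, seed=0)
        assert res.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_all_tied_scores(self):
        res = roc_youden([5.0] * 6, [0, 1, 0, 1, 0, 1], n_boot=10, seed=0)
        assert res.auc == 0.5

    def test_orientation_flip_recorded(self, rng):
        scores = rng.normal(size=200)
        labels = (scores < -0.2).astype(int)  # low scores predict the event
        res = roc_youden(scores, labels, n_boot=20, seed=0)
        assert res.orientation == "lower_predicts_event"
        assert res.auc > 0.9

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_pairwise_oracle(self, seed):
        gen = np.random.default_rng(seed)
        scores = np.round(gen.normal(size=60), 1)  # coarse values force ties
        labels = gen.integers(0, 2, size=60)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert auc_concordance(scores, labels) == pytest.approx(
            auc_pairwise(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_youden_matches_exhaustive_search(self, seed):
        gen = np.random.default_rng(seed)
        scores = np.round(gen.normal(size=80), 1)
        labels = (gen.random(80) < 0.3 + 0.4 * (scores > 0)).astype(int)
        res = roc_youden(scores, labels, n_boot=10, seed=0)
        higher = res.orientation == "higher_predicts_event"
        cutoff, (sens, spec) = youden_exhaustive(scores, labels, higher)
        assert res.cutoff == cutoff
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)

    def test_complement_symmetry(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:5] = 1
        labels[-5:] = 0
        assert auc_concordance(scores, labels) + auc_concordance(-scores, labels) == 1.0

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        a = auc_concordance(scores, labels)
        b = auc_concordance(np.exp(scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_brackets_estimate_and_is_deterministic(self, rng):
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.3 + 0.3 * (scores > 0)).astype(int)
        labels[0], labels[1] = 0, 1
        a = roc_youden(scores, labels, n_boot=200, seed=7)
        b = roc_youden(scores, labels, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.auc <= a.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_youden([1.0, 2.0, 3.0], [1, 1, 1], n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


class TestLogisticFit:
    def test_two_by_two_cross_product_ratio(self):
        # exposure=1: 20 events / 80 non-events; exposure=0: 10 / 90.
        exposure = np.repeat([1, 0], 100)
        outcome = np.concatenate([np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)])
        table = pd.DataFrame({"exposure": exposure, "outcome": outcome})
        res = logistic_fit(table, "outcome", ["exposure"], mode="univariate")
        row = res.row("exposure")
        assert row["ratio"] == pytest.approx(2.25, rel=1e-6)
        assert row["ci_low"] < 2.25 < row["ci_high"]

    def test_null_predictor_ci_covers_one(self):
        table = simulate_cohort(2000, beta_nhop=0.0, beta_suv=0.0, seed=3)
        res = logistic_fit(table, "recurrence", ["nhoc_max"], mode="univariate")
        row = res.row("nhoc_max")
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_parameter_recovery(self):
        gen = np.random.default_rng(0)
        x = gen.normal(size=2000)
        p = 1.0 / (1.0 + np.exp(-(-0.3 - 1.0 * x)))
        y = (gen.random(2000) < p).astype(int)
        table = pd.DataFrame({"x": x, "y": y})
        res = logistic_fit(table, "y", ["x"], mode="univariate")
        row = res.row("x")
        se = (math.log(row["ci_high"]) - math.log(row["ci_low"])) / (2 * 1.96)
        assert row["estimate"] == pytest.approx(-1.0, abs=3 * se)

    def test_multivariate_mode_joint_fit(self):
        table = simulate_cohort(1000, seed=5)
        res = logistic_fit(
            table, "recurrence", ["nhop_max", "suv_max"], mode="multivariate"
        )
        assert set(res.table["parameter"]) == {"nhop_max", "suv_max"}
        assert res.model_kind == "logistic"
        for _, row in res.table.iterrows():
            assert row["ratio"] == pytest.approx(math.exp(row["estimate"]), rel=1e-12)
            assert 0 < row["p_value"] <= 1

    def test_null_ci_coverage_rate(self):
        covered = 0
        for seed in range(50):
            gen = np.random.default_rng(seed)
            x = gen.normal(size=300)
            y = (gen.random(300) < 0.3).astype(int)
            if y.sum() in (0, 300):
                covered += 1
                continue
            row = logistic_fit(
                pd.DataFrame({"x": x, "y": y}), "y", ["x"], mode="univariate"
            ).row("x")
            if row["ci_low"] <= 1.0 <= row["ci_high"]:
                covered += 1
        assert covered >= 43  # ~95% nominal, 3-sigma binomial slack

    def test_separation_flagged_not_silent(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        jitter = np.linspace(-0.01, 0.01, 40)
        table = pd.DataFrame({"x": x + jitter, "y": y})
        res = logistic_fit(table, "y", ["x"], mode="univariate")
        assert not res.converged
        assert res.warnings

    def test_constant_predictor_rejected(self):
        table = pd.DataFrame({"x": np.ones(50), "y": np.tile([0, 1], 25)})
        with pytest.raises(InvalidArgumentError):
            logistic_fit(table, "y", ["x"], mode="univariate")

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"x": np.arange(8.0), "y": [0, 1] * 4})
        with pytest.raises(InvalidInputError):
            logistic_fit(table, "y", ["x", "x"], mode="multivariate")


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def efron_free_partial_loglik(beta, times, events, x):
    """Hand-written partial log-likelihood (no ties, all events)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = np.arange(len(times)) >= i
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_three_subject_toy_matches_brute_force(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        x = np.array([1.0, 0.0, 1.0])
        table = pd.DataFrame({"t": times, "e": events, "x": x})
        res = cox_fit(table, "t", "e", ["x"], mode="univariate")
        brute = optimize.minimize_scalar(
            lambda b: -efron_free_partial_loglik(b, times, events, x),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.row("x")["estimate"] == pytest.approx(brute.x, abs=1e-6)

    def test_null_predictor_ci_covers_one(self):
        table = simulate_cohort(2000, hr_nhop=1.0, seed=6)
        res = cox_fit(table, "dfs_months", "event", ["nhoc_max"], mode="univariate")
        row = res.row("nhoc_max")
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_two_group_recovery_single_replicate(self):
        gen = np.random.default_rng(1)
        x = gen.integers(0, 2, size=1000).astype(float)
        t = gen.exponential(1.0 / (0.05 * 0.4**x))
        table = pd.DataFrame({"t": t, "e": np.ones(1000, dtype=int), "x": x})
        res = cox_fit(table, "t", "e", ["x"], mode="univariate")
        assert res.row("x")["estimate"] == pytest.approx(math.log(0.4), abs=0.25)

    def test_null_ci_coverage_rate(self):
        covered = 0
        for seed in range(50):
            gen = np.random.default_rng(100 + seed)
            x = gen.normal(size=300)
            t = gen.exponential(10.0, size=300)
            table = pd.DataFrame({"t": t, "e": np.ones(300, dtype=int), "x": x})
            row = cox_fit(table, "t", "e", ["x"], mode="univariate").row("x")
            if row["ci_low"] <= 1.0 <= row["ci_high"]:
                covered += 1
        assert covered >= 43

    def test_zero_events_rejected(self):
        table = pd.DataFrame({"t": [1.0, 2.0], "e": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(InvalidInputError):
            cox_fit(table, "t", "e", ["x"])

    def test_nonpositive_times_rejected(self):
        table = pd.DataFrame({"t": [0.0, 2.0], "e": [1, 1], "x": [0.0, 1.0]})
        with pytest.raises(InvalidInputError):
            cox_fit(table, "t", "e", ["x"])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def logrank_chi2_oracle(times, events, groups):
    """Brute-force per-event-time tabulation of O-E and hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    variance = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / variance


class TestKMLogrank:
    def test_identical_groups_give_null_test(self):
        base = pd.DataFrame(
            {"t": [3.0, 5.0, 7.0, 9.0], "e": [1, 0, 1, 1]}
        )
        table = pd.concat(
            [base.assign(g="a"), base.assign(g="b")], ignore_index=True
        )
        res = km_logrank(table, "t", "e", "g")
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_six_subject_toy_matches_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        groups = np.array([1, 0, 1, 0, 1, 0])
        table = pd.DataFrame({"t": times, "e": events, "g": groups})
        res = km_logrank(table, "t", "e", "g")
        assert res.logrank_chi2 == pytest.approx(
            logrank_chi2_oracle(times, events, groups), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_tied_data_matches_oracle(self, seed):
        gen = np.random.default_rng(seed)
        times = gen.integers(1, 8, size=40).astype(float)  # heavy ties
        events = gen.integers(0, 2, size=40)
        groups = gen.integers(0, 2, size=40)
        if events.sum() == 0:
            events[0] = 1
        table = pd.DataFrame({"t": times, "e": events, "g": groups})
        res = km_logrank(table, "t", "e", "g")
        assert res.logrank_chi2 == pytest.approx(
            logrank_chi2_oracle(times, events, groups), rel=1e-9
        )

    def test_km_without_censoring_is_empirical_survival(self, rng):
        times = np.sort(rng.uniform(1, 50, size=30))
        table = pd.DataFrame(
            {"t": times, "e": np.ones(30, dtype=int), "g": ["x"] * 15 + ["y"] * 15}
        )
        res = km_logrank(table, "t", "e", "g")
        curve = res.curves["x"]
        sub = times[:15]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((sub > t).mean(), abs=1e-12)

    def test_curve_shape_invariants(self):
        table = simulate_cohort(300, seed=9)
        grouped = dichotomize(table, "nhop_max", float(table["nhop_max"].median()))
        res = km_logrank(grouped, "dfs_months", "event", "nhop_max_group")
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert np.all(np.diff(surv) <= 1e-12)  # non-increasing

    def test_single_group_rejected(self):
        table = pd.DataFrame({"t": [1.0, 2.0], "e": [1, 1], "g": ["a", "a"]})
        with pytest.raises(InvalidInputError):
            km_logrank(table, "t", "e", "g")


class TestDichotomize:
    def test_cutoff_below_minimum(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            out = dichotomize(table, "v", 0.0)
        assert (out["v_group"] == "high").all()

    def test_median_splits_evenly(self, rng):
        values = rng.permutation(np.arange(100, dtype=float))
        table = pd.DataFrame({"v": values})
        out = dichotomize(table, "v", float(np.median(values)))
        assert sorted(out["v_group"].value_counts()) == [50, 50]

    def test_equal_values_go_low(self):
        table = pd.DataFrame({"v": [0.43, 0.44, 0.42]})
        out = dichotomize(table, "v", 0.43)
        assert list(out["v_group"]) == ["low", "high", "low"]

    @pytest.mark.parametrize("seed", range(3))
    def test_counting_oracle(self, seed):
        gen = np.random.default_rng(seed)
        values = gen.uniform(0, 1, size=200)
        table = pd.DataFrame({"v": values})
        out = dichotomize(table, "v", 0.43)
        assert (out["v_group"] == "high").sum() == int((values > 0.43).sum())

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dichotomize(pd.DataFrame({"v": [1.0]}), "v", float("inf"))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


class TestBuildReport:
    def test_single_roc_row_shape(self):
        res = roc_youden([1, 2, 3, 4], [0, 0, 1, 1], n_boot=10, seed=0)
        report = build_report(roc={"nhop_max": res})
        assert tuple(report.tables["roc"].columns) == ROC_REPORT_COLUMNS
        assert len(report.tables["roc"]) == 1

    def test_missing_fields_render_blank(self, tmp_path):
        table = simulate_cohort(400, seed=2)
        uni = logistic_fit(table, "recurrence", ["nhop_max", "suv_max"], "univariate")
        report = build_report(logistic=(uni, None))
        frame = report.tables["logistic"]
        assert frame["multi_ratio"].isna().all()
        report.write(tmp_path)
        text = (tmp_path / "logistic.csv").read_text()
        assert ",,," in text  # blanks, not zeros

    def test_golden_headers(self, tmp_path):
        table = simulate_cohort(400, seed=3)
        roc = {"nhop_max": roc_youden(table["nhop_max"], table["recurrence"], 20, 0)}
        uni = logistic_fit(table, "recurrence", ["nhop_max"], "univariate")
        cox_uni = cox_fit(table, "dfs_months", "event", ["nhop_max"], "univariate")
        grouped = dichotomize(table, "nhop_max", float(table["nhop_max"].median()))
        km = km_logrank(grouped, "dfs_months", "event", "nhop_max_group")
        report = build_report(roc=roc, logistic=(uni, None), cox=(cox_uni, None), km=km)
        report.write(tmp_path)
        assert (tmp_path / "roc.csv").read_text().splitlines()[0] == ",".join(
            ROC_REPORT_COLUMNS
        )
        assert (tmp_path / "logistic.csv").read_text().splitlines()[0] == ",".join(
            REGRESSION_REPORT_COLUMNS
        )
        assert (tmp_path / "km_curves.csv").read_text().splitlines()[0] == "group,time,survival"

    def test_empty_report_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_report()
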