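"""Evaluation protocol: fold plans, six metrics, Bland-Altman, t-test, experiment driver."""

import numpy as np
import pytest

from cadx import (
    FoldPlan,
    bland_altman,
    make_folds,
    run_experiment,
    six_metrics,
    two_sample_t,
)

from _oracles import auc_pairs, pooled_t


def _fake_cases(n_per_class=30):
    return [(f"b{i}", "benign") for i in range(n_per_class)] + [
        (f"m{i}", "malignant") for i in range(n_per_class)
    ]


class TestMakeFolds:
    def test_partition_property(self):
        cases = _fake_cases(30)
        plan = make_folds(cases, seed=1)
        all_ids = {c[0] for c in cases}
        for rep in plan.repetitions:
            seen = [cid for fold in rep for cid in fold]
            assert set(seen) == all_ids and len(seen) == len(all_ids)

    def test_fold_sizes_even_split(self):
        plan = make_folds(_fake_cases(260), seed=0, n_repetitions=2)
        for rep in plan.repetitions:
            assert all(len(fold) == 52 for fold in rep)

    def test_repetitions_are_distinct_partitions(self):
        plan = make_folds(_fake_cases(30), seed=2)
        sigs = {frozenset(frozenset(f) for f in rep) for rep in plan.repetitions}
        assert len(sigs) == plan.n_repetitions == 10

    def test_stratification_keeps_class_balance(self):
        labels = dict(_fake_cases(30))
        plan = make_folds(_fake_cases(30), seed=3)
        for rep in plan.repetitions:
            for fold in rep:
                n_mal = sum(labels[c] == "malignant" for c in fold)
                assert n_mal == 3  # 30 malignant over 10 folds

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            make_folds(_fake_cases(5), seed=0)

    def test_json_round_trip(self, tmp_path):
        plan = make_folds(_fake_cases(20), seed=4, n_repetitions=3)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = FoldPlan.from_json(path)
        assert back.repetitions == plan.repetitions and back.seed == plan.seed


class TestSixMetrics:
    def test_confusion_matrix_hand_example(self):
        # TP=9, FN=1, TN=8, FP=2
        labels = ["malignant"] * 10 + ["benign"] * 10
        preds = ["malignant"] * 9 + ["benign"] + ["benign"] * 8 + ["malignant"] * 2
        scores = [1.0 if p == "malignant" else 0.0 for p in preds]
        m = six_metrics(labels, preds, scores)
        assert m["ACC"] == pytest.approx(0.85)
        assert m["SENS"] == pytest.approx(0.90)
        assert m["SPEC"] == pytest.approx(0.80)
        assert m["PPV"] == pytest.approx(9 / 11)
        assert m["NPV"] == pytest.approx(8 / 9)

    def test_perfect_and_reversed_auc(self):
        labels = ["benign"] * 5 + ["malignant"] * 5
        preds = labels
        m = six_metrics(labels, preds, np.arange(10))
        assert m["AUC"] == pytest.approx(1.0)
        m = six_metrics(labels, preds, -np.arange(10))
        assert m["AUC"] == pytest.approx(0.0)

    def test_auc_matches_all_pairs_mann_whitney(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.integers(0, 8, 30).astype(float)  # ties likely
            labels = ["malignant" if v else "benign" for v in y]
            m = six_metrics(labels, labels, scores)
            assert m["AUC"] == pytest.approx(auc_pairs(y, scores), abs=1e-12)

    def test_undefined_ratios_reported_as_nan(self):
        labels = ["benign"] * 4
        preds = ["benign"] * 4
        m = six_metrics(labels, preds, np.zeros(4))
        assert np.isnan(m["SENS"]) and np.isnan(m["PPV"]) and np.isnan(m["AUC"])
        assert m["SPEC"] == 1.0 and m["NPV"] == 1.0

    def test_acc_consistent_with_sens_spec_decomposition(self, rng):
        y = np.array([1] * 12 + [0] * 8)
        p = rng.integers(0, 2, 20)
        labels = ["malignant" if v else "benign" for v in y]
        preds = ["malignant" if v else "benign" for v in p]
        m = six_metrics(labels, preds, p.astype(float))
        recomposed = (m["SENS"] * 12 + m["SPEC"] * 8) / 20
        assert m["ACC"] == pytest.approx(recomposed, abs=1e-12)


class TestBlandAltman:
    def test_identical_series_zero_limits(self):
        ba = bland_altman([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert ba.mean_diff == 0.0 and ba.upper_limit == 0.0 and ba.lower_limit == 0.0

    def test_plus_minus_one_hand_example(self):
        ba = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(np.sqrt(2))
        assert ba.upper_limit == pytest.approx(1.96 * np.sqrt(2))
        assert ba.lower_limit == pytest.approx(-1.96 * np.sqrt(2))

    def test_limits_match_direct_formula(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        ba = bland_altman(a, b)
        d = a - b
        assert ba.mean_diff == pytest.approx(d.mean(), abs=1e-12)
        assert ba.upper_limit == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        assert ba.lower_limit == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0, 2.0])


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t_hand, p_hand = pooled_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_symmetry_under_swap(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_equal_means_convention(self):
        t, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0


@pytest.fixture(scope="module")
def report(small_ct_cases):
    plan = make_folds(small_ct_cases, seed=8, n_repetitions=2, n_folds=4)
    return run_experiment(small_ct_cases, ["morph"], "all", plan)


class TestRunExperiment:
    def test_fold_row_count(self, report):
        assert len(report.per_fold) == 2 * 4
        assert set(report.per_fold["method"]) == {"morph"}

    def test_aggregate_matches_bruteforce_recomputation(self, report):
        grp = report.per_fold[report.per_fold["method"] == "morph"]
        agg = report.aggregate.iloc[0]
        vals = grp["ACC"].dropna().to_numpy()
        assert agg["ACC_mean"] == pytest.approx(vals.mean(), abs=1e-12)
        assert agg["ACC_sd"] == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def test_plan_must_cover_cases(self, small_ct_cases):
        plan = make_folds(small_ct_cases[:-1], seed=0, n_repetitions=2, n_folds=4)
        with pytest.raises(ValueError):
            run_experiment(small_ct_cases, ["morph"], "all", plan)

    def test_single_equals_all_on_single_slice_cases(self, small_us_cases):
        plan = make_folds(small_us_cases, seed=9, n_repetitions=2, n_folds=4)
        r1 = run_experiment(small_us_cases, ["curve"], "single", plan)
        r2 = run_experiment(small_us_cases, ["curve"], "all", plan)
        import pandas as pd

        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)

    def test_report_writing(self, report, tmp_path):
        report.write(tmp_path)
        assert (tmp_path / "per_fold_metrics.csv").exists()
        assert (tmp_path / "aggregate_metrics.csv").exists()
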