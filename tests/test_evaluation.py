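"""Nested cross-testing harness: fold plans, leakage isolation, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tricoat import (CohortSpec, EvaluationReport, FlatFeatureClassifier,
                     make_fold_plan, paired_ttest, run_cross_testing,
                     simulate_cohort)


@pytest.fixture(scope="module")
def harness_cohort():
    cohort, labels = simulate_cohort(
        CohortSpec(n_per_class=(60, 70, 20), effect_size=1.0, seed=17))
    return cohort, labels


class TestFoldPlan:
    def test_outer_folds_partition_cohort(self, harness_cohort):
        _, labels = harness_cohort
        plan = make_fold_plan(labels, seed=0)
        all_test = [s for f in plan.outer for s in f["test"]]
        assert sorted(all_test) == sorted(labels.index)
        assert len(set(all_test)) == len(all_test)
        for fold in plan.outer:
            assert set(fold["train"]) | set(fold["test"]) == set(labels.index)
            assert not set(fold["train"]) & set(fold["test"])

    def test_inner_folds_partition_outer_train(self, harness_cohort):
        _, labels = harness_cohort
        plan = make_fold_plan(labels, seed=0)
        for k, inner in enumerate(plan.inner):
            train = set(plan.outer[k]["train"])
            test = set(plan.outer[k]["test"])
            all_val = [s for split in inner for s in split["val"]]
            assert set(all_val) == train
            for split in inner:
                assert not set(split["val"]) & test
                assert not set(split["train"]) & test
                assert set(split["train"]) | set(split["val"]) == train

    def test_exact_divisibility_gives_one_per_class(self):
        labels = pd.Series(np.repeat(["slow", "intermediate", "fast"], 10),
                           index=[f"S{i:03d}" for i in range(30)])
        plan = make_fold_plan(labels, seed=0)
        for fold in plan.outer:
            counts = labels.loc[fold["test"]].value_counts()
            assert counts.to_dict() == {"slow": 1, "intermediate": 1, "fast": 1}

    def test_stratification_chi_square_nonsignificant(self):
        """Fold label distributions are compatible with the cohort's."""
        _, labels = simulate_cohort(CohortSpec(seed=23))  # n = 494
        plan = make_fold_plan(labels, seed=1)
        overall = labels.value_counts(normalize=True)
        for fold in plan.outer:
            counts = labels.loc[fold["test"]].value_counts()
            counts = counts.reindex(overall.index, fill_value=0)
            expected = overall * counts.sum()
            chi2 = (((counts - expected) ** 2) / expected).sum()
            p = 1 - stats.chi2.cdf(chi2, df=2)
            assert p > 0.05

    def test_small_class_warns_but_splits(self):
        labels = pd.Series(["slow"] * 30 + ["intermediate"] * 30 + ["fast"] * 4,
                           index=[f"S{i:03d}" for i in range(64)])
        with pytest.warns(UserWarning, match="fewer members"):
            plan = make_fold_plan(labels, seed=0, n_outer=10)
        all_test = [s for f in plan.outer for s in f["test"]]
        assert sorted(all_test) == sorted(labels.index)

    def test_plan_deterministic_and_json_round_trip(self, harness_cohort,
                                                    tmp_path):
        _, labels = harness_cohort
        a = make_fold_plan(labels, seed=5)
        b = make_fold_plan(labels, seed=5)
        assert a.outer == b.outer and a.inner == b.inner
        a.to_json(tmp_path / "folds.json")
        from tricoat import FoldPlan
        c = FoldPlan.from_json(tmp_path / "folds.json")
        assert c.outer == a.outer and c.inner == a.inner


@pytest.fixture(scope="module")
def report(harness_cohort):
    cohort, labels = harness_cohort
    methods = {"svm": FlatFeatureClassifier(method="svm"),
               "rf": FlatFeatureClassifier(method="rf")}
    plan = make_fold_plan(labels, seed=3)
    return run_cross_testing(cohort, labels, methods, plan, seed=3)


class TestCrossTesting:
    def test_fifty_evaluations_per_method(self, report):
        counts = report.records.groupby("method").size()
        assert (counts == 50).all()

    def test_summary_uses_sample_sd(self, report):
        s = report.summary()
        svm = report.records.query("method == 'svm'")["auroc"]
        assert s.loc["svm", "sd_auroc"] == pytest.approx(svm.std(ddof=1))
        assert s.loc["svm", "mean_auroc"] == pytest.approx(svm.mean())

    def test_planted_signal_detected(self, report):
        assert report.summary()["mean_auroc"].min() > 0.6

    def test_perturbing_test_rows_changes_nothing_upstream(self,
                                                           harness_cohort):
        """Leakage probe: corrupting a fold's test-subject features leaves
        scaler statistics, inner-CV selections and validation scores
        bit-identical."""
        cohort, labels = harness_cohort
        methods = {"svm": FlatFeatureClassifier(method="svm")}
        plan = make_fold_plan(labels, seed=4, n_outer=4, n_inner=3)
        base = run_cross_testing(cohort, labels, methods, plan, seed=4)
        corrupted = cohort.copy()
        test0 = plan.outer[0]["test"]
        corrupted.clinical.loc[test0] += 1e3
        corrupted.imaging.loc[test0] -= 1e3
        probe = run_cross_testing(corrupted, labels, methods, plan, seed=4)
        f0 = base.records.query("outer_fold == 0")
        p0 = probe.records.query("outer_fold == 0")
        # fold 0 never trains, selects or scales on its own test subjects,
        # so everything upstream of its test AUROC is bit-identical
        assert (f0["val_auroc"].to_numpy() == p0["val_auroc"].to_numpy()).all()
        assert (f0["params"].to_numpy() == p0["params"].to_numpy()).all()

    def test_grid_selection_prefers_better_validation_setting(self,
                                                              harness_cohort):
        cohort, labels = harness_cohort
        methods = {"svm": FlatFeatureClassifier(method="svm")}
        plan = make_fold_plan(labels, seed=6, n_outer=3, n_inner=2)
        grid = {"svm": [{"modality": "all"}, {"modality": "genetics"}]}
        report = run_cross_testing(cohort, labels, methods, plan, grid=grid,
                                   seed=6)
        chosen = report.records["params"].map(lambda s: "all" in s)
        # imaging+clinical carry most signal, so "all" should dominate
        assert chosen.mean() > 0.5


class TestPairedTTest:
    @staticmethod
    def _report(a_scores, b_scores):
        rows = []
        for i, (a, b) in enumerate(zip(a_scores, b_scores)):
            rows.append({"method": "A", "outer_fold": i // 5, "repeat": i % 5,
                         "auroc": a, "val_auroc": a, "params": "{}"})
            rows.append({"method": "B", "outer_fold": i // 5, "repeat": i % 5,
                         "auroc": b, "val_auroc": b, "params": "{}"})
        return EvaluationReport(records=pd.DataFrame(rows))

    def test_identical_methods_p_one(self):
        x = np.linspace(0.5, 0.9, 50)
        rep = self._report(x, x)
        assert paired_ttest(rep, "A", "B") == 1.0

    def test_constant_nonzero_difference_p_zero(self):
        x = np.linspace(0.5, 0.9, 50)
        rep = self._report(x + 0.05, x)
        assert paired_ttest(rep, "A", "B") == 0.0

    def test_matches_scipy_on_generic_data(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 0.9, size=50)
        b = a + rng.normal(0, 0.03, size=50)
        rep = self._report(a, b)
        expect = stats.ttest_rel(a, b).pvalue
        assert paired_ttest(rep, "A", "B") == pytest.approx(expect)

    def test_null_p_values_uniform(self):
        """Matched samples from one distribution give uniform p (KS test)."""
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(500):
            a = rng.normal(0.7, 0.05, size=20)
            b = rng.normal(0.7, 0.05, size=20)
            pvals.append(stats.ttest_rel(a, b).pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_unmatched_entries_rejected(self):
        x = np.linspace(0.5, 0.9, 50)
        rep = self._report(x, x)
        rep.records = rep.records.iloc[:-1]
        with pytest.raises(ValueError, match="unmatched"):
            paired_ttest(rep, "A", "B")
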