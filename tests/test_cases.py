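import numpy as np
import pandas as pd
import pytest

import soundmvpa as sm
from soundmvpa.cases import (
    CaseParams,
    average_over_items,
    average_over_subjects,
    plan_across_subject,
    plan_within_subject,
    run_case,
    summarize_cases,
    ttest_one_sample,
    ttest_two_sample,
)
from conftest import make_clean_dataset


@pytest.fixture(scope="module")
def study_dataset(small_grid):
    """Full study design (7 runs x 42 trials) for one unperturbed subject."""
    ds, *_ = make_clean_dataset(
        small_grid, n_runs=7, n_categories=7, items=2, n_informative=3, seed=41
    )
    return ds


class TestWithinSubjectPlan:
    def test_fold_sizes_for_study_design(self, small_grid):
        ds, *_ = make_clean_dataset(
            small_grid, n_runs=7, n_categories=7, items=6, n_informative=2,
            seed=42, sigma_noise=0.1,
        )
        plan = plan_within_subject(ds, "sub1", n_reps=5, seed=0)
        assert len(plan.folds) == 5
        for train, test, _ in plan.folds:
            assert len(train) == 5 * 42 and len(test) == 2 * 42
            assert np.intersect1d(train, test).size == 0

    def test_splits_distinct_and_deterministic(self, study_dataset):
        p1 = plan_within_subject(study_dataset, "sub1", n_reps=5, seed=3)
        p2 = plan_within_subject(study_dataset, "sub1", n_reps=5, seed=3)
        key = lambda plan: [tuple(tr) for tr, _, _ in plan.folds]
        assert key(p1) == key(p2)
        assert len(set(key(p1))) == 5

    def test_too_many_repetitions_rejected(self, study_dataset):
        with pytest.raises(ValueError):
            plan_within_subject(study_dataset, "sub1", n_reps=22)  # C(7,5)=21

    def test_unknown_subject_rejected(self, study_dataset):
        with pytest.raises(KeyError):
            plan_within_subject(study_dataset, "nope")


class TestAcrossSubjectPlan:
    def test_one_fold_per_subject_partition(self, small_grid):
        ds, *_ = make_clean_dataset(small_grid, n_subjects=5, seed=43)
        plan = plan_across_subject(ds)
        assert len(plan.folds) == 5
        tested = np.concatenate([t for _, t, _ in plan.folds])
        assert np.array_equal(np.sort(tested), np.arange(ds.n_samples))

    def test_two_subjects_two_folds(self, small_grid):
        ds, *_ = make_clean_dataset(small_grid, n_subjects=2, seed=43)
        assert len(plan_across_subject(ds).folds) == 2

    def test_single_subject_rejected(self, small_grid):
        ds, *_ = make_clean_dataset(small_grid, n_subjects=1, seed=43)
        with pytest.raises(ValueError):
            plan_across_subject(ds)


class TestAveraging:
    def test_item_averaging_counts(self, small_grid):
        ds, *_ = make_clean_dataset(
            small_grid, n_runs=2, n_categories=7, items=6, n_informative=2, seed=44
        )
        avg = average_over_items(ds)
        assert avg.n_samples == 2 * 7  # one sample per (run, category)
        assert set(avg.labels["item"]) == {"avg"}

    def test_item_averaging_of_identical_items_is_identity(self, small_grid):
        ds, *_ = make_clean_dataset(
            small_grid, sigma_noise=0.0, sigma_item=0.0, seed=44
        )
        avg = average_over_items(ds)
        # noiseless samples of a category are identical, so the mean equals any one
        row0 = ds.X[0]
        c0 = ds.labels.loc[0, ["subject", "run", "category"]]
        m = (
            (avg.labels["subject"] == c0["subject"])
            & (avg.labels["run"] == c0["run"])
            & (avg.labels["category"] == c0["category"])
        ).to_numpy()
        assert np.allclose(avg.X[m][0], row0)

    def test_item_averaging_reduces_noise_by_sqrt_n(self, small_grid):
        ds, *_ = make_clean_dataset(
            small_grid, n_runs=6, n_categories=4, items=6, effect=0.0,
            sigma_noise=1.0, seed=45,
        )
        avg = average_over_items(ds)
        ratio = avg.X.std() / ds.X.std()
        assert abs(ratio - 1 / np.sqrt(6)) < 0.05

    def test_missing_item_rejected(self, small_grid):
        ds, *_ = make_clean_dataset(small_grid, seed=46)
        with pytest.raises(ValueError):
            average_over_items(ds.subset(np.arange(1, ds.n_samples)))

    def test_subject_averaging_counts_and_identity(self, small_grid):
        ds2, *_ = make_clean_dataset(small_grid, n_subjects=3, seed=47)
        avg = average_over_subjects(ds2)
        assert avg.n_samples == ds2.n_samples // 3
        assert set(avg.labels["subject"]) == {"avg"}
        ds1, *_ = make_clean_dataset(small_grid, n_subjects=1, seed=47)
        same = average_over_subjects(ds1)
        assert np.allclose(same.X, ds1.X)

    def test_averaging_operators_commute(self, small_grid):
        ds, *_ = make_clean_dataset(
            small_grid, n_subjects=2, sigma_noise=1.0, seed=48
        )
        a = average_over_items(average_over_subjects(ds))
        b = average_over_subjects(average_over_items(ds))
        key = ["run", "category", "item"]
        a_sorted = a.X[a.labels.sort_values(key).index.to_numpy()]
        b_sorted = b.X[b.labels.sort_values(key).index.to_numpy()]
        assert np.allclose(a_sorted, b_sorted)

    def test_unequal_designs_rejected(self, small_grid):
        ds, *_ = make_clean_dataset(small_grid, n_subjects=2, seed=49)
        with pytest.raises(ValueError):
            average_over_subjects(ds.subset(np.arange(ds.n_samples - 1)))


class TestTTests:
    def test_one_sample_symmetry_and_hand_formula(self):
        r = ttest_one_sample([0.1, 0.3], 0.2)
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)
        accs = np.array([0.3, 0.4, 0.5])
        r = ttest_one_sample(accs, 1 / 7)
        t_hand = (accs.mean() - 1 / 7) / (accs.std(ddof=1) / np.sqrt(3))
        assert r.t == pytest.approx(t_hand) and r.df == 2

    def test_one_sample_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ttest_one_sample([0.5], 0.2)
        with pytest.raises(ValueError):
            ttest_one_sample([0.4, 0.4, 0.4], 0.2)

    def test_two_sample_identity_antisymmetry_and_hand_check(self):
        a = [0.5, 0.6, 0.7]
        assert ttest_two_sample(a, a).t == pytest.approx(0.0)
        b = [0.2, 0.3, 0.35, 0.4]
        r1, r2 = ttest_two_sample(a, b), ttest_two_sample(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)
        assert r1.df == len(a) + len(b) - 2
        # pooled-variance hand computation
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = (2 * va + 3 * vb) / 5
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 4))
        assert r1.t == pytest.approx(t_hand)

    def test_two_sample_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_sample([0.5], [0.4, 0.3])


@pytest.fixture(scope="module")
def mini_results(small_grid):
    ds, *_ = make_clean_dataset(
        small_grid, n_runs=4, n_categories=3, items=2, n_subjects=2,
        effect=2.5, sigma_noise=0.5, seed=50,
    )
    params = CaseParams(n_reps=2, n_train_runs=3, seed=50, keep_fits=False)
    return {
        c: run_case(ds, c, params)
        for c in ("WithinSub", "AcrossSub", "AvgItem", "AvgSub")
    }


class TestRunCaseAndSummary:
    def test_high_snr_within_subject_accuracy(self, mini_results):
        r = mini_results["WithinSub"]
        assert r.mean >= 0.8
        assert len(r.accuracies) == 2 * 2  # subjects x repetitions
        assert {k[0] for k in r.fold_keys} == {"sub1", "sub2"}

    def test_avgsub_close_to_within_mean_without_subject_effects(self, mini_results):
        # no subject perturbation -> averaged-subject decoding mirrors the
        # within-subject level
        assert abs(mini_results["AvgSub"].mean - mini_results["WithinSub"].mean) <= 0.2

    def test_all_cases_within_bounds(self, mini_results):
        for r in mini_results.values():
            assert np.all((r.accuracies >= 0.0) & (r.accuracies <= 1.0))

    def test_summary_table_and_comparisons(self, mini_results):
        table, comps = summarize_cases(list(mini_results.values()))
        assert list(table["case"]) == ["WithinSub", "AcrossSub", "AvgItem", "AvgSub"]
        assert set(comps["case_a"]) == {"WithinSub", "AvgItem"}
        row = comps[comps.case_a == "WithinSub"].iloc[0]
        ref = ttest_two_sample(
            mini_results["WithinSub"].accuracies,
            mini_results["AcrossSub"].accuracies,
        )
        assert row["t"] == pytest.approx(ref.t)

    def test_single_case_no_comparisons(self, mini_results):
        table, comps = summarize_cases([mini_results["WithinSub"]])
        assert len(table) == 1 and comps.empty

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize_cases([])

    def test_unknown_case_rejected(self, small_grid):
        ds, *_ = make_clean_dataset(small_grid, seed=51)
        with pytest.raises(ValueError):
            run_case(ds, "Bogus")

    def test_exclude_subjects(self, small_grid):
        ds, *_ = make_clean_dataset(
            small_grid, n_subjects=3, n_runs=4, n_categories=3, items=2, seed=52
        )
        params = CaseParams(
            n_reps=1, n_train_runs=3, exclude_subjects=("sub2",), keep_fits=False
        )
        r = run_case(ds, "AcrossSub", params)
        assert {k[0] for k in r.fold_keys} == {"sub1", "sub3"}
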