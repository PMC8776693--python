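import numpy as np
import pandas as pd
import pytest

from ofrad.cohort import CohortConfig, cohort_from_counts, sample_clinical_table
from ofrad.evaluation import (
    ModelSpec,
    assign_folds,
    auc_mann_whitney,
    c_index,
    idi,
    nri,
    risk_group_km,
    roc_and_auc,
    run_experiment,
    threshold_metrics,
)
from ofrad.exceptions import ConfigurationError, DataError


@pytest.fixture(scope="module")
def cohort180():
    return sample_clinical_table(CohortConfig(n_patients=180, seed=6))


class TestFolds:
    def test_fivefold_partitions_into_equal_folds(self, cohort180):
        scheme = assign_folds(cohort180, "fivefold", seed=0)
        sizes = [len(te) for _, te in scheme.folds]
        assert sizes == [36] * 5
        all_test = np.sort(np.concatenate([te for _, te in scheme.folds]))
        assert np.array_equal(all_test, np.arange(180))

    def test_training_folds_contain_both_classes(self, cohort180):
        scheme = assign_folds(cohort180, "fivefold", seed=0)
        y = cohort180["ofr_event"].to_numpy()
        for tr, _ in scheme.folds:
            assert y[tr].any() and not y[tr].all()

    def test_same_seed_same_assignment(self, cohort180):
        s1 = assign_folds(cohort180, "fivefold", seed=3)
        s2 = assign_folds(cohort180, "fivefold", seed=3)
        for (a, b), (c, d) in zip(s1.folds, s2.folds):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_zero_event_institutions_never_test(self, cohort180):
        scheme = assign_folds(cohort180, "leave_one_institution_out")
        assert scheme.always_train_institutions == {"H", "J"}
        inst = cohort180["institution"].to_numpy()
        tested = {inst[te[0]] for _, te in scheme.folds}
        assert "H" not in tested and "J" not in tested

    def test_three_institution_holdout_uses_large_sites(self, cohort180):
        scheme = assign_folds(cohort180, "three_institution_holdout")
        inst = cohort180["institution"].to_numpy()
        tested = {inst[te[0]] for _, te in scheme.folds}
        sizes = pd.Series(inst).value_counts()
        assert all(sizes[t] > 20 for t in tested)


class TestROC:
    def test_perfect_separation(self):
        _, _, _, auc = roc_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_binary_marker_auc_from_printed_contingency(self):
        """A binary predictor's AUC equals (sensitivity + specificity) / 2:
        with 12/38 sensitive and 133/142 specific the AUC is ~0.6262."""
        records = cohort_from_counts()
        auc = auc_mann_whitney(
            records["paln"].to_numpy(dtype=float), records["ofr_event"].to_numpy()
        )
        assert auc == pytest.approx((12 / 38 + 133 / 142) / 2, abs=1e-10)
        assert auc == pytest.approx(0.6262, abs=5e-4)

    def test_null_scores_auc_half(self, rng):
        y = rng.random(10_000) < 0.3
        p = rng.random(10_000)
        assert auc_mann_whitney(p, y) == pytest.approx(0.5, abs=0.02)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = (rng.random(500) < 0.3).astype(int)
        p = np.round(rng.random(500), 2)  # force ties
        assert auc_mann_whitney(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            auc_mann_whitney([0.5, 0.6], [1, 1])


class TestThresholdMetrics:
    def test_hand_toy_confusion(self):
        m = threshold_metrics([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0])
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_degenerate_all_positive(self):
        m = threshold_metrics([1.0, 1.0], [1, 1])
        assert m["accuracy"] == 1.0 and m["sensitivity"] == 1.0
        assert np.isnan(m["specificity"])

    def test_zero_threshold_full_sensitivity(self, rng):
        p = rng.random(50)
        y = rng.random(50) < 0.4
        y[0] = True
        assert threshold_metrics(p, y, threshold=0.0)["sensitivity"] == 1.0


class TestNriIdi:
    def test_hand_computed_toy(self):
        # events: 0.2->0.3, 0.4->0.5 (both up); non-event: 0.5->0.4 (down)
        p_ref = np.array([0.2, 0.4, 0.5])
        p_new = np.array([0.3, 0.5, 0.4])
        y = np.array([True, True, False])
        assert nri(p_ref, p_new, y, n_boot=10).value == pytest.approx(2.0)
        assert idi(p_ref, p_new, y, n_boot=10).value == pytest.approx(0.2)

    def test_identical_vectors_zero(self, rng):
        p = rng.random(40)
        y = rng.random(40) < 0.5
        y[:2] = [True, False]
        assert nri(p, p, y, n_boot=10).value == 0.0
        assert idi(p, p, y, n_boot=10).value == 0.0

    def test_antisymmetric_under_swap(self, rng):
        a, b = rng.random(60), rng.random(60)
        y = rng.random(60) < 0.4
        y[:2] = [True, False]
        assert nri(a, b, y, n_boot=10).value == pytest.approx(-nri(b, a, y, n_boot=10).value)
        assert idi(a, b, y, n_boot=10).value == pytest.approx(-idi(b, a, y, n_boot=10).value)

    def test_bootstrap_ci_brackets_point(self, rng):
        n = 300
        y = rng.random(n) < 0.4
        p_ref = np.clip(0.3 + 0.2 * y + rng.normal(0, 0.15, n), 0.01, 0.99)
        p_new = np.clip(p_ref + 0.1 * y - 0.05, 0.01, 0.99)
        res = idi(p_ref, p_new, y, n_boot=400, seed=1)
        assert res.ci_low <= res.value <= res.ci_high
        assert 0 <= res.p <= 1


class TestCIndex:
    def test_perfect_concordance(self):
        times = np.array([5.0, 3.0, 9.0, 1.0])
        scores = -times
        assert c_index(scores, times, np.ones(4, bool)) == 1.0

    def test_constant_scores_half(self, rng):
        times = rng.exponential(10, 30)
        assert c_index(np.ones(30), times, np.ones(30, bool)) == 0.5

    def test_five_subject_toy_matches_hand_count(self):
        # subjects: times 2,4,6,8,10; subject at 6 censored; scores below
        times = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        events = np.array([True, True, False, True, True])
        scores = np.array([0.9, 0.3, 0.5, 0.4, 0.1])
        # comparable pairs and concordances counted by hand:
        # event@2 vs {4,6,8,10}: 0.9 > all -> 4 concordant
        # event@4 vs {6,8,10}: 0.3 vs 0.5 disc, 0.3 vs 0.4 disc, 0.3 vs 0.1 conc
        # censored@6: no pairs as the earlier subject of any remaining pair
        # event@8 vs {10}: 0.4 > 0.1 -> concordant
        # total: 6 concordant of 8 comparable
        assert c_index(scores, times, events) == pytest.approx(6 / 8)


class TestRiskGroups:
    def test_probabilities_equal_labels_separate_curves(self, rng):
        n = 100
        events = np.r_[np.ones(30, bool), np.zeros(70, bool)]
        times = np.where(events, rng.uniform(1, 36, n), rng.uniform(36, 96, n))
        records = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "time_months": times, "ofr_event": events}
        )
        hi, lo, lr = risk_group_km(events.astype(float), records)
        assert lr.p < 0.01
        assert hi.survival_at(36.0) < lo.survival_at(36.0)

    def test_threshold_outside_unit_interval_rejected(self, rng):
        records = pd.DataFrame(
            {"patient_id": ["a", "b"], "time_months": [5.0, 40.0], "ofr_event": [True, False]}
        )
        with pytest.raises(ConfigurationError):
            risk_group_km([0.2, 0.7], records, threshold=1.5)

    def test_single_group_flagged_without_test(self):
        records = pd.DataFrame(
            {"patient_id": ["a", "b"], "time_months": [5.0, 40.0], "ofr_event": [True, False]}
        )
        hi, lo, lr = risk_group_km([0.9, 0.8], records)
        assert lo is None and lr is None


@pytest.fixture(scope="module")
def toy_cohort():
    rng = np.random.default_rng(8)
    n = 80
    records = sample_clinical_table(CohortConfig(n_patients=n, seed=8))
    signal = records["ofr_event"].to_numpy().astype(float)
    feats = pd.DataFrame(
        {
            "good": signal + rng.normal(0, 0.6, n),
            **{f"n{i}": rng.normal(size=n) for i in range(5)},
        },
        index=records["patient_id"].to_numpy(),
    )
    return records, feats


class TestRunExperiment:
    def test_report_has_five_fold_aucs(self, toy_cohort):
        records, feats = toy_cohort
        rep = run_experiment(records, feats, ModelSpec("lasso", "radiomics_only"), "fivefold", seed=1)
        assert len(rep.fold_aucs) == 5
        assert 0.0 <= rep.pooled_auc <= 1.0
        assert rep.oof_probs.index.is_unique and len(rep.oof_probs) == len(records)

    def test_no_leakage_test_labels_do_not_affect_fit(self, toy_cohort):
        """Shuffling labels inside the held-out fold must leave the fitted
        fold model (and its predictions) unchanged."""
        records, feats = toy_cohort
        scheme = assign_folds(records, "fivefold", seed=2)
        tr, te = scheme.folds[0]
        shuffled = records.copy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(te)
        shuffled.loc[shuffled.index[te], "ofr_event"] = records["ofr_event"].to_numpy()[perm]
        rep1 = run_experiment(records, feats, ModelSpec("lasso", "radiomics_only"), scheme, seed=1)
        rep2 = run_experiment(shuffled, feats, ModelSpec("lasso", "radiomics_only"), scheme, seed=1)
        te_ids = records["patient_id"].to_numpy()[te]
        p1 = rep1.oof_probs.loc[te_ids].to_numpy()
        p2 = rep2.oof_probs.loc[te_ids].to_numpy()
        assert np.allclose(p1, p2)

    def test_selection_runs_inside_folds_for_ridge(self, toy_cohort):
        records, feats = toy_cohort
        rep = run_experiment(
            records, feats, ModelSpec("ridge", "radiomics_only"), "fivefold", seed=1, selection_k=3
        )
        assert len(rep.selection_counts) > 0
        assert (rep.selection_counts <= 5).all()

    def test_summary_mentions_model_and_auc(self, toy_cohort):
        records, feats = toy_cohort
        rep = run_experiment(records, feats, ModelSpec("lasso", "radiomics_only"), "fivefold", seed=1)
        text = rep.summary()
        assert "lasso" in text and "AUC" in text
        assert len(rep.fold_rocs) == len(rep.fold_aucs)


def test_pooled_and_mean_fold_auc_agree_on_homogeneous_cohort(rng):
    """On a homogeneous cohort the pooled out-of-fold AUC and the mean of the
    per-fold AUCs estimate the same quantity (within 0.05)."""
    n = 400
    records = sample_clinical_table(CohortConfig(n_patients=n, seed=15))
    signal = records["ofr_event"].to_numpy().astype(float)
    feats = pd.DataFrame(
        {"good": signal + rng.normal(0, 1.0, n), "noise": rng.normal(size=n)},
        index=records["patient_id"].to_numpy(),
    )
    rep = run_experiment(records, feats, ModelSpec("ridge", "radiomics_only"), "fivefold", seed=2,
                         selection_k=2)
    assert abs(rep.pooled_auc - rep.mean_auc) < 0.05


def test_nri_idi_converge_to_population_values(rng):
    """Deterministic shifts give analytically known NRI/IDI at any n."""
    n = 2000
    y = rng.random(n) < 0.3
    p_ref = np.clip(rng.random(n), 0.05, 0.95)
    p_new = np.where(y, p_ref + 0.02, p_ref - 0.01)  # events up, non-events down
    assert nri(p_ref, p_new, y, n_boot=10).value == pytest.approx(2.0)
    assert idi(p_ref, p_new, y, n_boot=10).value == pytest.approx(0.03, abs=1e-12)


def test_institution_holdout_averages_fold_models(cohort180):
    """Each >20-patient site is held out once; the held-out predictions are
    the average of the five inner fold-models."""
    from ofrad.evaluation import institution_holdout_experiment

    results = institution_holdout_experiment(
        cohort180, None, ModelSpec("ridge", "clinical_only"), seed=4
    )
    assert {r["institution"] for r in results} == {"A", "B", "C"}
    for r in results:
        assert r["n_test"] > 20
        if "auc" in r:
            assert 0.0 <= r["auc"] <= 1.0
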