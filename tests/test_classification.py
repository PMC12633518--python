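import numpy as np
import pandas as pd
import pytest

from netfp.classification import (
    ClassifierConfig,
    classify_disease_binary,
    classify_multiclass,
    coefficient_overlap,
    patient_fingerprint,
    predict_covariate,
    regional_importance,
)
from netfp.synthetic import roi_edge_signature, simulate_edge_cohort

FAST = ClassifierConfig(
    l1_lambda_grid=(0.01, 0.1, 1.0, 10.0),
    cv_folds=5,
    cv_repeats=2,
    n_bootstrap=200,
)


def _separable_cohort(seed=0, n=30, n_edges=45):
    """Disjoint edge supports -> perfectly separable."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n):
        is_pos = i % 2 == 0
        v = np.zeros(n_edges)
        if is_pos:
            v[: n_edges // 2] = rng.uniform(2, 3, n_edges // 2)
        else:
            v[n_edges // 2:] = rng.uniform(2, 3, n_edges - n_edges // 2)
        rows.append(v + 0.01 * rng.normal(size=n_edges))
        labels.append("DIS" if is_pos else "HC")
    ids = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(rows, index=ids, columns=[f"e{k}" for k in range(n_edges)])
    return df, pd.Series(labels, index=ids)


class TestBinary:
    def test_separable_ap_one(self):
        df, labels = _separable_cohort()
        report = classify_disease_binary(df, labels, config=FAST, seed=3)
        assert report.ap == 1.0
        assert report.roc_auc == 1.0
        assert report.ap_ci == (1.0, 1.0)

    def test_chance_level_is_test_prevalence(self):
        df, labels = _separable_cohort()
        report = classify_disease_binary(df, labels, config=FAST, seed=3)
        n_test = len(report.test_scan_ids)
        n_pos = sum(labels.loc[report.test_scan_ids] == "DIS")
        assert report.ap_chance == pytest.approx(n_pos / n_test)

    def test_too_few_positives(self):
        df, labels = _separable_cohort()
        labels[:] = "HC"
        labels.iloc[0] = "DIS"
        with pytest.raises(ValueError, match=">= 2 scans per class"):
            classify_disease_binary(df, labels, config=FAST, seed=0)

    def test_permutation_null_ap(self):
        """Permuted labels on null data: AP inside the null central 90%.

        A single draw lands outside the central 90% band 10% of the time by
        construction, so the check is repeated over seeds.
        """
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(42)
        hits = 0
        for seed in range(5):
            df, _ = simulate_edge_cohort({"HC": 30, "DIS": 30}, n_rois=15,
                                         signatures=None, effect_size=0.0,
                                         seed=7 + seed)
            labels = pd.Series(
                rng.permutation(["HC"] * 30 + ["DIS"] * 30), index=df.index
            )
            report = classify_disease_binary(df, labels, config=FAST, seed=seed)
            y_test = (labels.loc[report.test_scan_ids] != "HC").to_numpy(int)
            # permutation null: shuffle test labels against the fitted scores
            null = [
                average_precision_score(rng.permutation(y_test), report.test_scores)
                for _ in range(1000)
            ]
            lo, hi = np.percentile(null, [5, 95])
            hits += lo <= report.ap <= hi
        assert hits >= 3  # P(<3 | per-seed rate 0.9) ~ 8e-3

    def test_power_with_injected_signal(self):
        rng = np.random.default_rng(0)
        sig = roi_edge_signature(20, [0, 1, 2, 3, 4], edges_per_roi=10, rng=rng)
        wins = 0
        for seed in range(10):
            df, labels = simulate_edge_cohort(
                {"HC": 30, "DIS": 30}, n_rois=20, signatures={"DIS": sig},
                effect_size=3.0, seed=100 + seed,
            )
            report = classify_disease_binary(df, labels, config=FAST, seed=seed)
            wins += report.ap > report.ap_chance
        assert wins >= 9

    def test_leakage_audit(self):
        """Perturbing test rows leaves all train-derived quantities unchanged."""
        df, labels = _separable_cohort(seed=1)
        r1 = classify_disease_binary(df, labels, config=FAST, seed=2)
        df2 = df.copy()
        rng = np.random.default_rng(9)
        df2.loc[r1.test_scan_ids] += rng.normal(0, 0.5, size=(len(r1.test_scan_ids), df.shape[1]))
        r2 = classify_disease_binary(df2, labels, config=FAST, seed=2)
        assert r1.selected_lambda == r2.selected_lambda
        pd.testing.assert_series_equal(r1.coefficients, r2.coefficients)


class TestMulticlass:
    def test_separable_groups(self):
        rng = np.random.default_rng(1)
        rows, labels, ids = [], [], []
        for g in range(5):
            for i in range(8):
                v = np.zeros(50)
                v[g * 10:(g + 1) * 10] = rng.uniform(2, 3, 10)
                rows.append(v + 0.01 * rng.normal(size=50))
                labels.append(f"G{g}")
                ids.append(f"g{g}s{i}")
        df = pd.DataFrame(rows, index=ids)
        df.columns = [f"e{k}" for k in range(50)]
        report = classify_multiclass(df, pd.Series(labels, index=ids), config=FAST, seed=0)
        assert report.balanced_accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2)
        df, labels = simulate_edge_cohort(
            {f"G{g}": 12 for g in range(5)}, n_rois=12, signatures=None,
            effect_size=0.0, seed=3,
        )
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        report = classify_multiclass(df, shuffled, config=FAST, seed=1)
        assert report.balanced_accuracy < 0.55  # chance is 0.2

    def test_confusion_rows_sum_to_test_group_sizes(self):
        df, labels = simulate_edge_cohort(
            {"A": 10, "B": 10, "C": 10}, n_rois=10, signatures=None, effect_size=0.0, seed=4
        )
        report = classify_multiclass(df, labels, config=FAST, seed=0)
        test_labels = labels.loc[report.test_scan_ids]
        for g in ("A", "B", "C"):
            assert report.confusion.loc[g].sum() == (test_labels == g).sum()


class TestCovariatePrediction:
    def test_injected_batch_effect_detectable(self):
        rng = np.random.default_rng(5)
        n = 60
        ids = [f"s{i}" for i in range(n)]
        batch = np.array(["b0"] * (n // 2) + ["b1"] * (n // 2))
        base = rng.normal(1.0, 0.3, size=300)
        rows = []
        for i in range(n):
            scale = 1.1 if batch[i] == "b1" else 1.0  # 10% multiplicative batch effect
            rows.append(base * scale + 0.03 * rng.normal(size=300))
        df = pd.DataFrame(rows, index=ids, columns=[f"e{k}" for k in range(300)])
        cov = pd.DataFrame(
            {
                "batch": batch,
                "sex": rng.choice(["M", "F"], n),
                "genotype": rng.choice(["HAB", "MAB"], n),
                "age": rng.uniform(20, 70, n),
                "dw": rng.uniform(2, 6, n),
            },
            index=ids,
        )
        report = predict_covariate(df, cov, "batch", config=FAST, seed=0, models=["KNN"])
        assert report.balanced_accuracy > 0.9

    def test_null_sex_effect_near_chance(self):
        rng = np.random.default_rng(6)
        n = 60
        ids = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(rng.normal(size=(n, 100)), index=ids,
                          columns=[f"e{k}" for k in range(100)])
        cov = pd.DataFrame(
            {
                "batch": rng.choice(["b0", "b1"], n),
                "sex": ["M"] * (n // 2) + ["F"] * (n // 2),
                "genotype": rng.choice(["HAB", "MAB"], n),
                "age": rng.uniform(20, 70, n),
                "dw": rng.uniform(2, 6, n),
            },
            index=ids,
        )
        report = predict_covariate(df, cov, "sex", config=FAST, seed=0, models=["KNN"])
        assert 0.2 <= report.balanced_accuracy <= 0.8

    def test_single_class_target_errors(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"s{i}" for i in range(10)])
        cov = pd.DataFrame({"sex": ["M"] * 10}, index=df.index)
        with pytest.raises(ValueError, match="single class"):
            predict_covariate(df, cov, "sex", config=FAST, seed=0)


class TestRegionalImportance:
    def test_three_roi_example(self):
        # edges in canonical order: AB, AC, BC
        score = regional_importance([0.5, -0.25, 0.0], ["A", "B", "C"])
        assert score["A"] == pytest.approx(0.75)
        assert score["B"] == pytest.approx(0.5)
        assert score["C"] == pytest.approx(0.25)

    def test_all_zero(self):
        score = regional_importance(np.zeros(6), ["A", "B", "C", "D"])
        assert np.all(score.to_numpy() == 0.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(8)
        beta = rng.normal(size=87 * 86 // 2)
        score = regional_importance(beta, [f"r{i}" for i in range(87)])
        assert score.sum() == pytest.approx(2.0 * np.abs(beta).sum(), abs=1e-12)

    def test_wrong_length(self):
        with pytest.raises(ValueError, match="does not match"):
            regional_importance([1.0, 2.0], ["A", "B", "C"])


class TestCoefficientOverlap:
    def test_identity_tau_one(self):
        rng = np.random.default_rng(9)
        b = rng.normal(size=100)
        tau, _ = coefficient_overlap(b, b)
        assert tau == pytest.approx(1.0)

    def test_negation_tau_minus_one(self):
        rng = np.random.default_rng(10)
        b = rng.normal(size=100)
        tau, _ = coefficient_overlap(b, -b)
        assert tau == pytest.approx(-1.0)

    def test_spearman_variant(self):
        rng = np.random.default_rng(11)
        b = rng.normal(size=50)
        rho, _ = coefficient_overlap(b, b, method="spearman")
        assert rho == pytest.approx(1.0)

    def test_independent_sparse_near_zero(self):
        rng = np.random.default_rng(12)
        small = 0
        for _ in range(20):
            b1 = np.zeros(3741)
            b2 = np.zeros(3741)
            nz = int(0.05 * 3741)
            b1[rng.choice(3741, nz, replace=False)] = rng.normal(size=nz)
            b2[rng.choice(3741, nz, replace=False)] = rng.normal(size=nz)
            tau, _ = coefficient_overlap(b1, b2)
            small += abs(tau) < 0.05
        assert small >= 18

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            coefficient_overlap([1, 2], [1, 2], method="pearson")


class TestFingerprint:
    def test_duplicated_groups_perfect(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=50), rng.normal(size=50)
        rows = [a, a, a, b, b, b]
        ids = [f"s{i}" for i in range(6)]
        df = pd.DataFrame(rows, index=ids)
        df.columns = [f"e{k}" for k in range(50)]
        df += 0.001 * rng.normal(size=df.shape)  # break exact self-ties
        diag = pd.Series(["X", "X", "X", "Y", "Y", "Y"], index=ids)
        fp = patient_fingerprint(df, diag)
        assert fp.balanced_accuracy == 1.0
        assert np.all(fp.recall.to_numpy() == 1.0)

    def test_confusion_rows_sum_to_group_sizes(self):
        df, labels = simulate_edge_cohort(
            {"A": 7, "B": 5, "C": 9}, n_rois=12, signatures=None, effect_size=0.0, seed=5
        )
        fp = patient_fingerprint(df, labels)
        for g, n in (("A", 7), ("B", 5), ("C", 9)):
            assert fp.confusion.loc[g].sum() == n
        assert fp.balanced_accuracy == pytest.approx(float(fp.recall.mean()))

    def test_group_signatures_recovered(self):
        rng = np.random.default_rng(14)
        n_rois = 87
        n_edges = n_rois * (n_rois - 1) // 2
        sigs = {}
        all_edges = rng.permutation(n_edges)
        for g in range(5):
            sigs[f"G{g}"] = all_edges[g * 40:(g + 1) * 40]
        df, labels = simulate_edge_cohort(
            {f"G{g}": 10 for g in range(5)}, n_rois=n_rois, signatures=sigs,
            effect_size=3.0, seed=6,
        )
        fp = patient_fingerprint(df, labels)
        assert fp.balanced_accuracy > 0.8

    def test_monotone_transform_invariance(self):
        df, labels = simulate_edge_cohort(
            {"A": 6, "B": 6}, n_rois=10, signatures={"A": np.arange(10)},
            effect_size=2.0, seed=7,
        )
        fp1 = patient_fingerprint(df, labels)
        fp2 = patient_fingerprint(np.tanh(df) * 3 + 1, labels)
        assert fp1.balanced_accuracy == fp2.balanced_accuracy
        pd.testing.assert_series_equal(fp1.assigned, fp2.assigned)

    def test_single_group_errors(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        with pytest.raises(ValueError, match=">= 2 diagnostic groups"):
            patient_fingerprint(df, pd.Series(["X"] * 4, index=df.index))
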