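import numpy as np
import pandas as pd
import pytest

from usradiomics.evaluation import (
    compute_metrics, external_test, make_cv_plan, median_ci, run_nested_cv,
    select_best_model, univariate_feature_stats, wilcoxon_vs_chance,
    export_reports,
)
from usradiomics.modeling import AdasynConfig, EnsembleSpec, fit_ensemble


def toy_table(n_a=40, n_b=24, sep=3.0, seed=0, n_feat=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_a + n_b, n_feat))
    y = np.array(["benign"] * n_a + ["malignant"] * n_b)
    X[y == "malignant"] += sep
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_feat)])
    df.insert(0, "case_id", [f"c{i}" for i in range(len(y))])
    return df, y


class TestCVPlan:
    def test_minimal_plan_8_cases(self):
        y = np.array(["a", "b"] * 4)
        plan = make_cv_plan(y, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sizes == [2, 2, 2, 2]
        tested = sorted(r["test"] for r in plan.rotations)
        assert tested == [0, 1, 2, 3]

    def test_stratification_within_one_case(self):
        y = np.array(["benign"] * 102 + ["malignant"] * 40)
        plan = make_cv_plan(y, seed=1)
        all_idx = np.concatenate(plan.folds)
        assert sorted(all_idx) == list(range(142))
        for fold in plan.folds:
            n_mal = np.sum(y[fold] == "malignant")
            assert abs(n_mal - 10) <= 1
            assert abs(len(fold) - 35.5) <= 1

    def test_rotation_structure(self):
        y = np.array(["a", "b"] * 8)
        plan = make_cv_plan(y, seed=2)
        for r in plan.rotations:
            parts = set(r["train"]) | {r["validation"], r["test"]}
            assert parts == {0, 1, 2, 3}
            assert len(r["train"]) == 2

    def test_seed_sensitivity(self):
        y = np.array(["a", "b"] * 10)
        p1 = make_cv_plan(y, seed=0)
        p2 = make_cv_plan(y, seed=99)
        assert any(not np.array_equal(a, b) for a, b in zip(p1.folds, p2.folds))

    def test_too_small_class_raises(self):
        y = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.raises(ValueError, match="stratify"):
            make_cv_plan(y)


class TestComputeMetrics:
    def test_external_worked_example(self):
        """21 cases: 6 malignant all called malignant, 13 of 15 benign
        called benign -> accuracy 90.5, sensitivity 100, specificity 86.7,
        PPV 75, NPV 100 (positive class = malignant)."""
        y_true = ["malignant"] * 6 + ["benign"] * 15
        y_pred = ["malignant"] * 6 + ["malignant"] * 2 + ["benign"] * 13
        m = compute_metrics(y_true, y_pred, positive_class="malignant")
        assert round(m.values["accuracy"], 1) == 90.5
        assert m.values["sensitivity"] == 100.0
        assert round(m.values["specificity"], 1) == 86.7
        assert m.values["ppv"] == 75.0
        assert m.values["npv"] == 100.0

    def test_benign_positive_orientation_of_same_matrix(self):
        # the same confusion matrix read with benign as the positive class
        y_true = ["malignant"] * 6 + ["benign"] * 15
        y_pred = ["malignant"] * 6 + ["malignant"] * 2 + ["benign"] * 13
        m = compute_metrics(y_true, y_pred, positive_class="benign")
        assert round(m.values["sensitivity"], 1) == 86.7
        assert m.values["specificity"] == 100.0
        assert m.values["ppv"] == 100.0
        assert m.values["npv"] == 75.0

    def test_perfect_prediction_all_100(self):
        y = ["malignant", "benign"] * 5
        m = compute_metrics(y, y, np.tile([1.0, 0.0], 5))
        assert all(v == 100.0 for v in m.values.values())

    def test_constant_scores_auc_50(self):
        y = ["malignant"] * 5 + ["benign"] * 5
        m = compute_metrics(y, y, np.ones(10))
        assert m.values["roc_auc"] == 50.0

    def test_metric_identities_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true = rng.choice(["benign", "malignant"], size=40)
            y_pred = rng.choice(["benign", "malignant"], size=40)
            if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
                continue
            m = compute_metrics(y_true, y_pred).values
            tp = np.sum((y_true == "malignant") & (y_pred == "malignant"))
            tn = np.sum((y_true == "benign") & (y_pred == "benign"))
            assert np.isclose(m["accuracy"], 100 * (tp + tn) / 40)
            # Bayes identity: PPV relates sensitivity to prevalence
            prev = np.mean(y_true == "malignant")
            sens, spec = m["sensitivity"] / 100, m["specificity"] / 100
            expected_ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
            if "ppv" in m and not np.isnan(expected_ppv):
                assert np.isclose(m["ppv"], 100 * expected_ppv, atol=1e-9)

    def test_ci_contains_point_estimate(self):
        y_true = ["malignant"] * 8 + ["benign"] * 12
        y_pred = ["malignant"] * 6 + ["benign"] * 14
        m = compute_metrics(y_true, y_pred, np.linspace(1, 0, 20))
        for k, (lo, hi) in m.ci.items():
            assert lo <= m.values[k] <= hi


class TestWilcoxon:
    def test_six_positive_differences_exact_p(self):
        p = wilcoxon_vs_chance([60, 62, 64, 66, 68, 70], 50)
        assert np.isclose(p, 1 / 64)

    def test_symmetric_about_null_p_near_half(self):
        d = 50 + np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0, -4.0, 4.0])
        p = wilcoxon_vs_chance(d, 50)
        assert 0.3 < p < 0.7

    def test_all_equal_to_null_p_one(self):
        assert wilcoxon_vs_chance([50.0] * 10, 50) == 1.0


@pytest.fixture(scope="module")
def cv_result():
    table, y = toy_table(n_a=40, n_b=24, sep=4.0)
    plan = make_cv_plan(y, seed=0)
    spec = EnsembleSpec(kind="random_forest", trees_per_member=10)
    return run_nested_cv(table, y, spec, plan, AdasynConfig(seed=0), seed=1), y


class TestNestedCV:
    def test_separable_training_metrics_100(self, cv_result):
        res, _ = cv_result
        for r in res.rotations:
            for v in r.metrics["training"].values.values():
                assert v == 100.0

    def test_each_case_tested_exactly_once(self, cv_result):
        res, y = cv_result
        tested = np.concatenate([r.test_index for r in res.rotations])
        assert sorted(tested) == list(range(len(y)))

    def test_member_metrics_64_rows(self, cv_result):
        res, _ = cv_result
        assert res.internal_mean.n == 64

    def test_permuted_labels_auc_near_chance(self):
        """Label permutation destroys the signal: mean internal AUC over
        permutation seeds sits in the chance band."""
        table, y = toy_table(n_a=30, n_b=18, sep=3.0)
        aucs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            plan = make_cv_plan(yp, seed=seed)
            spec = EnsembleSpec(kind="random_forest", trees_per_member=10)
            res = run_nested_cv(table, yp, spec, plan, AdasynConfig(seed=seed),
                                seed=seed)
            aucs.append(res.internal_mean.values["roc_auc"])
        assert 40 < np.mean(aucs) < 60

    def test_leakage_guard_test_fold_cannot_influence_preprocessing(self):
        """Replacing the internal-test fold's feature values changes nothing
        about the fitted preprocessing or the training-fold predictions."""
        table, y = toy_table(n_a=32, n_b=16, sep=3.0, seed=5)
        plan = make_cv_plan(y, seed=3)
        spec = EnsembleSpec(kind="svm_pca_fdr", trees_per_member=5)
        res1 = run_nested_cv(table, y, spec, plan, AdasynConfig(seed=2), seed=7)
        rot = res1.rotations[0]
        tampered = table.copy()
        cols = [c for c in table.columns if c.startswith("f")]
        tampered.loc[rot.test_index, cols] = 999.0
        res2 = run_nested_cv(tampered, y, spec, plan, AdasynConfig(seed=2), seed=7)
        e1, e2 = res1.rotations[0].ensemble, res2.rotations[0].ensemble
        assert np.allclose(e1.scaler.mean_, e2.scaler.mean_)
        assert np.allclose(e1.pca.components_, e2.pca.components_)
        assert np.array_equal(e1.component_order, e2.component_order)
        m1 = res1.rotations[0].metrics["training"].values
        m2 = res2.rotations[0].metrics["training"].values
        assert m1 == m2


class TestModelSelectionAndExternal:
    def test_argmax_and_tiebreak(self):
        from usradiomics.evaluation import MetricSet, NestedCVResult

        def fake(kind, mean_auc, maj_auc):
            return NestedCVResult(
                model_kind=kind, rotations=[],
                internal_mean=MetricSet("internal_mean", {"roc_auc": mean_auc}),
                internal_majority=MetricSet("internal_majority", {"roc_auc": maj_auc}),
                stage_means={},
            )

        res = {"random_forest": fake("random_forest", 84, 85),
               "svm_pca_fdr": fake("svm_pca_fdr", 79, 80),
               "knn_pca_fdr": fake("knn_pca_fdr", 77, 79)}
        assert select_best_model(res) == "random_forest"
        res["svm_pca_fdr"].internal_mean.values["roc_auc"] = 84
        assert select_best_model(res) == "random_forest"  # majority AUC breaks tie
        res["svm_pca_fdr"].internal_majority.values["roc_auc"] = 85
        assert select_best_model(res) == "random_forest"  # model order breaks tie
        assert select_best_model({"knn_pca_fdr": res["knn_pca_fdr"]}) == "knn_pca_fdr"

    def test_reoriented_external_swaps_sensitivity_and_specificity(self):
        from usradiomics.evaluation import reorient_external

        table, y = toy_table(n_a=30, n_b=18, sep=3.0, seed=4)
        plan = make_cv_plan(y, seed=1)
        res = run_nested_cv(table, y, EnsembleSpec(trees_per_member=5), plan,
                            AdasynConfig(seed=0), seed=0)
        ext, y_ext = toy_table(n_a=10, n_b=6, sep=3.0, seed=8)
        m_mal = external_test(res.all_ensembles(), ext, y_ext, "malignant")
        m_ben = reorient_external(res.all_ensembles(), ext, y_ext,
                                  positive_class="benign",
                                  negative_class="malignant")
        assert np.isclose(m_mal.values["sensitivity"], m_ben.values["specificity"])
        assert np.isclose(m_mal.values["specificity"], m_ben.values["sensitivity"])
        assert np.isclose(m_mal.values["accuracy"], m_ben.values["accuracy"])

    def test_external_pooled_vote_and_determinism(self):
        table, y = toy_table(n_a=40, n_b=24, sep=4.0, seed=2)
        plan = make_cv_plan(y, seed=0)
        res = run_nested_cv(table, y, EnsembleSpec(trees_per_member=10), plan,
                            AdasynConfig(seed=0), seed=1)
        ext, y_ext = toy_table(n_a=15, n_b=6, sep=4.0, seed=9)
        m1 = external_test(res.all_ensembles(), ext, y_ext)
        assert set(m1.values) == {"roc_auc", "accuracy", "sensitivity",
                                  "specificity", "ppv", "npv"}
        # duplicated external set -> identical per-case predictions
        ext2 = pd.concat([ext, ext], ignore_index=True)
        m2 = external_test(res.all_ensembles(), ext2, np.concatenate([y_ext, y_ext]))
        assert np.allclose(
            [m1.values[k] for k in sorted(m1.values)],
            [m2.values[k] for k in sorted(m2.values)],
        )


class TestUnivariateStats:
    def test_fully_separated_3v3_exact(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        y = np.array(["benign"] * 3 + ["malignant"] * 3)
        s = univariate_feature_stats(t, y)[0]
        assert s.u_statistic in (0.0, 9.0)  # orientation of U
        assert np.isclose(s.p_raw, 0.1)

    def test_holm_adjustment_values(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.001, 0.01, 0.04], method="holm")[1]
        assert np.allclose(adj, [0.003, 0.02, 0.04])

    def test_stats_fields_and_ordering(self):
        rng = np.random.default_rng(0)
        y = np.array(["benign"] * 30 + ["malignant"] * 20)
        t = pd.DataFrame({
            "strong": (y == "malignant") * 5.0 + rng.normal(size=50),
            "weak": rng.normal(size=50),
        })
        stats_list = univariate_feature_stats(t, y)
        assert stats_list[0].feature == "strong"
        assert stats_list[0].stars == "**"
        for s in stats_list:
            assert s.p_adjusted >= s.p_raw - 1e-15
            lo, hi = s.median_benign_ci
            assert lo <= s.median_benign <= hi

    def test_permuted_labels_star_rate_near_nominal(self):
        """With no true class difference, raw-p rejections at 0.05 stay
        near 5% across many independent features."""
        rng = np.random.default_rng(1)
        y = np.array(["benign"] * 35 + ["malignant"] * 15)
        t = pd.DataFrame({f"f{i}": rng.normal(size=50) for i in range(400)})
        stats_list = univariate_feature_stats(t, y)
        rate = np.mean([s.p_raw < 0.05 for s in stats_list])
        assert 0.01 < rate < 0.10

    def test_constant_feature_p_one(self):
        t = pd.DataFrame({"f": np.ones(20)})
        y = np.array(["benign"] * 12 + ["malignant"] * 8)
        s = univariate_feature_stats(t, y)[0]
        assert s.p_raw == 1.0

    def test_median_ci_order_statistics(self):
        x = np.arange(1, 101, dtype=float)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi
        assert 35 <= lo <= 45 and 55 <= hi <= 65


class TestExportReports:
    def test_report_files_schema(self, tmp_path):
        table, y = toy_table(n_a=24, n_b=16, sep=4.0, seed=3)
        plan = make_cv_plan(y, seed=0)
        results = {}
        for kind in ("random_forest", "knn_pca_fdr"):
            results[kind] = run_nested_cv(
                table, y, EnsembleSpec(kind=kind, trees_per_member=5),
                plan, AdasynConfig(seed=0), seed=2,
            )
        stats_list = univariate_feature_stats(table, y)
        ext_m = compute_metrics(["malignant", "benign"], ["malignant", "benign"],
                                [0.9, 0.1], stage="external")
        out = export_reports(tmp_path, cv_results=results, external=ext_m,
                            best_model="random_forest", univariate=stats_list,
                            table=table, labels=y, manifest={"seed": 0})
        metrics = pd.read_csv(out / "metrics.csv")
        assert set(metrics.columns) >= {"model", "stage", "metric", "value",
                                        "ci_low", "ci_high", "p_value"}
        stages = set(metrics["stage"])
        assert {"training", "validation", "internal_mean",
                "internal_majority", "external"} <= stages
        uni = pd.read_csv(out / "univariate_stats.csv")
        assert {"feature", "median_benign", "median_malignant", "p_raw",
                "p_adjusted"} <= set(uni.columns)
        assert (out / "roc_random_forest.csv").exists()
        assert (out / "feature_values_by_class.csv").exists()
        assert (out / "run_manifest.json").exists()
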