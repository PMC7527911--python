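import numpy as np
import pytest

from voicepd.modeling import (
    ConfusionMatrix,
    FeatureTable,
    classification_metrics,
    feature_significance,
    kfold_split,
    lasso_feature_ranking,
    read_uci_table,
    regression_metrics,
    run_classification,
    run_regression,
)
from voicepd.synth import synth_classification_table, synth_regression_table

PARKINSONS_CSV = """name,{feats},status
rec1,{row1},1
rec2,{row2},1
rec3,{row3},0
"""

TELE_CSV = """subject#,age,sex,test_time,motor_UPDRS,total_UPDRS,{feats}
1,72,0,5.64,28.2,34.4,{row1}
1,72,0,12.66,28.4,34.9,{row2}
2,58,1,19.68,20.0,25.0,{row3}
"""


def _toy_csv(tmp_path, template, n_feats=22):
    rng = np.random.default_rng(0)
    feats = ",".join(f"f{i}" for i in range(n_feats))
    rows = [",".join(f"{v:.4f}" for v in rng.uniform(size=n_feats)) for _ in range(3)]
    p = tmp_path / "toy.csv"
    p.write_text(template.format(feats=feats, row1=rows[0], row2=rows[1], row3=rows[2]))
    return p


class TestReadUciTable:
    def test_parkinsons_dialect(self, tmp_path):
        table = read_uci_table(_toy_csv(tmp_path, PARKINSONS_CSV), "parkinsons")
        assert table.n == 3
        assert len(table.feature_names) == 22
        assert set(table.y) == {0.0, 1.0}
        assert list(table.groups) == ["rec1", "rec2", "rec3"]

    def test_telemonitoring_dialect(self, tmp_path):
        table = read_uci_table(_toy_csv(tmp_path, TELE_CSV, 16), "telemonitoring")
        assert len(table.feature_names) == 16
        np.testing.assert_allclose(table.y, [34.4, 34.9, 25.0])
        assert {"age", "sex"} <= set(table.meta.columns)
        table_m = read_uci_table(
            _toy_csv(tmp_path, TELE_CSV, 16), "telemonitoring", target="motor_UPDRS"
        )
        np.testing.assert_allclose(table_m.y, [28.2, 28.4, 20.0])

    def test_missing_status_column_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,f0,f1\nrec1,0.1,0.2\n")
        with pytest.raises(ValueError, match="status"):
            read_uci_table(p, "parkinsons")


class TestKFold:
    def test_fold_sizes_195(self):
        folds = kfold_split(195, 5, seed=1)
        assert all(len(va) == 39 for _, va in folds)

    def test_remainder_distribution(self):
        sizes = sorted(len(va) for _, va in kfold_split(7, 5, seed=1))
        assert sizes == [1, 1, 1, 2, 2]

    def test_partition_properties(self):
        folds = kfold_split(53, 5, seed=3)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(53))
        for tr, va in folds:
            assert set(tr) & set(va) == set()
            assert sorted(np.concatenate([tr, va])) == list(range(53))

    def test_seed_determinism(self):
        a = kfold_split(100, 5, seed=9)
        b = kfold_split(100, 5, seed=9)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5)


class TestClassificationMetrics:
    def test_hand_example(self):
        acc, prec, rec, f1 = classification_metrics(ConfusionMatrix(90, 10, 5, 95))
        assert acc == pytest.approx(92.5)
        assert prec == pytest.approx(94.7368, abs=1e-3)
        assert rec == pytest.approx(90.0)
        assert f1 == pytest.approx(92.3077, abs=1e-3)

    def test_perfect_classifier(self):
        assert classification_metrics(ConfusionMatrix(10, 0, 0, 10)) == (100, 100, 100, 100)

    def test_degenerate_conventions(self):
        acc, prec, rec, f1 = classification_metrics(ConfusionMatrix(0, 10, 0, 90))
        assert (prec, rec, f1) == (0.0, 0.0, 0.0)
        assert acc == pytest.approx(90.0)


class TestRegressionMetrics:
    def test_identity(self):
        assert regression_metrics([1, 2, 3], [1, 2, 3]) == (0, 0, 0)

    def test_unit_offset(self):
        assert regression_metrics([1, 2, 3], [2, 3, 4]) == (1, 1, 1)

    def test_hand_example(self):
        mae, mse, rmse = regression_metrics([1, 2, 3], [3, 2, 1])
        assert mae == pytest.approx(4 / 3)
        assert mse == pytest.approx(8 / 3)
        assert rmse == pytest.approx(np.sqrt(8 / 3))

    def test_jensen_relations_on_random_inputs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            mae, mse, rmse = regression_metrics(rng.normal(size=n), rng.normal(size=n))
            assert rmse**2 == pytest.approx(mse, rel=1e-9)
            assert mae <= rmse + 1e-12


class TestRunClassification:
    def test_separated_gaussians_high_accuracy(self):
        table, _ = synth_classification_table(100, 22, separation=4.0, seed=0)
        rep = run_classification(table, "svm", 5, seed=0)
        assert rep.accuracy >= 95.0

    def test_permuted_labels_chance_level(self):
        accs = []
        for seed in range(20):
            table, _ = synth_classification_table(50, 10, separation=4.0, seed=seed)
            rng = np.random.default_rng(seed)
            table.y = rng.permutation(table.y)
            accs.append(run_classification(table, "svm", 5, seed=seed).accuracy)
        assert 40.0 <= np.mean(accs) <= 60.0

    @pytest.mark.parametrize("algo", ["svm", "logreg", "nn1", "nn2", "gnb"])
    def test_perfectly_separable_single_feature(self, algo):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.uniform(-2, -1, 100), rng.uniform(1, 2, 100)])[:, None]
        y = np.concatenate([np.zeros(100), np.ones(100)])
        table = FeatureTable(["only"], x, y)
        rep = run_classification(table, algo, 5, seed=0)
        assert rep.accuracy == 100.0

    def test_single_class_rejected(self):
        table = FeatureTable(["a"], np.zeros((10, 1)), np.ones(10))
        with pytest.raises(ValueError):
            run_classification(table, "svm")

    def test_pooled_metrics_match_per_fold_recomputation(self):
        table, _ = synth_classification_table(60, 8, separation=2.0, seed=5)
        rep = run_classification(table, "gnb", 5, seed=5)
        tp = sum(cm.tp for cm in rep.per_fold)
        fn = sum(cm.fn for cm in rep.per_fold)
        fp = sum(cm.fp for cm in rep.per_fold)
        tn = sum(cm.tn for cm in rep.per_fold)
        acc, prec, rec, f1 = classification_metrics(ConfusionMatrix(tp, fn, fp, tn))
        assert rep.accuracy == pytest.approx(acc)
        assert rep.f1 == pytest.approx(f1)

    def test_determinism(self):
        table, _ = synth_classification_table(50, 10, separation=2.0, seed=2)
        a = run_classification(table, "svm", 5, seed=3)
        b = run_classification(table, "svm", 5, seed=3)
        assert a.to_dict() == b.to_dict()


class TestRunRegression:
    def test_noiseless_linear_system_interpolated(self):
        table, truth = synth_regression_table(300, 10, support=10, noise_sd=0.0, seed=0)
        rep = run_regression(table, "linear", seed=0)
        assert rep.mae < 1e-8

    def test_svr_error_tracks_noise_scale(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((1000, 8))
        w = rng.uniform(1, 2, 8)
        y = X @ w + rng.normal(0, 2.0, 1000)
        table = FeatureTable([f"f{i}" for i in range(8)], X, y)
        rep = run_regression(table, "svr", seed=4)
        assert 1.2 <= rep.mae <= 2.0

    def test_report_invariants(self):
        table, _ = synth_regression_table(200, 10, support=5, noise_sd=1.0, seed=1)
        rep = run_regression(table, "lasso", seed=1)
        assert rep.rmse == pytest.approx(np.sqrt(rep.mse), rel=1e-9)
        assert rep.mae <= rep.rmse + 1e-9

    def test_determinism(self):
        table, _ = synth_regression_table(200, 10, support=5, noise_sd=1.0, seed=2)
        assert run_regression(table, "svr", seed=7).to_dict() == run_regression(
            table, "svr", seed=7
        ).to_dict()


class TestStandardizationLeakage:
    def test_validation_outlier_does_not_change_training_statistics(self, monkeypatch):
        """Fit statistics must come from the training fold only."""
        from sklearn.preprocessing import StandardScaler

        table, _ = synth_classification_table(30, 4, separation=2.0, seed=0)
        seen_means = []
        orig_fit = StandardScaler.fit

        def spy(self, X, y=None):
            seen_means.append(X.mean(axis=0))
            return orig_fit(self, X, y)

        monkeypatch.setattr(StandardScaler, "fit", spy)
        run_classification(table, "gnb", 5, seed=0)
        base = [m.copy() for m in seen_means]
        seen_means.clear()

        # inject a huge outlier; folds with it in validation must be unaffected
        folds = kfold_split(table.n, 5, seed=0)
        outlier_idx = folds[0][1][0]  # lands in fold 0's validation split
        table.X[outlier_idx] += 1e6
        run_classification(table, "gnb", 5, seed=0)
        np.testing.assert_allclose(seen_means[0], base[0])


class TestLassoRanking:
    def test_recovers_planted_sparse_support_with_signs(self):
        table, truth = synth_regression_table(500, 20, support=5, noise_sd=0.5, seed=3)
        ranking = lasso_feature_ranking(table, seed=3)
        top5 = {name for name, _ in ranking[:5]}
        expected = {table.feature_names[i] for i in truth["support"]}
        assert top5 == expected
        name_to_idx = {n: i for i, n in enumerate(table.feature_names)}
        for name, w in ranking[:5]:
            assert np.sign(w) == np.sign(truth["w"][name_to_idx[name]])

    def test_null_target_near_empty_ranking(self, rng):
        X = rng.standard_normal((300, 15))
        y = rng.standard_normal(300)
        table = FeatureTable([f"f{i}" for i in range(15)], X, y)
        try:
            ranking = lasso_feature_ranking(table, seed=0)
            weights = np.array([abs(w) for _, w in ranking])
            assert np.all(weights < 0.15)
        except ValueError:
            pass  # fully empty ranking is also acceptable for a null model

    def test_collinear_duplicate_gets_single_weight(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 5))
        X = np.column_stack([X, X[:, 0]])  # duplicate column
        y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(400)
        table = FeatureTable([f"f{i}" for i in range(6)], X, y)
        ranking = dict(lasso_feature_ranking(table, seed=0))
        pair = sorted(abs(ranking.get(f, 0.0)) for f in ("f0", "f5"))
        assert pair[0] < 0.2 * max(pair[1], 1e-9) or pair[1] == 0


class TestFeatureSignificance:
    def test_large_shift_tiny_p(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 1)), rng.normal(5, 1, (50, 1))])
        y = np.repeat([0.0, 1.0], 50)
        (_, _, p), = feature_significance(FeatureTable(["f"], X, y))
        assert p < 1e-6

    def test_null_features_type_one_error_calibrated(self, rng):
        X = rng.standard_normal((100, 1000))
        y = np.repeat([0.0, 1.0], 50)
        results = feature_significance(FeatureTable([f"f{i}" for i in range(1000)], X, y))
        frac = np.mean([p < 0.05 for _, _, p in results])
        assert 0.03 <= frac <= 0.07

    def test_constant_feature_p_one(self):
        X = np.ones((20, 1))
        y = np.repeat([0.0, 1.0], 10)
        (_, _, p), = feature_significance(FeatureTable(["const"], X, y))
        assert p == 1.0

    def test_bh_correction_monotone(self, rng):
        X = rng.standard_normal((60, 20))
        X[:30, 0] += 3.0
        y = np.concatenate([np.ones(30), np.zeros(30)])
        raw = feature_significance(FeatureTable([f"f{i}" for i in range(20)], X, y))
        adj = feature_significance(
            FeatureTable([f"f{i}" for i in range(20)], X, y), correct=True
        )
        for (_, _, p), (_, _, q) in zip(raw, adj):
            assert q >= p - 1e-12
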