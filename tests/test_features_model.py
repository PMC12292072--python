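"""Feature assembly, standardisation and the SVM-RBF classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from trimciv import features_model as fm
from trimciv.family_db import FALSE, TRUE


def blob_records(n=60, gap=6.0, seed=0, cancers=("AAA", "BBB")):
    """Two well-separated Gaussian classes in the numeric features."""
    rng = np.random.default_rng(seed)
    half = n // 2
    return pd.DataFrame(
        {
            "trim": [f"TR{i}" for i in range(n)],
            "target": [f"TG{i}" for i in range(n)],
            "cancer": [cancers[i % len(cancers)] for i in range(n)],
            "logFC": np.r_[rng.normal(0, 1, half), rng.normal(gap, 1, half)],
            "R": np.r_[rng.normal(0, 0.1, half), rng.normal(0.5, 0.1, half)],
            "zrank_score": rng.uniform(-90, 0, n),
            "label": [FALSE] * half + [TRUE] * half,
        }
    )


class TestBuildFeatures:
    @pytest.fixture
    def fixture_tables(self):
        # ten pairs, one cancer; six survive the three-way evidence join,
        # each dropped pair failing exactly one filter
        pairs = pd.DataFrame(
            {
                "trim": [f"T{i}" for i in range(10)],
                "target": [f"G{i}" for i in range(10)],
                "label": [TRUE] * 5 + [FALSE] * 5,
            }
        )
        de = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(9)],  # G9 absent: no_de (T9)
                "cancer": "C1",
                "logFC": 2.0,
                "is_deg": [True] * 8 + [False],  # G8 fails DEG filter (T8)
            }
        )
        corr = pd.DataFrame(
            {
                "trim": [f"T{i}" for i in range(8)],
                "gene": [f"G{i}" for i in range(8)],
                "cancer": "C1",
                "rho": 0.7,
                "significant": [True] * 7 + [False],  # T7 not significant
            }
        )
        dock = pd.DataFrame(
            {
                "trim": [f"T{i}" for i in range(10) if i != 6],  # T6: no_docking
                "target": [f"G{i}" for i in range(10) if i != 6],
                "zrank_score": -40.0,
            }
        )
        return de, corr, dock, pairs

    def test_designed_survivor_set(self, fixture_tables):
        de, corr, dock, pairs = fixture_tables
        records, losses = fm.build_features(de, corr, dock, pairs, "MS")
        assert sorted(records["trim"]) == [f"T{i}" for i in range(6)]
        assert losses == {
            "no_de": 1, "not_deg": 1, "no_correlation": 0,
            "not_significant": 1, "no_docking": 1,
        }

    def test_unmeasured_correlation_counted(self, fixture_tables):
        de, corr, dock, pairs = fixture_tables
        records, losses = fm.build_features(de, corr.iloc[1:], dock, pairs, "MS")
        assert losses["no_correlation"] == 1  # T0's pair lost its row
        assert "T0" not in set(records["trim"])

    def test_pair_present_everywhere_survives(self, fixture_tables):
        de, corr, dock, pairs = fixture_tables
        records, _ = fm.build_features(de, corr, dock, pairs.iloc[:1], "MS")
        assert len(records) == 1
        row = records.iloc[0]
        assert (row["logFC"], row["R"], row["zrank_score"]) == (2.0, 0.7, -40.0)


class TestStandardize:
    def test_fit_transform_zero_mean_unit_sd(self):
        rec = blob_records()
        X, stats_ = fm.standardize(rec)
        num = X[:, :3]
        assert np.allclose(num.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(num.std(axis=0), 1, atol=1e-10)

    def test_onehot_columns_sum_to_one(self):
        rec = blob_records()
        X, stats_ = fm.standardize(rec)
        onehot = X[:, 3:]
        assert onehot.shape[1] == 2
        assert np.allclose(onehot.sum(axis=1), 1.0)

    def test_stored_stats_applied_verbatim(self):
        rec = blob_records(seed=1)
        _, stats_ = fm.standardize(rec)
        other = blob_records(seed=2)
        X, _ = fm.standardize(other, fit_stats=stats_)
        expected = (other["logFC"].values - stats_.means[0]) / stats_.scales[0]
        assert np.allclose(X[:, 0], expected)

    def test_zero_variance_feature_named(self):
        rec = blob_records()
        rec["zrank_score"] = -40.0
        with pytest.raises(ValueError, match="zrank_score"):
            fm.standardize(rec)

    def test_unseen_disease_rejected(self):
        rec = blob_records()
        _, stats_ = fm.standardize(rec)
        other = blob_records()
        other.loc[0, "cancer"] = "ZZZ"
        with pytest.raises(ValueError, match="ZZZ"):
            fm.standardize(other, fit_stats=stats_)


class TestRbfKernel:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=5)
            assert fm.rbf_kernel(x, x, gamma=rng.uniform(0.01, 10)) == pytest.approx(1.0)

    def test_unit_distance_closed_form(self):
        assert fm.rbf_kernel([0, 0], [1, 0], gamma=1.0) == pytest.approx(np.exp(-1))

    def test_small_gamma_limit(self):
        assert fm.rbf_kernel([0, 0], [5, 5], gamma=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fm.rbf_kernel([1, 2], [1, 2, 3], gamma=1.0)


class TestTrain:
    def test_separable_blobs_high_training_accuracy(self):
        rec = blob_records(n=100)
        bundle = fm.train(rec, fm.HyperParams(1, 1))
        pred = fm.predict(bundle, rec)
        acc = (pred["predicted"] == rec["label"]).mean()
        assert acc >= 0.99

    def test_duplicated_dataset_same_boundary(self):
        rec = blob_records(n=60)
        doubled = pd.concat([rec, rec], ignore_index=True)
        b1 = fm.train(rec, fm.HyperParams(1, 1))
        b2 = fm.train(doubled, fm.HyperParams(1, 1))
        s1 = fm.predict(b1, rec)["score"].values
        s2 = fm.predict(b2, rec)["score"].values
        assert np.allclose(s1, s2, atol=1e-8)

    def test_single_class_rejected(self):
        rec = blob_records()
        rec["label"] = TRUE
        with pytest.raises(ValueError):
            fm.train(rec, fm.HyperParams())

    def test_decision_function_matches_sklearn(self):
        rec = blob_records(n=80, gap=2.0, seed=3)
        bundle = fm.train(rec, fm.HyperParams(1, 1))
        X, _ = fm.standardize(rec, fit_stats=bundle.stats)
        svc = SVC(C=1, gamma=1).fit(X, (rec["label"] == TRUE).astype(int))
        assert np.allclose(bundle.decision_function(X), svc.decision_function(X), atol=1e-10)


class TestPredict:
    def test_true_centroid_predicted_true(self):
        rec = blob_records(n=100, gap=8.0)
        bundle = fm.train(rec, fm.HyperParams(1, 1))
        centroid = rec[rec["label"] == TRUE].iloc[:1].copy()
        for col in ("logFC", "R", "zrank_score"):
            centroid[col] = rec.loc[rec["label"] == TRUE, col].mean()
        assert fm.predict(bundle, centroid)["predicted"].iloc[0] == TRUE

    def test_unknown_cancer_code_rejected(self):
        rec = blob_records()
        bundle = fm.train(rec, fm.HyperParams(1, 1))
        bad = rec.iloc[:1].copy()
        bad["cancer"] = "XXX"
        with pytest.raises(ValueError, match="XXX"):
            fm.predict(bundle, bad)


class TestSerialization:
    def test_roundtrip_preserves_decision_scores(self, tmp_path):
        rec = blob_records(n=80, gap=2.0)
        bundle = fm.train(rec, fm.HyperParams(2.0, 0.5), layer="RNASEQ",
                          metadata={"seed": 3})
        path = tmp_path / "model.json"
        bundle.save(path)
        back = fm.ModelBundle.load(path)
        X, _ = fm.standardize(rec, fit_stats=bundle.stats)
        assert np.allclose(bundle.decision_function(X), back.decision_function(X), atol=1e-10)
        assert back.layer == "RNASEQ" and back.metadata == {"seed": 3}

    def test_newer_schema_fails_loudly(self, tmp_path):
        rec = blob_records()
        bundle = fm.train(rec, fm.HyperParams(1, 1))
        path = tmp_path / "model.json"
        bundle.save(path)
        doc = path.read_text().replace('"schema": 1', '"schema": 99')
        path.write_text(doc)
        with pytest.raises(ValueError, match="schema"):
            fm.ModelBundle.load(path)


class TestCrossValidation:
    def test_fixed_seed_reproduces_folds_and_scores(self):
        rec = blob_records(n=60, gap=2.0)
        f1 = fm.cross_val_scores(rec, fm.HyperParams(1, 1), seed=5)
        f2 = fm.cross_val_scores(rec, fm.HyperParams(1, 1), seed=5)
        for (s1, y1), (s2, y2) in zip(f1, f2):
            assert np.array_equal(s1, s2) and np.array_equal(y1, y2)

    def test_no_leakage_fold_recomputation(self):
        # recompute each fold by hand: scaler fit on the training split
        # only must reproduce the returned held-out scores exactly
        rec = blob_records(n=60, gap=2.0, seed=4)
        seed = 9
        folds = fm.cross_val_scores(rec, fm.HyperParams(1, 1), seed=seed)
        y = (rec["label"] == TRUE).astype(int).values
        X_raw = rec[["logFC", "R", "zrank_score"]].values
        onehot = pd.get_dummies(rec["cancer"]).values.astype(float)
        skf = StratifiedKFold(5, shuffle=True, random_state=seed)
        for (scores, labels), (tr, te) in zip(folds, skf.split(X_raw, y)):
            sc = StandardScaler().fit(X_raw[tr])
            Xtr = np.hstack([sc.transform(X_raw[tr]), onehot[tr]])
            Xte = np.hstack([sc.transform(X_raw[te]), onehot[te]])
            svc = SVC(C=1, gamma=1).fit(Xtr, y[tr])
            assert np.allclose(scores, svc.decision_function(Xte), atol=1e-10)
            assert np.array_equal(labels, y[te])


class TestGridSearch:
    def test_trivial_grid_returns_the_only_cell(self):
        rec = blob_records(n=60)
        best, grid = fm.grid_search_cv(rec, C_grid=[1.0], gamma_grid=[1.0])
        assert (best.C, best.gamma) == (1.0, 1.0)
        assert len(grid) == 1

    def test_nonlinear_structure_selects_larger_gamma(self):
        # XOR-style layout: linearly inseparable, so the near-linear
        # (tiny gamma) kernel cannot beat the local one
        rng = np.random.default_rng(6)
        n = 120
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        rec = pd.DataFrame(
            {
                "trim": [f"T{i}" for i in range(n)],
                "target": [f"G{i}" for i in range(n)],
                "cancer": "AAA",
                "logFC": a * 4.0 + rng.normal(0, 0.3, n),
                "R": b * 0.5 + rng.normal(0, 0.05, n),
                "zrank_score": rng.uniform(-90, 0, n),
                "label": np.where(a == b, TRUE, FALSE),
            }
        )
        best, _ = fm.grid_search_cv(rec, C_grid=[1.0], gamma_grid=[1e-4, 1.0], seed=0)
        assert best.gamma == 1.0

    def test_deterministic_given_seed(self):
        rec = blob_records(n=60, gap=2.0)
        _, g1 = fm.grid_search_cv(rec, C_grid=[0.5, 1], gamma_grid=[0.5, 1], seed=3)
        _, g2 = fm.grid_search_cv(rec, C_grid=[0.5, 1], gamma_grid=[0.5, 1], seed=3)
        pd.testing.assert_frame_equal(g1, g2)

    def test_class_smaller_than_folds_rejected(self):
        rec = blob_records(n=8)
        with pytest.raises(ValueError):
            fm.grid_search_cv(rec, C_grid=[1.0], gamma_grid=[1.0], n_folds=5)
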