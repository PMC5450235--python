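"""The probabilistic targeting SVM: fitting, prediction, CV, persistence."""

import json

import numpy as np
import pytest

from tapredict import (
    CLASS_ORDER,
    TargetingModel,
    TargetingResults,
    loocv_misclassifications,
)
from tapredict.synthesis import ClassSpec, synth_feature_dataset


def make_model(df, **kwargs):
    return TargetingModel.from_dataframe(df, **kwargs)


class TestTrain:
    def test_separable_blobs_fit_perfectly(self, separable_results):
        assert separable_results.in_sample_misclassifications() == 0

    def test_class_with_single_example_rejected(self):
        X = [[6, 1.7], [6.1, 1.6], [1, 1.2], [0.9, 1.3], [0.2, 2.8]]
        y = ["PO", "PO", "MITO", "MITO", "ER"]
        with pytest.raises(ValueError, match="< 2"):
            TargetingModel(X, y)

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            TargetingModel([[1, 2], [2, 3]], ["PO", "PO"])

    def test_zero_variance_feature_rejected(self):
        X = [[5, 2.0], [5, 2.1], [5, 1.0], [5, 1.1]]
        with pytest.raises(ValueError, match="zero-variance"):
            TargetingModel(X, ["PO", "PO", "MITO", "MITO"]).fit()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            TargetingModel([[1, 2], [2, 3]], ["PO", "GOLGI"])

    def test_same_seed_gives_byte_identical_model_files(self, separable_blobs, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        make_model(separable_blobs, seed=5).fit().save(p1)
        make_model(separable_blobs, seed=5).fit().save(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPredictProba:
    def test_rows_sum_to_one(self, separable_results, rng):
        X = np.column_stack([rng.uniform(-5, 15, 200), rng.uniform(0, 4, 200)])
        proba = separable_results.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()

    def test_class_centroid_gets_majority_probability(self, separable_results):
        for point, cls in [((6.03, 1.7), "PO"), ((1.12, 1.2), "MITO"), ((0.21, 2.8), "ER")]:
            proba = separable_results.predict_proba([point])[0]
            assert proba[CLASS_ORDER.index(cls)] > 0.5

    def test_non_finite_input_rejected(self, separable_results):
        with pytest.raises(ValueError):
            separable_results.predict_proba([[np.nan, 1.0]])

    def test_prediction_result_argmax_and_fields(self, separable_results):
        res = separable_results.predict([[6.03, 1.7]], ids=["q"])[0]
        assert res.id == "q"
        assert res.predicted == "PO"
        assert res.p_PO + res.p_MITO + res.p_ER == pytest.approx(1.0, abs=1e-9)

    def test_ambiguity_note_near_boundary(self, separable_results):
        # scan a transect between the PO and MITO centroids for a point
        # where the top-two probabilities nearly tie
        notes = []
        for w in np.linspace(0, 1, 101):
            x = (1 - w) * np.array([6.03, 1.7]) + w * np.array([1.12, 1.2])
            notes.append(separable_results.predict([x])[0].margin_note)
        assert any(n is not None for n in notes)

    def test_standardization_equivariance(self, separable_blobs):
        base = make_model(separable_blobs).fit()
        df2 = separable_blobs.copy()
        df2["tail_charge"] = df2["tail_charge"] * 3.0 - 7.0
        df2["tmd_gravy"] = df2["tmd_gravy"] * 0.25 + 2.0
        mapped = make_model(df2).fit()
        X = np.column_stack(
            [np.linspace(-4, 12, 25), np.linspace(0.5, 3.5, 25)]
        )
        X2 = np.column_stack([X[:, 0] * 3.0 - 7.0, X[:, 1] * 0.25 + 2.0])
        assert np.allclose(
            base.predict_proba(X), mapped.predict_proba(X2), atol=1e-9
        )


class TestInSample:
    def test_permuted_labels_err_near_chance(self, separable_blobs, rng):
        # with labels shuffled, accuracy should hover around 1/3
        rates = []
        for seed in range(5):
            df = separable_blobs.copy()
            df["label"] = rng.permutation(df["label"].to_numpy())
            counts = df["label"].value_counts()
            if counts.min() < 2:
                continue
            results = make_model(df, seed=seed).fit()
            rates.append(results.in_sample_misclassifications() / len(df))
        assert np.mean(rates) > 0.25  # far from separable behaviour


class TestLoocv:
    def test_separable_blobs_have_zero_loocv_error(self, separable_blobs):
        assert make_model(separable_blobs).loocv_misclassifications() == 0

    def test_functional_wrapper_matches(self, separable_blobs):
        X = separable_blobs[["tail_charge", "tmd_gravy"]].to_numpy()
        y = separable_blobs["label"].to_numpy()
        assert loocv_misclassifications(X, y) == 0

    def test_one_example_per_class_is_error(self):
        with pytest.raises(ValueError):
            TargetingModel(
                [[6, 1.7], [1, 1.2], [0.2, 2.8]], ["PO", "MITO", "ER"]
            )

    def test_starved_class_folds_count_as_misclassified(self, caplog):
        # exactly two ER points: each ER fold leaves one, so ER is
        # dropped from that fold and both ER points must count as wrong
        import logging

        df = synth_feature_dataset(
            (
                ClassSpec("PO", 8.0, 0.1, 1.7, 0.1, 6),
                ClassSpec("MITO", 1.0, 0.1, 1.2, 0.1, 6),
                ClassSpec("ER", 0.21, 0.05, 2.8, 0.05, 2),
            ),
            seed=2,
        )
        model = make_model(df)
        with caplog.at_level(logging.WARNING, logger="tapredict.model"):
            wrong = model.loocv_misclassifications()
        assert wrong == 2  # PO/MITO blobs are trivially separable
        assert any("starved" in rec.message for rec in caplog.records)

    def test_parameter_recovery_error_vanishes_with_spread(self):
        # classes centred at the published group means; LOOCV error
        # shrinks to zero as the spread does
        errors = []
        for spread in (1.5, 0.5, 0.05):
            df = synth_feature_dataset(
                (
                    ClassSpec("PO", 6.03, spread, 1.7, spread / 4, 8),
                    ClassSpec("MITO", 1.12, spread, 1.8, spread / 4, 8),
                    ClassSpec("ER", 0.21, spread, 2.4, spread / 4, 8),
                ),
                seed=4,
            )
            errors.append(make_model(df).loocv_misclassifications())
        assert errors[-1] == 0
        assert errors[0] >= errors[-1]

    def test_deterministic_given_seed(self, separable_blobs):
        m1 = make_model(separable_blobs, seed=3).loocv_misclassifications()
        m2 = make_model(separable_blobs, seed=3).loocv_misclassifications()
        assert m1 == m2


class TestProbabilityGrid:
    def test_single_point_grid_matches_predict(self, separable_results):
        grid = separable_results.probability_grid((2.0, 2.0), (1.5, 1.5), step=1.0)
        assert len(grid) == 1
        direct = separable_results.predict_proba([[2.0, 1.5]])[0]
        assert grid.iloc[0][["p_PO", "p_MITO", "p_ER"]].to_numpy() == pytest.approx(direct)

    def test_rows_sum_to_one(self, separable_results):
        grid = separable_results.probability_grid((-2, 10), (1, 3), step=0.5)
        total = grid[["p_PO", "p_MITO", "p_ER"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_high_charge_moderate_gravy_corner_is_po(self, fixture_entries):
        results = TargetingModel.from_entries(fixture_entries).fit()
        grid = results.probability_grid((-2, 10), (1, 3), step=0.5)
        corner = grid[(grid["tail_charge"] == 10.0) & (grid["tmd_gravy"] == 2.0)]
        assert corner.iloc[0]["argmax"] == "PO"

    def test_empty_range_is_error(self, separable_results):
        with pytest.raises(ValueError):
            separable_results.probability_grid((5, 4), (1, 3), step=0.5)
        with pytest.raises(ValueError):
            separable_results.probability_grid((0, 1), (1, 3), step=0.0)


class TestPersistence:
    def test_round_trip_predictions_identical(self, separable_results, tmp_path, rng):
        p = tmp_path / "model.json"
        separable_results.save(p)
        reloaded = TargetingResults.load(p)
        X = np.column_stack([rng.uniform(-5, 15, 100), rng.uniform(0, 4, 100)])
        assert np.allclose(
            separable_results.predict_proba(X), reloaded.predict_proba(X), atol=1e-12
        )

    def test_version_mismatch_rejected(self, separable_results, tmp_path):
        p = tmp_path / "model.json"
        separable_results.save(p)
        payload = json.loads(p.read_text())
        payload["format_version"] = 999
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            TargetingResults.load(p)

    def test_corrupt_file_rejected(self, tmp_path):
        p = tmp_path / "model.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="corrupt"):
            TargetingResults.load(p)

    def test_foreign_json_rejected(self, tmp_path):
        p = tmp_path / "model.json"
        p.write_text(json.dumps({"hello": 1}))
        with pytest.raises(ValueError, match="not a"):
            TargetingResults.load(p)

    def test_fingerprint_mismatch_warns(self, separable_results, separable_blobs):
        X = separable_blobs[["tail_charge", "tmd_gravy"]].to_numpy().copy()
        y = separable_blobs["label"].to_numpy()
        X[0, 0] += 1.0
        with pytest.warns(UserWarning, match="fingerprint"):
            separable_results.evaluate(X, y)

    def test_matching_data_does_not_warn(self, separable_results, separable_blobs):
        import warnings as w

        X = separable_blobs[["tail_charge", "tmd_gravy"]].to_numpy()
        y = separable_blobs["label"].to_numpy()
        with w.catch_warnings():
            w.simplefilter("error")
            report = separable_results.evaluate(X, y)
        assert report["correct"].all()


class TestSummary:
    def test_summary_mentions_key_quantities(self, separable_results):
        text = separable_results.summary()
        assert "RBF" in text
        assert "misclassified" in text
        assert "gamma=0.5" in text
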