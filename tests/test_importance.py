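import numpy as np
import pytest

from cvpfi import CVPFI, PFI, corrupt_validation_block, cvpfi, pfi, score
from cvpfi.correlation import gate_correlations
from cvpfi.datasets import generate_case1


class TestScore:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert score(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert score(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_r2(self):
        assert score(np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 5.0])) == pytest.approx(0.8)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            score(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_classification_accuracy(self):
        assert score(np.array([0, 1, 1, 0]), np.array([0, 1, 0, 0]),
                     task="classification") == 0.75

    def test_nonfinite_regression_rejected(self):
        with pytest.raises(ValueError):
            score(np.array([1.0, np.inf]), np.array([1.0, 2.0]))


class TestCorruptValidationBlock:
    def _setup(self, seed=0, m=40, p=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(m, p))
        return X, np.arange(5, 15)

    def test_requires_rng(self):
        X, val = self._setup()
        with pytest.raises(ValueError, match="rng"):
            corrupt_validation_block(X, val, 0, np.zeros(3), None)

    def test_constant_target_column_unchanged(self):
        X, val = self._setup()
        X[:, 1] = 7.0
        block = corrupt_validation_block(
            X, val, 1, np.zeros(3), np.random.default_rng(0)
        )
        np.testing.assert_array_equal(block[:, 1], X[val, 1])

    def test_only_target_column_changes_without_companions(self):
        X, val = self._setup()
        block = corrupt_validation_block(
            X, val, 0, np.array([1.0, 0.0, 0.0]), np.random.default_rng(1)
        )
        np.testing.assert_array_equal(block[:, 1:], X[val, 1:])
        # drawn without replacement from the full column: values are a subset
        assert set(block[:, 0]) <= set(X[:, 0])
        assert len(set(block[:, 0])) == len(val)

    def test_companion_replacement_frequencies(self):
        X, val = self._setup(seed=2)
        reps = 1000
        always, half = 0, 0
        for j in range(reps):
            rng = np.random.default_rng(j)
            b1 = corrupt_validation_block(X, val, 0, np.array([1.0, 1.0, 0.0]), rng)
            always += not np.array_equal(b1[:, 1], X[val, 1])
            rng = np.random.default_rng(10_000 + j)
            b2 = corrupt_validation_block(X, val, 0, np.array([1.0, 0.5, 0.0]), rng)
            half += not np.array_equal(b2[:, 1], X[val, 1])
        assert always == reps  # Bernoulli(1.0) companion always replaced
        se = np.sqrt(0.25 / reps)
        assert abs(half / reps - 0.5) < 3 * se

    def test_joint_rows_preserve_pairing(self):
        X, val = self._setup(seed=3)
        X[:, 1] = X[:, 0]  # perfectly paired columns
        block = corrupt_validation_block(
            X, val, 0, np.array([1.0, 1.0, 0.0]), np.random.default_rng(4),
            joint_rows=True,
        )
        np.testing.assert_array_equal(block[:, 0], block[:, 1])


class TestCVPFIModel:
    def test_importance_identity_exact(self, lsq):
        X, y, _ = generate_case1(0)
        res = CVPFI(X, y, lsq).fit(J=3, seed=1)
        np.testing.assert_array_equal(
            res.importances, res.reference_score - res.corrupted_scores.mean(axis=1)
        )
        assert np.isfinite(res.corrupted_scores).all()
        assert res.corrupted_scores.shape == (15, 3)

    def test_seed_reproducibility(self, lsq):
        X, y, _ = generate_case1(1)
        a = CVPFI(X, y, lsq).fit(J=2, seed=5)
        b = CVPFI(X, y, lsq).fit(J=2, seed=5)
        np.testing.assert_array_equal(a.importances, b.importances)
        np.testing.assert_array_equal(a.corrupted_scores, b.corrupted_scores)
        assert a.reference_score == b.reference_score

    def test_constant_feature_importance_exactly_zero(self, lsq):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        X[:, 2] = 1.0
        y = X[:, 0] + rng.normal(scale=0.1, size=30)
        with pytest.warns(UserWarning, match="constant"):
            res = CVPFI(X, y, lsq).fit(J=3, seed=0)
        assert res.importances[2] == 0.0

    def test_duplicated_perfect_predictors_share_importance(self, lsq):
        # co-sampling at gated correlation 1.0 makes the twin columns'
        # corruption events coincide, so neither drains the other's credit
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=40)
            X = np.column_stack([y, y, rng.normal(size=(40, 2))])
            res = CVPFI(X, y, lsq).fit(J=5, seed=seed)
            assert res.importances[0] > 0.5
            diffs.append(
                abs(res.importances[0] - res.importances[1])
                / max(res.importances[0], res.importances[1])
            )
        assert np.mean(diffs) < 0.2

    def test_null_calibration(self, lsq):
        # y independent of every feature: mean importance compatible with 0
        per_seed = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(30, 4))
            y = rng.normal(size=30)
            per_seed.append(CVPFI(X, y, lsq).fit(J=3, seed=seed).importances)
        per_seed = np.array(per_seed)
        mean = per_seed.mean(axis=0)
        se = per_seed.std(axis=0, ddof=1) / np.sqrt(len(per_seed))
        assert np.all(np.abs(mean) < 3 * se + 1e-12)

    def test_more_repetitions_reduce_variance(self, lsq):
        # across-seed variance of the importance estimate shrinks with J
        var = {}
        for J in (1, 5):
            imps = []
            for seed in range(20):
                X, y, _ = generate_case1(seed)
                imps.append(CVPFI(X, y, lsq).fit(J=J, seed=seed).importances)
            var[J] = np.array(imps).var(axis=0, ddof=1).mean()
        assert var[5] < var[1]

    def test_from_dataframe_and_functional_wrapper(self, lsq):
        import pandas as pd

        X, y, _ = generate_case1(2)
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(15)])
        frame["bp"] = y
        res = CVPFI.from_dataframe(frame, "bp", lsq).fit(J=2, seed=3)
        res_fn = cvpfi(lsq, X, y, J=2, seed=3)
        np.testing.assert_array_equal(res.importances, res_fn.importances)
        assert res.feature_names[0] == "f0"

    def test_fold_override_respected(self, lsq):
        X, y, _ = generate_case1(0)
        res = CVPFI(X, y, lsq, n_folds=5).fit(J=1, seed=0)
        assert res.fold_plan.n_splits == 5

    def test_j_must_be_positive(self, lsq):
        X, y, _ = generate_case1(0)
        with pytest.raises(ValueError):
            CVPFI(X, y, lsq).fit(J=0, seed=0)


class TestPFIModel:
    def test_importance_identity_and_determinism(self, lsq):
        X, y, _ = generate_case1(3)
        a = PFI(X, y, lsq).fit(J=4, seed=2)
        b = PFI(X, y, lsq).fit(J=4, seed=2)
        np.testing.assert_array_equal(
            a.importances, a.reference_score - a.corrupted_scores.mean(axis=1)
        )
        np.testing.assert_array_equal(a.importances, b.importances)

    def test_split_fractions(self, lsq):
        X, y, _ = generate_case1(0)
        model = PFI(X, y, lsq)
        train, val = model.split_indices(seed=0)
        assert len(val) == 5 and len(train) == 15  # 75/25 of 20 samples
        assert not set(train) & set(val)

    def test_constant_validation_column_importance_zero(self, lsq):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 3))
        X[:, 1] = 5.0  # permutation of equal values is the identity
        y = X[:, 0] + rng.normal(scale=0.1, size=24)
        res = PFI(X, y, lsq).fit(J=3, seed=0)
        assert res.importances[1] == 0.0

    def test_single_row_validation_warns_and_zeroes(self, lsq):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        with pytest.warns(UserWarning, match="single-row"):
            res = PFI(X, y, lsq, validation_fraction=0.125).fit(J=2, seed=0)
        np.testing.assert_array_equal(res.importances, 0.0)

    def test_explicit_split_wrapper(self, lsq):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = X @ [2.0, 0.0, -1.0] + rng.normal(scale=0.1, size=40)
        res = pfi(lsq, X[:30], y[:30], X[30:], y[30:], J=3, seed=0)
        assert res.method == "pfi"
        assert res.importances[0] > res.importances[1]


class TestResultsObject:
    def test_rank_sorts_descending_with_index_tiebreak(self, lsq):
        X, y, _ = generate_case1(0)
        res = CVPFI(X, y, lsq).fit(J=2, seed=0)
        ranked = res.rank()
        assert list(ranked["importance"]) == sorted(res.importances, reverse=True)

    def test_csv_and_json_serialisation(self, tmp_path, lsq):
        import json

        import pandas as pd

        X, y, _ = generate_case1(0)
        res = CVPFI(X, y, lsq).fit(J=2, seed=0)
        res.to_csv(tmp_path / "imp.csv")
        back = pd.read_csv(tmp_path / "imp.csv")
        assert list(back.columns) == [
            "feature", "importance", "reference_score", "J", "method", "seed",
        ]
        np.testing.assert_allclose(back["importance"], res.importances)
        res.to_json(tmp_path / "imp.json")
        audit = json.loads((tmp_path / "imp.json").read_text())
        assert np.asarray(audit["corrupted_scores"]).shape == (15, 2)

    def test_summary_mentions_reference_score(self, lsq):
        X, y, _ = generate_case1(0)
        res = CVPFI(X, y, lsq).fit(J=2, seed=0)
        text = res.summary()
        assert "reference score" in text
        assert res.feature_names[0] in text


def test_gated_probabilities_computed_on_full_data(lsq):
    # the gate comes from the whole dataset, not per fold: the stored matrix
    # must equal a direct full-data computation
    X, y, _ = generate_case1(0)
    res = CVPFI(X, y, lsq).fit(J=1, seed=0)
    direct = gate_correlations(X, 0.999)
    np.testing.assert_array_equal(res.gated_correlations.values, direct.values)
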