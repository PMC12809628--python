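"""Design-matrix assembly, stratified splitting, training, evaluation."""

import numpy as np
import pandas as pd
import pytest

from slc5pcm import (
    SyntheticSpec,
    assemble,
    curate,
    evaluate_per_target,
    generate_dataset,
    morgan_features,
    stratified_split,
    train,
    variable_positions,
)
from slc5pcm.modeling import FeatureMatrix, SplitIndex
from slc5pcm.synthetic import default_targets

TINY_RF = {"n_estimators": 80, "max_features": 0.3}


class TestAssemble:
    def test_two_by_two_crossed(self, ztable):
        targets = default_targets()[:2]
        positions = variable_positions(targets)
        block = morgan_features(
            ["CCOc1ccccc1", "CCNc1ccccc1"], ["K1", "K2"]
        )
        dp = pd.DataFrame(
            {
                "inchikey": ["K1", "K1", "K2", "K2"],
                "target_id": ["SYNT001", "SYNT002"] * 2,
                "pic50": [7.0, 8.0, 6.0, 7.0],
            }
        )
        fm = assemble(dp, block, targets, positions, ztable)
        assert fm.n_rows == 4
        prot = fm.X[fm.protein_columns]
        assert len(prot.drop_duplicates()) == 2

    def test_column_count_arithmetic(self, tiny_spec, tiny_matrix, tiny_block):
        positions = variable_positions(tiny_spec.targets)
        n_total = len(tiny_matrix.X.columns) + len(tiny_matrix.dropped_constant)
        assert n_total == len(tiny_block.feature_names) + 3 * len(positions)

    def test_protein_columns_constant_within_target(self, tiny_matrix):
        joined = pd.concat(
            [tiny_matrix.meta["target_id"], tiny_matrix.X[tiny_matrix.protein_columns]],
            axis=1,
        )
        assert (joined.groupby("target_id").nunique() == 1).all().all()

    def test_single_target_protein_block_flagged(self, ztable):
        targets = default_targets()[:1] + default_targets()[:1]
        positions = default_targets()[0].positions
        block = morgan_features(["CCOc1ccccc1", "CCNc1ccccc1"], ["K1", "K2"])
        dp = pd.DataFrame(
            {
                "inchikey": ["K1", "K2"],
                "target_id": ["SYNT001", "SYNT001"],
                "pic50": [7.0, 6.0],
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            fm = assemble(dp, block, default_targets()[:1], positions, ztable)
        assert fm.protein_columns == []

    def test_unresolvable_ids_listed(self, tiny_spec, tiny_block, ztable):
        positions = variable_positions(tiny_spec.targets)
        dp = pd.DataFrame(
            {"inchikey": ["NOPE"], "target_id": ["SYNT001"], "pic50": [7.0]}
        )
        with pytest.raises(KeyError, match="NOPE"):
            assemble(dp, tiny_block, tiny_spec.targets, positions, ztable)


class TestStratifiedSplit:
    def _matrix(self, counts):
        rows = []
        for tgt, n in counts.items():
            rows.extend({"inchikey": f"K{i}{tgt}", "target_id": tgt} for i in range(n))
        meta = pd.DataFrame(rows)
        X = pd.DataFrame({"f": np.arange(len(meta), dtype=float)})
        y = pd.Series(np.linspace(5, 9, len(meta)))
        return FeatureMatrix(X=X, y=y, meta=meta, ligand_columns=["f"], protein_columns=[])

    def test_ten_rows_split_seven_three(self):
        split = stratified_split(self._matrix({"T1": 10}), 0.7, seed=0)
        assert (len(split.train), len(split.test)) == (7, 3)

    def test_three_rows_split_two_one(self):
        split = stratified_split(self._matrix({"T1": 3}), 0.7, seed=0)
        assert (len(split.train), len(split.test)) == (2, 1)

    def test_singleton_target_goes_to_train(self):
        split = stratified_split(self._matrix({"T1": 10, "T2": 1}), 0.7, seed=0)
        m = self._matrix({"T1": 10, "T2": 1})
        assert set(m.meta.loc[split.train, "target_id"]) == {"T1", "T2"}

    def test_same_seed_identical_split(self):
        m = self._matrix({"T1": 20, "T2": 7})
        a = stratified_split(m, 0.7, seed=5)
        b = stratified_split(m, 0.7, seed=5)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)

    def test_disjoint_and_covering(self, tiny_matrix, tiny_split):
        both = np.concatenate([tiny_split.train, tiny_split.test])
        assert len(np.unique(both)) == tiny_matrix.n_rows

    def test_overlapping_indices_rejected(self):
        with pytest.raises(ValueError):
            SplitIndex(train=np.array([0, 1]), test=np.array([1, 2]), fraction=0.7, seed=0)


class TestTrain:
    def test_noiseless_strong_signal_learnable(self, ztable):
        spec = SyntheticSpec(
            n_scaffolds=10, series_size=12, seed=3,
            noise_sd=0.0, cliff_fraction=0.0, duplicate_rate=0.0,
            censored_fraction=0.0,
        )
        records, _ = generate_dataset(spec)
        cur = curate(records, profiles=spec.targets)
        block = morgan_features(
            cur.molecules["standardized_smiles"].tolist(),
            cur.molecules["inchikey"].tolist(),
        )
        positions = variable_positions(spec.targets)
        fm = assemble(cur.datapoints, block, spec.targets, positions, ztable)
        split = stratified_split(fm, 0.7, seed=1)
        res = train(
            fm, split, "rf", hyperparameters={"n_estimators": 200, "max_features": 0.3},
            seed=1, compute_cv=False,
        )
        assert res.metrics["r2_test"] > 0.9

    def test_dummy_baselines_near_zero(self, tiny_matrix, tiny_split):
        for algo in ("dummy-mean", "dummy-median"):
            res = train(tiny_matrix, tiny_split, algo, compute_cv=False)
            assert abs(res.metrics["r2_test"]) < 0.15

    def test_y_scrambling_control_destroys_signal(self, tiny_matrix, tiny_split):
        rng = np.random.default_rng(0)
        scrambled = FeatureMatrix(
            X=tiny_matrix.X,
            y=pd.Series(rng.permutation(tiny_matrix.y.to_numpy())),
            meta=tiny_matrix.meta,
            ligand_columns=tiny_matrix.ligand_columns,
            protein_columns=tiny_matrix.protein_columns,
        )
        res = train(
            scrambled, tiny_split, "rf", hyperparameters=TINY_RF, seed=1,
            compute_cv=False,
        )
        assert res.metrics["r2_test"] < 0.1

    def test_q2_equals_mean_of_fold_r2_recomputed(self, tiny_matrix, tiny_split):
        res = train(
            tiny_matrix, tiny_split, "rf", hyperparameters=TINY_RF, seed=2,
            cv_folds=5,
        )
        recomputed = []
        for fp in res.fold_predictions:
            ss_res = float(np.sum((fp.y_true - fp.y_pred) ** 2))
            ss_tot = float(np.sum((fp.y_true - fp.y_true.mean()) ** 2))
            recomputed.append(1.0 - ss_res / ss_tot)
        assert res.metrics["q2_cv10"] == pytest.approx(np.mean(recomputed), abs=1e-12)
        # folds partition the training rows
        covered = np.concatenate([fp.test_indices for fp in res.fold_predictions])
        assert sorted(covered) == list(range(len(tiny_split.train)))

    def test_svm_scaler_fitted_on_train_rows_only(self, tiny_matrix, tiny_split):
        res = train(
            tiny_matrix, tiny_split, "svm", seed=1, compute_cv=False,
            hyperparameters={"kernel": "rbf", "C": 10.0},
        )
        scaler = res.estimator.named_steps["scale"]
        X_train = tiny_matrix.X.to_numpy(dtype=float)[tiny_split.train]
        assert np.allclose(scaler.mean_, X_train.mean(axis=0))

    def test_xgb_trains_and_beats_dummy(self, tiny_matrix, tiny_split):
        res = train(
            tiny_matrix, tiny_split, "xgb",
            hyperparameters={"n_estimators": 80, "max_depth": 5, "learning_rate": 0.2},
            seed=1, compute_cv=False,
        )
        dummy = train(tiny_matrix, tiny_split, "dummy-mean", compute_cv=False)
        assert res.metrics["r2_test"] > dummy.metrics["r2_test"] + 0.3

    def test_grid_search_uses_train_rows_and_improves_nothing_blindly(
        self, tiny_matrix, tiny_split
    ):
        res = train(
            tiny_matrix, tiny_split, "rf",
            grid={"n_estimators": [40, 80], "max_features": [0.3]},
            seed=1, compute_cv=False,
        )
        assert res.hyperparameters["n_estimators"] in (40, 80)

    def test_constant_response_rejected(self, tiny_matrix, tiny_split):
        flat = FeatureMatrix(
            X=tiny_matrix.X,
            y=pd.Series(np.full(tiny_matrix.n_rows, 7.0)),
            meta=tiny_matrix.meta,
            ligand_columns=tiny_matrix.ligand_columns,
            protein_columns=tiny_matrix.protein_columns,
        )
        with pytest.raises(ValueError, match="constant"):
            train(flat, tiny_split, "rf", compute_cv=False)


class TestEvaluatePerTarget:
    def test_fractions_match_brute_force_count(self, tiny_rf, tiny_matrix, tiny_split):
        table = evaluate_per_target(tiny_rf, tiny_matrix, tiny_split)
        targets = tiny_matrix.targets.to_numpy()[tiny_split.test]
        y = tiny_matrix.y.to_numpy()[tiny_split.test]
        pred = tiny_rf.y_pred_test
        for row in table.itertuples():
            mask = targets == row.target_id
            errs = [abs(a - b) for a, b in zip(y[mask], pred[mask])]
            assert row.frac_within_1 == pytest.approx(
                sum(e <= 1.0 for e in errs) / len(errs)
            )
            assert row.frac_within_05 == pytest.approx(
                sum(e <= 0.5 for e in errs) / len(errs)
            )
            assert row.n_test == len(errs)

    def test_undefined_r2_for_tiny_targets_but_fractions_reported(self, ztable):
        targets = default_targets()[:2]
        positions = variable_positions(targets)
        block = morgan_features(
            ["CCOc1ccccc1", "CCNc1ccccc1", "CCSc1ccccc1", "COc1ccccc1"],
            ["K1", "K2", "K3", "K4"],
        )
        dp = pd.DataFrame(
            {
                "inchikey": ["K1", "K2", "K3", "K4", "K1"],
                "target_id": ["SYNT001"] * 4 + ["SYNT002"],
                "pic50": [7.0, 6.5, 8.0, 5.5, 7.5],
            }
        )
        fm = assemble(dp, block, targets, positions, ztable)
        split = SplitIndex(
            train=np.array([0, 1, 2]), test=np.array([3, 4]), fraction=0.7, seed=0
        )
        res = train(fm, split, "rf", hyperparameters={"n_estimators": 20}, seed=0,
                    compute_cv=False)
        table = evaluate_per_target(res, fm, split).set_index("target_id")
        assert np.isnan(table.loc["SYNT002", "r2"])
        assert 0.0 <= table.loc["SYNT002", "frac_within_1"] <= 1.0
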