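"""Interpretation: importance, ablation, outliers, selectivity, mutants."""

import numpy as np
import pandas as pd
import pytest

from slc5pcm import (
    SyntheticSpec,
    assemble,
    curate,
    generate_dataset,
    impurity_rank_stats,
    morgan_features,
    mutant_report,
    outlier_census,
    position_ablation,
    predict_for_profile,
    selectivity_eval,
    stratified_split,
    train,
    variable_positions,
)
from slc5pcm.interpret import protein_feature_positions, shuffle_permutation_importance
from slc5pcm.modeling import SplitIndex
from slc5pcm.synthetic import default_targets

TINY_RF = {"n_estimators": 80, "max_features": 0.3}


@pytest.fixture(scope="module")
def two_target_setup(ztable):
    """Two targets differing only at position 286: every other position is
    constant across the data and pruned at assembly."""
    targets = default_targets()[:2]
    positions = variable_positions(targets)
    spec = SyntheticSpec(
        n_scaffolds=4, series_size=8, seed=13, targets=targets,
        causal_positions={"7VSI:286": 1.0}, target_weights=None,
        duplicate_rate=0.0, censored_fraction=0.0,
    )
    records, _ = generate_dataset(spec)
    cur = curate(records, profiles=targets)
    block = morgan_features(
        cur.molecules["standardized_smiles"].tolist(),
        cur.molecules["inchikey"].tolist(),
    )
    fm = assemble(cur.datapoints, block, targets, positions, ztable)
    split = stratified_split(fm, 0.7, seed=2)
    model = train(fm, split, "rf", hyperparameters=TINY_RF, seed=2, compute_cv=False)
    return {
        "targets": targets, "positions": positions, "block": block,
        "matrix": fm, "split": split, "model": model,
    }


@pytest.fixture(scope="module")
def rank_report(tiny_matrix, tiny_split):
    return impurity_rank_stats(
        tiny_matrix, tiny_split, seeds=[1, 2, 3], hyperparameters=TINY_RF
    )


@pytest.fixture(scope="module")
def ablation_report(tiny_matrix, tiny_split):
    return position_ablation(
        tiny_matrix, tiny_split, hyperparameters=TINY_RF, seed=1,
        subset=[286, 460],
    )


@pytest.fixture(scope="module")
def sel_summary(tiny_rf, tiny_matrix, tiny_split):
    return selectivity_eval(tiny_rf, tiny_matrix, tiny_split)


class TestImpurityRankStats:
    def test_ranks_form_a_permutation(self, rank_report, tiny_matrix):
        n = len(tiny_matrix.X.columns)
        for col in rank_report.ranks.columns:
            assert sorted(rank_report.ranks[col]) == list(range(1, n + 1))

    def test_causal_positions_dominate_protein_features(self, rank_report):
        top = rank_report.position_summary()
        assert set(top.head(2)["position"]) == {286, 460}

    def test_reproducible_for_same_seeds(self, tiny_matrix, tiny_split, rank_report):
        again = impurity_rank_stats(
            tiny_matrix, tiny_split, seeds=[1, 2, 3], hyperparameters=TINY_RF
        )
        assert rank_report.ranks.equals(again.ranks)
        assert rank_report.summary.equals(again.summary)

    def test_single_run_has_zero_rank_std(self, tiny_matrix, tiny_split):
        rep = impurity_rank_stats(
            tiny_matrix, tiny_split, seeds=[7], hyperparameters=TINY_RF
        )
        assert (rep.summary["std"] == 0.0).all()


class TestPositionAblation:
    def test_full_subset_reproduces_reference_exactly(self, tiny_matrix, tiny_split):
        positions = sorted(protein_feature_positions(tiny_matrix.X.columns))
        rep = position_ablation(
            tiny_matrix, tiny_split, hyperparameters=TINY_RF, seed=1,
            positions=[], subset=positions,
        )
        assert rep.baselines["subset"]["r2_test"] == pytest.approx(
            rep.baselines["all_positions"]["r2_test"], abs=1e-12
        )

    def test_causal_removal_collapses_and_noncausal_does_not(self, ablation_report):
        drops = ablation_report.drop_from_reference()
        assert drops.loc[286] > 0.15
        non_causal = [p for p in drops.index if p not in (286, 460)]
        assert drops.loc[non_causal].abs().max() < 0.1

    def test_causal_subset_recovers_reference_performance(self, ablation_report):
        assert ablation_report.baselines["subset"]["r2_test"] == pytest.approx(
            ablation_report.baselines["all_positions"]["r2_test"], abs=0.1
        )

    def test_add_one_back_ranking_puts_causal_first(self, ablation_report):
        ranking = ablation_report.position_ranking(by="r2_test_only")
        assert set(ranking[:2]) == {286, 460}

    def test_position_without_columns_equals_reference(self, two_target_setup):
        fm = two_target_setup["matrix"]
        assert protein_feature_positions(fm.X.columns).keys() == {286}
        rep = position_ablation(
            fm, two_target_setup["split"], hyperparameters=TINY_RF, seed=2,
            positions=[286, 460],
        )
        assert rep.table.loc[460, "r2_test_removed"] == pytest.approx(
            rep.baselines["all_positions"]["r2_test"], abs=1e-12
        )
        assert (
            rep.table.loc[286, "r2_test_removed"]
            < rep.baselines["all_positions"]["r2_test"]
        )

    def test_shuffle_mode_agrees_on_top_position(
        self, tiny_rf, tiny_matrix, tiny_split
    ):
        table = shuffle_permutation_importance(
            tiny_rf, tiny_matrix, tiny_split, n_repeats=5, seed=0
        )
        assert table.iloc[0]["position"] in (286, 460)


class TestOutlierCensus:
    def test_infinite_threshold_empty(self, tiny_matrix, tiny_split):
        census = outlier_census(
            tiny_matrix, tiny_split, seeds=[1], threshold=np.inf,
            hyperparameters=TINY_RF,
        )
        assert census.empty

    def test_census_counts_bounded_by_runs_and_errors_exceed_threshold(
        self, tiny_matrix, tiny_split
    ):
        census = outlier_census(
            tiny_matrix, tiny_split, seeds=[1, 2, 3], threshold=1.0,
            hyperparameters=TINY_RF,
        )
        assert (census["times_observed"] <= 3).all()
        assert (census["times_observed"] >= 1).all()
        assert (census["max_abs_error"] > 1.0).all()
        for row in census.itertuples():
            errs = [abs(row.pic50_exp - p) for p in row.pic50_pred_runs]
            assert row.max_abs_error == pytest.approx(max(errs))
            assert row.times_observed == sum(e > 1.0 for e in errs)


class TestSelectivity:
    def test_records_recomputable_from_predictions(
        self, sel_summary, tiny_rf, tiny_matrix, tiny_split
    ):
        assert not sel_summary.empty
        meta_test = tiny_matrix.meta.iloc[tiny_split.test].reset_index(drop=True)
        y_test = tiny_matrix.y.to_numpy()[tiny_split.test]
        lookup = {
            (meta_test.loc[i, "inchikey"], meta_test.loc[i, "target_id"]): (
                y_test[i],
                tiny_rf.y_pred_test[i],
            )
            for i in meta_test.index
        }
        for row in sel_summary.records.itertuples():
            e1, p1 = lookup[(row.inchikey, row.target_1)]
            e2, p2 = lookup[(row.inchikey, row.target_2)]
            assert row.pic_diff == pytest.approx((e1 - e2) - (p1 - p2), abs=1e-9)

    def test_molecules_are_test_only(self, sel_summary, tiny_matrix, tiny_split):
        train_keys = set(tiny_matrix.meta["inchikey"].to_numpy()[tiny_split.train])
        assert not set(sel_summary.records["inchikey"]) & train_keys

    def test_antisymmetric_under_target_swap(self, sel_summary):
        for row in sel_summary.records.itertuples():
            swapped = -(row.delta_exp - row.delta_pred)
            assert -row.pic_diff == pytest.approx(swapped, abs=1e-12)

    def test_fractions_match_brute_force(self, sel_summary):
        diffs = sel_summary.records["pic_diff"].abs().to_numpy()
        assert sel_summary.metrics["frac_within_1"] == pytest.approx(
            (diffs <= 1.0).mean()
        )
        assert sel_summary.metrics["frac_within_05"] == pytest.approx(
            (diffs <= 0.5).mean()
        )

    def test_no_qualifying_molecules_warns(self, tiny_matrix):
        lonely = SplitIndex(
            train=np.arange(tiny_matrix.n_rows - 1),
            test=np.array([tiny_matrix.n_rows - 1]),
            fraction=0.99,
            seed=0,
        )
        retrained = train(
            tiny_matrix, lonely, "rf", hyperparameters={"n_estimators": 20},
            seed=0, compute_cv=False,
        )
        with pytest.warns(UserWarning, match="test set"):
            out = selectivity_eval(retrained, tiny_matrix, lonely)
        assert out.empty


class TestMutantPrediction:
    def test_wild_type_equals_row_prediction(
        self, tiny_rf, tiny_matrix, tiny_split, tiny_spec, tiny_block, ztable
    ):
        positions = variable_positions(tiny_spec.targets)
        i = int(tiny_split.test[0])
        ikey = tiny_matrix.meta.loc[i, "inchikey"]
        tgt = tiny_matrix.meta.loc[i, "target_id"]
        profile = next(p for p in tiny_spec.targets if p.target_id == tgt)
        lig = tiny_block.features.loc[ikey]
        pred = predict_for_profile(tiny_rf, lig, profile, positions, ztable)
        assert pred == pytest.approx(
            float(tiny_rf.y_pred_test[list(tiny_split.test).index(i)]), abs=1e-9
        )

    def test_mutation_outside_model_positions_is_inert(self, two_target_setup, ztable):
        # in the two-target matrix only 286 is encoded, so mutating 460
        # cannot change the prediction
        model = two_target_setup["model"]
        block = two_target_setup["block"]
        wt = two_target_setup["targets"][0]
        assert wt.at(460) == "S"
        with pytest.warns(UserWarning, match="wild type"):
            rep = mutant_report(
                model, block.features.iloc[0], wt, ["S460T"],
                two_target_setup["positions"], ztable,
            )
        assert rep.loc[1, "shift_from_wt"] == pytest.approx(0.0, abs=1e-12)
        assert not rep.loc[1, "mutated_position_in_model"]

    def test_causal_mutation_moves_prediction_toward_planted_offset(
        self, two_target_setup, ztable
    ):
        # the generator adds effect x Z-distance from the reference residue,
        # so mutating 286 V->L on the V-pocket must raise the prediction
        model = two_target_setup["model"]
        block = two_target_setup["block"]
        wt = two_target_setup["targets"][0]
        assert wt.at(286) == "V"
        rep = mutant_report(
            model, block.features.iloc[0], wt, ["V286L"],
            two_target_setup["positions"], ztable,
        )
        assert rep.loc[1, "shift_from_wt"] > 0.5

    def test_report_orders_wt_first(self, tiny_rf, tiny_spec, tiny_block, ztable):
        positions = variable_positions(tiny_spec.targets)
        wt = tiny_spec.targets[0]
        rep = mutant_report(
            tiny_rf, tiny_block.features.iloc[0], wt, ["S460T"], positions, ztable
        )
        assert rep.loc[0, "variant"] == "wt"
        assert len(rep) == 2
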