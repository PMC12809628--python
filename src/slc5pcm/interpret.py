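"""Model interpretation: residue importance, outliers, selectivity, mutants.

Two complementary residue-importance readouts are provided. The first ranks
all features by the forest's mean decrease in impurity across several
re-seeded fits; ranks are ascending, so the most important feature of an
n-feature model has rank n. Impurity importance cannot tell whether another
feature could substitute for the one it credits, so the second method
retrains the model with each binding-site position removed (all three
Z-scales at once) and with each position alone added back to the ligand
features, using fixed hyperparameters and a fixed split. An optional
value-shuffling permutation importance is included for comparison.

The strong-outlier census re-trains the model under several seeds on one
split and counts, per test datapoint, the runs where the absolute
prediction error exceeds 2 pIC50 units. Selectivity is judged by
pIC_diff = (experimental potency difference between two targets) minus
(predicted difference) for molecules confined to the test set; the measure
is antisymmetric under swapping the target pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score

from .modeling import (
    DEFAULT_HYPERPARAMETERS,
    FeatureMatrix,
    ModelResult,
    SplitIndex,
    train,
)
from .proteins import Position, ResidueProfile, ZScaleTable, encode_zscales

_POS_COL_RE = re.compile(r"^pos(\d+)_Z[123]$")

OUTLIER_THRESHOLD = 2.0


def protein_feature_positions(feature_names: Iterable[str]) -> dict[int, list[str]]:
    """Group Z-scale column names by their position number."""
    out: dict[int, list[str]] = {}
    for name in feature_names:
        m = _POS_COL_RE.match(name)
        if m:
            out.setdefault(int(m.group(1)), []).append(name)
    return out


# --------------------------------------------------------------------------
# method 1: impurity-based rank statistics
# --------------------------------------------------------------------------


@dataclass
class ImportanceReport:
    """Feature ranks across randomized runs, summarized for protein features.

    ``ranks`` holds the ascending rank of every feature per run (rank n =
    most important of n features; each run's ranks are a permutation of
    1..n). ``summary`` reports mean/median/std of the ranks for the
    protein (Z-scale) features, sorted by mean rank, highest first.
    """

    ranks: pd.DataFrame  # features x runs
    summary: pd.DataFrame  # protein features: mean, median, std
    seeds: list[int]

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.summary.head(k)

    def position_summary(self) -> pd.DataFrame:
        """Per position: the best (max) mean rank among its Z-scale features."""
        groups = protein_feature_positions(self.summary.index)
        rows = [
            {
                "position": pos,
                "best_feature": self.summary.loc[cols, "mean"].idxmax(),
                "best_mean_rank": float(self.summary.loc[cols, "mean"].max()),
            }
            for pos, cols in groups.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values("best_mean_rank", ascending=False)
            .reset_index(drop=True)
        )

    def per_run_position_ranking(self) -> dict[str, list[int]]:
        """For each run, positions ordered by their best feature rank."""
        groups = protein_feature_positions(self.summary.index)
        out = {}
        for run in self.ranks.columns:
            score = {
                pos: int(self.ranks.loc[cols, run].max())
                for pos, cols in groups.items()
            }
            out[run] = sorted(score, key=lambda p: -score[p])
        return out


def _rank_ascending(importances: pd.Series) -> pd.Series:
    """Dense 1..n ranks, most important = n; ties broken by feature name."""
    order = sorted(importances.index, key=lambda c: (importances[c], c))
    return pd.Series(
        {name: i + 1 for i, name in enumerate(order)}, name=importances.name
    )


def impurity_rank_stats(
    matrix: FeatureMatrix,
    split: SplitIndex,
    seeds: Sequence[int],
    *,
    hyperparameters: Mapping | None = None,
    algorithm: str = "rf",
) -> ImportanceReport:
    """Train one forest per seed and summarize feature-importance ranks.

    Importance is the mean decrease in impurity of the trees; working with
    its ascending rank keeps runs comparable (the higher the importance,
    the higher the rank).
    """
    rank_cols = {}
    for seed in seeds:
        res = train(
            matrix,
            split,
            algorithm,
            hyperparameters=hyperparameters,
            seed=seed,
            compute_cv=False,
        )
        imp = pd.Series(
            res.estimator.feature_importances_, index=res.feature_names
        )
        rank_cols[f"seed_{seed}"] = _rank_ascending(imp)
    ranks = pd.DataFrame(rank_cols)
    prot = [c for c in ranks.index if _POS_COL_RE.match(c)]
    summary = pd.DataFrame(
        {
            "mean": ranks.loc[prot].mean(axis=1),
            "median": ranks.loc[prot].median(axis=1),
            "std": ranks.loc[prot].std(axis=1, ddof=1) if len(seeds) > 1 else 0.0,
        }
    ).sort_values("mean", ascending=False)
    return ImportanceReport(ranks=ranks, summary=summary, seeds=list(seeds))


# --------------------------------------------------------------------------
# method 2: exhaustive position ablation with retraining
# --------------------------------------------------------------------------


@dataclass
class AblationReport:
    """Model performance with each position removed / alone included.

    ``table`` is indexed by position number with columns
    ``r2_test_removed``/``mse_removed`` (position's Z-scales dropped) and
    ``r2_test_only``/``mse_only`` (that position the only protein
    information). ``baselines`` holds the all-positions reference, the
    no-positions floor, and optionally a caller-specified subset. Positions
    whose columns were constant (hence pruned from the matrix) reproduce
    the reference metrics exactly under removal.
    """

    table: pd.DataFrame
    baselines: dict[str, dict]
    hyperparameters: dict
    seed: int

    def position_ranking(self, by: str = "r2_test_only") -> list[int]:
        """Positions ordered by decreasing importance under the given view.

        ``r2_test_only``: add-one-back performance, higher = more
        important. ``r2_test_removed``: removal performance, lower = more
        important (the ordering is flipped accordingly).
        """
        asc = by == "r2_test_removed"
        col = self.table[by].sort_values(ascending=asc, kind="stable")
        return list(col.index)

    def drop_from_reference(self) -> pd.Series:
        """Reference test R^2 minus test R^2 with each position removed."""
        return self.baselines["all_positions"]["r2_test"] - self.table["r2_test_removed"]


def position_ablation(
    matrix: FeatureMatrix,
    split: SplitIndex,
    *,
    hyperparameters: Mapping | None = None,
    positions: Sequence[int] | None = None,
    subset: Sequence[int] | None = None,
    seed: int = 1,
    algorithm: str = "rf",
    with_q2: bool = False,
    include: Sequence[str] = ("removed", "only"),
) -> AblationReport:
    """Retrain with each binding-site position removed and alone included.

    All runs share the seed, the split, and the fixed hyperparameters (no
    grid search), so metric differences are attributable to the feature
    change alone. ``positions`` defaults to every position present in the
    matrix column names; ``subset`` additionally evaluates one model
    restricted to the given positions (e.g. a minimal important set);
    ``include`` restricts the per-position views computed ("removed",
    "only", or both).
    """
    if not set(include) <= {"removed", "only"}:
        raise ValueError("include entries must be 'removed' and/or 'only'")
    hp = dict(
        hyperparameters
        if hyperparameters is not None
        else DEFAULT_HYPERPARAMETERS.get(algorithm, {})
    )
    pos_cols_all = protein_feature_positions(matrix.X.columns)
    if positions is None:
        positions = sorted(pos_cols_all)
    lig_cols = matrix.ligand_columns

    def _metrics(fm: FeatureMatrix) -> dict:
        res = train(
            fm, split, algorithm, hyperparameters=hp, seed=seed,
            compute_cv=with_q2,
        )
        out = {
            "r2_test": res.metrics["r2_test"],
            "mse_test": res.metrics["mse_test"],
        }
        if with_q2:
            out["q2"] = res.metrics["q2_cv10"]
        return out

    baselines = {
        "all_positions": _metrics(matrix),
        "no_positions": _metrics(matrix.subset_columns(lig_cols)),
    }
    if subset is not None:
        keep = list(lig_cols) + [
            c for p in subset for c in pos_cols_all.get(p, [])
        ]
        baselines["subset"] = _metrics(matrix.subset_columns(keep))
        baselines["subset"]["positions"] = list(subset)

    rows = {}
    for pos in positions:
        cols = pos_cols_all.get(pos, [])
        row = {}
        if "removed" in include:
            removed = _metrics(matrix.drop_columns(cols)) if cols else dict(
                baselines["all_positions"]
            )
            row.update({f"{k}_removed": v for k, v in removed.items()})
        if "only" in include:
            only = _metrics(matrix.subset_columns(list(lig_cols) + cols))
            row.update({f"{k}_only": v for k, v in only.items()})
        rows[pos] = row
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("position")
    table = table.rename(
        columns={
            "r2_test_removed": "r2_test_removed",
            "mse_test_removed": "mse_removed",
            "r2_test_only": "r2_test_only",
            "mse_test_only": "mse_only",
            "q2_removed": "q2_removed",
            "q2_only": "q2_only",
        }
    )
    return AblationReport(
        table=table, baselines=baselines, hyperparameters=hp, seed=seed
    )


def shuffle_permutation_importance(
    result: ModelResult,
    matrix: FeatureMatrix,
    split: SplitIndex,
    *,
    positions: Sequence[int] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Value-shuffling permutation importance per position (comparison mode).

    Shuffles the three Z-scale columns of a position jointly across the
    test rows and reports the mean test-R^2 drop over repeats. No
    retraining is involved, unlike :func:`position_ablation`.
    """
    rng = np.random.default_rng(seed)
    pos_cols = protein_feature_positions(result.feature_names)
    if positions is None:
        positions = sorted(pos_cols)
    X_test = matrix.X.to_numpy(dtype=float)[split.test]
    y_test = matrix.y.to_numpy(dtype=float)[split.test]
    base = r2_score(y_test, result.estimator.predict(X_test))
    col_idx = {c: i for i, c in enumerate(result.feature_names)}
    rows = []
    for pos in positions:
        cols = [col_idx[c] for c in pos_cols.get(pos, [])]
        drops = []
        for _ in range(n_repeats):
            Xp = X_test.copy()
            perm = rng.permutation(len(Xp))
            for c in cols:
                Xp[:, c] = Xp[perm, c]
            drops.append(base - r2_score(y_test, result.estimator.predict(Xp)))
        rows.append(
            {
                "position": pos,
                "mean_r2_drop": float(np.mean(drops)) if cols else 0.0,
                "std_r2_drop": float(np.std(drops)) if cols else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "mean_r2_drop", ascending=False
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# strong-outlier census
# --------------------------------------------------------------------------


def outlier_census(
    matrix: FeatureMatrix,
    split: SplitIndex,
    seeds: Sequence[int],
    *,
    threshold: float = OUTLIER_THRESHOLD,
    hyperparameters: Mapping | None = None,
    algorithm: str = "rf",
) -> pd.DataFrame:
    """Count, per test datapoint, the randomized runs with |error| > threshold.

    One model per seed is trained on the same split; datapoints observed as
    strong outliers in at least one run are reported, sorted by the number
    of runs and then by the largest absolute error.
    """
    preds = []
    for seed in seeds:
        res = train(
            matrix, split, algorithm, hyperparameters=hyperparameters,
            seed=seed, compute_cv=False,
        )
        preds.append(res.y_pred_test)
    preds = np.vstack(preds)  # runs x test rows
    y_test = matrix.y.to_numpy(dtype=float)[split.test]
    errs = np.abs(y_test[None, :] - preds)
    times = (errs > threshold).sum(axis=0)
    meta = matrix.meta.iloc[split.test].reset_index(drop=True)
    rows = []
    for i in np.nonzero(times >= 1)[0]:
        rows.append(
            {
                "inchikey": meta.loc[i, "inchikey"],
                "target_id": meta.loc[i, "target_id"],
                "pic50_exp": float(y_test[i]),
                "pic50_pred_runs": [float(p) for p in preds[:, i]],
                "times_observed": int(times[i]),
                "max_abs_error": float(errs[:, i].max()),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "inchikey", "target_id", "pic50_exp", "pic50_pred_runs",
            "times_observed", "max_abs_error",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["times_observed", "max_abs_error"], ascending=False
        ).reset_index(drop=True)
    return df


# --------------------------------------------------------------------------
# selectivity
# --------------------------------------------------------------------------


@dataclass
class SelectivitySummary:
    """pIC_diff records and their aggregate quality metrics."""

    records: pd.DataFrame  # inchikey, target_1, target_2, delta_exp, delta_pred, pic_diff
    metrics: dict
    n_compounds: int

    @property
    def empty(self) -> bool:
        return len(self.records) == 0


def selectivity_eval(
    result: ModelResult, matrix: FeatureMatrix, split: SplitIndex
) -> SelectivitySummary:
    """Selectivity check on molecules confined to the test set.

    For every molecule with measurements against at least two targets and
    no row in training, each target pair (t1, t2), ordered by target id,
    contributes pIC_diff = (pIC_t1 - pIC_t2)_exp - (pIC_t1 - pIC_t2)_pred.
    Reported metrics are the R^2 and MSE of the predicted differences and
    the fractions of |pIC_diff| within 1 and 0.5 units.
    """
    train_keys = set(matrix.meta["inchikey"].to_numpy()[split.train])
    meta_test = matrix.meta.iloc[split.test].reset_index(drop=True)
    y_test = matrix.y.to_numpy(dtype=float)[split.test]
    pred_test = result.y_pred_test
    rows = []
    n_compounds = 0
    for ikey, grp in meta_test.groupby("inchikey", sort=True):
        if ikey in train_keys or grp["target_id"].nunique() < 2:
            continue
        n_compounds += 1
        per_target = {
            grp.loc[i, "target_id"]: (y_test[i], pred_test[i]) for i in grp.index
        }
        for t1, t2 in combinations(sorted(per_target), 2):
            d_exp = per_target[t1][0] - per_target[t2][0]
            d_pred = per_target[t1][1] - per_target[t2][1]
            rows.append(
                {
                    "inchikey": ikey,
                    "target_1": t1,
                    "target_2": t2,
                    "delta_exp": float(d_exp),
                    "delta_pred": float(d_pred),
                    "pic_diff": float(d_exp - d_pred),
                }
            )
    records = pd.DataFrame(
        rows,
        columns=["inchikey", "target_1", "target_2", "delta_exp", "delta_pred", "pic_diff"],
    )
    if records.empty:
        import warnings

        warnings.warn("no molecules with >=2 targets confined to the test set",
                      stacklevel=2)
        metrics = {}
    else:
        diffs = records["pic_diff"].abs()
        metrics = {
            "r2": float(r2_score(records["delta_exp"], records["delta_pred"]))
            if len(records) >= 2 and records["delta_exp"].nunique() > 1
            else float("nan"),
            "mse": float(
                mean_squared_error(records["delta_exp"], records["delta_pred"])
            ),
            "frac_within_1": float((diffs <= 1.0).mean()),
            "frac_within_05": float((diffs <= 0.5).mean()),
        }
    return SelectivitySummary(
        records=records, metrics=metrics, n_compounds=n_compounds
    )


# --------------------------------------------------------------------------
# in-silico point-mutant prediction
# --------------------------------------------------------------------------


def predict_for_profile(
    result: ModelResult,
    ligand_features: pd.Series,
    profile: ResidueProfile,
    positions: Sequence[Position],
    ztable: ZScaleTable,
) -> float:
    """Predict a compound's pIC50 against an arbitrary (e.g. mutated) pocket.

    The profile is Z-scale encoded, combined with the compound's ligand
    features, and reduced to the model's feature columns. Mutations at
    positions whose columns were pruned from the model cannot change the
    prediction by construction.
    """
    prot = encode_zscales(profile, positions, ztable)
    row = pd.concat([ligand_features, prot])
    row = row[~row.index.duplicated(keep="last")]
    missing = [c for c in result.feature_names if c not in row.index]
    if missing:
        raise KeyError(
            f"ligand features lack model columns: {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    x = row[result.feature_names].to_numpy(dtype=float)[None, :]
    return float(result.estimator.predict(x)[0])


def mutant_report(
    result: ModelResult,
    ligand_features: pd.Series,
    wild_type: ResidueProfile,
    mutations: Sequence[str],
    positions: Sequence[Position],
    ztable: ZScaleTable,
) -> pd.DataFrame:
    """Wild-type versus point-mutant predictions for one compound.

    Each row is a mutant (plus the wild type), with its predicted pIC50 and
    the shift from wild type. A mutation touching no position included in
    the model is flagged: its prediction equals the wild type's.
    """
    from .proteins import mutate, parse_mutation

    included = set(protein_feature_positions(result.feature_names))
    wt_pred = predict_for_profile(
        result, ligand_features, wild_type, positions, ztable
    )
    rows = [
        {
            "variant": "wt",
            "predicted_pic50": wt_pred,
            "shift_from_wt": 0.0,
            "mutated_position_in_model": True,
        }
    ]
    for mut in mutations:
        _, num, _ = parse_mutation(mut)
        prof = mutate(wild_type, mut)
        pred = predict_for_profile(result, ligand_features, prof, positions, ztable)
        in_model = num in included
        if not in_model:
            import warnings

            warnings.warn(
                f"mutation {mut} touches no model position; prediction equals wild type",
                stacklevel=2,
            )
        rows.append(
            {
                "variant": mut,
                "predicted_pic50": pred,
                "shift_from_wt": pred - wt_pred,
                "mutated_position_in_model": in_model,
            }
        )
    return pd.DataFrame(rows)
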