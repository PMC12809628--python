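"""PCM design-matrix assembly, stratified splitting, training, evaluation.

The proteochemometric design matrix concatenates a ligand feature block
(one row per molecule, joined by InChIKey) with the Z-scale encoding of the
target's binding site (identical for all rows of the same target). A
target-stratified 70/30 split keeps every target represented in training;
models are SVM (with location-scale standardization fitted on the training
rows only), random forest, gradient-boosted trees, and mean/median dummy
baselines. Q^2 is the mean of the ten cross-validation fold R^2 values on
the training rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, GroupKFold, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .ligands import LigandFeatureBlock
from .proteins import Position, ResidueProfile, ZScaleTable, protein_feature_frame

log = logging.getLogger(__name__)

ALGORITHMS = ("svm", "rf", "xgb", "dummy-mean", "dummy-median")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "rf": {"n_estimators": 300, "max_features": 0.3},
    "xgb": {"n_estimators": 400, "learning_rate": 0.1, "max_depth": 6},
    "svm": {"kernel": "rbf", "C": 10.0, "gamma": "scale", "epsilon": 0.1},
}

#: conventional small grids, overridable via config
DEFAULT_GRIDS: dict[str, dict] = {
    "rf": {
        "n_estimators": [100, 300, 500],
        "max_features": ["sqrt", 0.3],
    },
    "xgb": {
        "n_estimators": [200, 400],
        "learning_rate": [0.05, 0.1],
        "max_depth": [4, 6],
    },
    "svm": {
        "C": [1.0, 10.0, 100.0],
        "gamma": ["scale", 0.01],
        "epsilon": [0.1, 0.3],
    },
}


@dataclass
class FeatureMatrix:
    """Ligand block ++ protein block with a pIC50 response."""

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame  # inchikey, target_id per row
    ligand_columns: list[str]
    protein_columns: list[str]
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def targets(self) -> pd.Series:
        return self.meta["target_id"]

    def subset_columns(self, columns: Sequence[str]) -> "FeatureMatrix":
        cols = [c for c in self.X.columns if c in set(columns)]
        return FeatureMatrix(
            X=self.X[cols],
            y=self.y,
            meta=self.meta,
            ligand_columns=[c for c in self.ligand_columns if c in set(cols)],
            protein_columns=[c for c in self.protein_columns if c in set(cols)],
            dropped_constant=list(self.dropped_constant),
        )

    def drop_columns(self, columns: Sequence[str]) -> "FeatureMatrix":
        drop = set(columns)
        return self.subset_columns([c for c in self.X.columns if c not in drop])


def assemble(
    datapoints: pd.DataFrame,
    ligand_block: LigandFeatureBlock,
    profiles: Sequence[ResidueProfile],
    positions: Sequence[Position],
    ztable: ZScaleTable,
) -> FeatureMatrix:
    """Build the PCM matrix: one row per curated datapoint.

    ``datapoints`` needs columns inchikey, target_id, pic50; the ligand
    block must be indexed by InChIKey. Constant columns (over the rows
    actually present) are dropped and recorded, because they cannot inform
    the regression; this includes Z-scale columns of positions that do not
    vary across the targets in the data.
    """
    for col in ("inchikey", "target_id", "pic50"):
        if col not in datapoints.columns:
            raise ValueError(f"datapoints missing column {col!r}")
    missing_mols = sorted(
        set(datapoints["inchikey"]) - set(ligand_block.features.index)
    )
    if missing_mols:
        raise KeyError(f"inchikeys absent from ligand block: {missing_mols[:5]}"
                       f"{'...' if len(missing_mols) > 5 else ''}")
    prof_ids = {p.target_id for p in profiles}
    missing_tgts = sorted(set(datapoints["target_id"]) - prof_ids)
    if missing_tgts:
        raise KeyError(f"targets without residue profiles: {missing_tgts}")

    used = [p for p in profiles if p.target_id in set(datapoints["target_id"])]
    prot = protein_feature_frame(used, positions, ztable)
    lig = ligand_block.features.loc[datapoints["inchikey"]].reset_index(drop=True)
    prow = prot.loc[datapoints["target_id"]].reset_index(drop=True)
    X = pd.concat([lig, prow], axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in assembled matrix columns: {bad[:5]}")

    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if set(prot.columns) <= set(constant):
        warnings.warn(
            "protein block is constant across rows (single effective target); "
            "the model cannot learn any target dependence",
            stacklevel=2,
        )
    X = X.drop(columns=constant)
    return FeatureMatrix(
        X=X,
        y=datapoints["pic50"].reset_index(drop=True).astype(float),
        meta=datapoints[["inchikey", "target_id"]].reset_index(drop=True),
        ligand_columns=[c for c in ligand_block.feature_names if c in X.columns],
        protein_columns=[c for c in prot.columns if c in X.columns],
        dropped_constant=constant,
    )


@dataclass
class SplitIndex:
    """Target-stratified train/test row indices."""

    train: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def stratified_split(
    matrix: FeatureMatrix, fraction: float = 0.7, seed: int = 0
) -> SplitIndex:
    """Per-target split as close to ``fraction`` as integers allow.

    Targets contributing a single row go entirely to training so every
    target's protein features are seen during fitting.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for _, grp in matrix.meta.groupby("target_id", sort=True):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_train = max(1, int(round(fraction * len(idx))))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return SplitIndex(
        train=np.sort(np.asarray(train_idx, dtype=int)),
        test=np.sort(np.asarray(test_idx, dtype=int)),
        fraction=fraction,
        seed=seed,
    )


def _make_estimator(algorithm: str, hyperparams: Mapping, seed: int):
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hyperparams)
    if algorithm == "xgb":
        return XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, **hyperparams
        )
    if algorithm == "svm":
        # scaling lives inside the pipeline so its location/scale parameters
        # are fitted on the training rows only (no test leakage)
        return Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(**hyperparams))]
        )
    if algorithm == "dummy-mean":
        return DummyRegressor(strategy="mean")
    if algorithm == "dummy-median":
        return DummyRegressor(strategy="median")
    raise ValueError(f"unsupported algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class FoldPrediction:
    fold: int
    test_indices: np.ndarray  # positions within the training rows
    y_true: np.ndarray
    y_pred: np.ndarray

    @property
    def r2(self) -> float:
        return float(r2_score(self.y_true, self.y_pred))


@dataclass
class ModelResult:
    algorithm: str
    hyperparameters: dict
    seed: int
    metrics: dict
    fold_predictions: list[FoldPrediction]
    estimator: object
    feature_names: list[str]
    y_pred_train: np.ndarray
    y_pred_test: np.ndarray

    @property
    def fold_r2(self) -> list[float]:
        return [fp.r2 for fp in self.fold_predictions]

    @property
    def q2(self) -> float:
        return self.metrics["q2_cv10"]


def _cross_validate(
    estimator, X: np.ndarray, y: np.ndarray, *, folds: int, seed: int,
    groups: np.ndarray | None,
) -> list[FoldPrediction]:
    if groups is not None:
        splitter = GroupKFold(n_splits=folds)
        iterator = splitter.split(X, y, groups)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        iterator = splitter.split(X, y)
    out = []
    for k, (tr, te) in enumerate(iterator):
        est = clone(estimator)
        est.fit(X[tr], y[tr])
        out.append(
            FoldPrediction(
                fold=k, test_indices=te, y_true=y[te], y_pred=est.predict(X[te])
            )
        )
    return out


def train(
    matrix: FeatureMatrix,
    split: SplitIndex,
    algorithm: str = "rf",
    *,
    hyperparameters: Mapping | None = None,
    grid: Mapping | str | None = None,
    seed: int = 1,
    cv_folds: int = 10,
    group_cv_by_molecule: bool = False,
    compute_cv: bool = True,
) -> ModelResult:
    """Fit one model on the training rows and evaluate it.

    ``grid="default"`` (or an explicit parameter grid) runs a grid search
    scored by cross-validation on the training rows; otherwise the fixed
    ``hyperparameters`` (falling back to conventional defaults) are used.
    Cross-validation folds are random over rows by default; with
    ``group_cv_by_molecule`` folds are grouped by InChIKey so a molecule
    measured against several targets never straddles a fold boundary.
    """
    y = matrix.y.to_numpy(dtype=float)
    y_train = y[split.train]
    if np.all(y_train == y_train[0]):
        raise ValueError("training response is constant; nothing to fit")
    X = matrix.X.to_numpy(dtype=float)
    X_train, X_test = X[split.train], X[split.test]
    y_test = y[split.test]

    hp = dict(
        hyperparameters
        if hyperparameters is not None
        else DEFAULT_HYPERPARAMETERS.get(algorithm, {})
    )
    estimator = _make_estimator(algorithm, hp, seed)

    if grid is not None and algorithm not in ("dummy-mean", "dummy-median"):
        param_grid = DEFAULT_GRIDS[algorithm] if grid == "default" else dict(grid)
        if algorithm == "svm":
            param_grid = {f"svr__{k}": v for k, v in param_grid.items()}
        search = GridSearchCV(
            estimator, param_grid, scoring="r2",
            cv=KFold(5, shuffle=True, random_state=seed), n_jobs=1,
        )
        search.fit(X_train, y_train)
        estimator = search.best_estimator_
        best = {
            k.removeprefix("svr__"): v for k, v in search.best_params_.items()
        }
        hp.update(best)
    else:
        estimator.fit(X_train, y_train)

    folds: list[FoldPrediction] = []
    q2 = float("nan")
    if compute_cv and algorithm not in ("dummy-mean", "dummy-median"):
        groups = (
            matrix.meta["inchikey"].to_numpy()[split.train]
            if group_cv_by_molecule
            else None
        )
        n_folds = min(cv_folds, len(y_train))
        folds = _cross_validate(
            estimator, X_train, y_train, folds=n_folds, seed=seed, groups=groups
        )
        q2 = float(np.mean([fp.r2 for fp in folds]))

    y_pred_train = estimator.predict(X_train)
    y_pred_test = estimator.predict(X_test)
    metrics = {
        "r2_train": float(r2_score(y_train, y_pred_train)),
        "r2_test": float(r2_score(y_test, y_pred_test)) if len(y_test) > 1 else float("nan"),
        "mse_train": float(mean_squared_error(y_train, y_pred_train)),
        "mse_test": float(mean_squared_error(y_test, y_pred_test)) if len(y_test) else float("nan"),
        "q2_cv10": q2,
    }
    return ModelResult(
        algorithm=algorithm,
        hyperparameters=hp,
        seed=seed,
        metrics=metrics,
        fold_predictions=folds,
        estimator=estimator,
        feature_names=list(matrix.X.columns),
        y_pred_train=np.asarray(y_pred_train, dtype=float),
        y_pred_test=np.asarray(y_pred_test, dtype=float),
    )


def evaluate_per_target(
    result: ModelResult, matrix: FeatureMatrix, split: SplitIndex
) -> pd.DataFrame:
    """Test-set R^2, MSE, and the fractions of predictions within +/-1 and
    +/-0.5 pIC50 units, per target.

    R^2 is undefined (NaN) for targets with fewer than two test rows or a
    constant observed response; the fractions are always reported.
    """
    targets = matrix.targets.to_numpy()[split.test]
    y_true = matrix.y.to_numpy(dtype=float)[split.test]
    y_pred = result.y_pred_test
    rows = []
    for tgt in sorted(pd.unique(targets)):
        mask = targets == tgt
        yt, yp = y_true[mask], y_pred[mask]
        err = np.abs(yt - yp)
        r2 = (
            float(r2_score(yt, yp))
            if len(yt) >= 2 and np.ptp(yt) > 0
            else float("nan")
        )
        rows.append(
            {
                "target_id": tgt,
                "n_test": int(mask.sum()),
                "r2": r2,
                "mse": float(mean_squared_error(yt, yp)),
                "frac_within_1": float((err <= 1.0).mean()),
                "frac_within_05": float((err <= 0.5).mean()),
            }
        )
    return pd.DataFrame(rows)
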