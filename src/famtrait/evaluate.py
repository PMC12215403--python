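"""The replicated training/evaluation protocol.

One replicate = a fresh balanced holdout and stratified folds, feature
selection on the training partition only, a grid search scored by mean CV F1,
a final fit with the winning hyperparameters, pooled out-of-fold validation
predictions, and holdout-test predictions.  Replicates differ only through
their seed (``base_seed + r``); confusion matrices are row-normalized per
replicate before averaging, and the mean ROC is obtained by interpolating
each replicate's step ROC onto a fixed false-positive-rate grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import make_split
from .forest import ForestParams, fit_forest, grid_search, predict_proba, select_top_features
from .metrics import auc_pr, auc_roc, confusion_matrix, f1_score, precision_recall, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "evaluate_replicates", "FPR_GRID"]

FPR_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


@dataclass
class EvaluationReport:
    """Per-replicate metrics plus their across-replicate summaries.

    ``metrics`` has one row per replicate and partition ("validation" /
    "test") with F1, AUC-ROC, AUC-PR, precision and recall.  Validation
    scores pool the out-of-fold predictions of all folds before computing
    each metric (the per-fold average is also reported as
    ``auc_roc_fold_mean``).  ``mean_confusion`` is the across-replicate mean
    of row-normalized validation confusion matrices, so each row sums to 1.
    """

    metrics: pd.DataFrame
    mean_confusion: np.ndarray
    roc_fpr_grid: np.ndarray
    roc_tpr_mean: np.ndarray
    roc_tpr_sd: np.ndarray
    n_replicates: int
    selected_features: list = field(default_factory=list)
    best_params: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.metrics.groupby("partition").mean(numeric_only=True)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "n_replicates": self.n_replicates,
                    "metrics": self.metrics.to_dict(orient="records"),
                    "mean_confusion": self.mean_confusion.tolist(),
                    "roc_fpr_grid": self.roc_fpr_grid.tolist(),
                    "roc_tpr_mean": self.roc_tpr_mean.tolist(),
                    "roc_tpr_sd": self.roc_tpr_sd.tolist(),
                    "selected_features": [list(f) for f in self.selected_features],
                    "best_params": [p.to_dict() for p in self.best_params],
                },
                fh, indent=2,
            )


def _interp_roc(scores, labels, grid):
    fpr, tpr = roc_curve(scores, labels)
    return np.interp(grid, fpr, tpr)


def _partition_metrics(labels, scores, partition, replicate):
    preds = (np.asarray(scores) >= 0.5).astype(int)
    precision, recall = precision_recall(labels, preds)
    return {
        "replicate": replicate,
        "partition": partition,
        "f1": f1_score(labels, preds),
        "auc_roc": auc_roc(scores, labels),
        "auc_pr": auc_pr(scores, labels),
        "precision": precision,
        "recall": recall,
    }


def evaluate_replicates(
    table: pd.DataFrame,
    n_replicates: int = 100,
    holdout_frac: float = 0.1,
    k: int = 10,
    n_select: int = 50,
    grid: dict | None = None,
    selection_params: ForestParams = ForestParams(),
    base_seed: int = 0,
) -> EvaluationReport:
    """Run the full replicated protocol on a labelled instance table.

    Parameters
    ----------
    table : DataFrame
        Species x (families + 'class') instance table.
    grid : dict
        Hyperparameter grid for :func:`~famtrait.forest.grid_search`;
        ``None`` uses the package default
        ``{n_estimators: [100, 500], max_depth: [5, 10], max_features: ["sqrt"]}``.
    selection_params : ForestParams
        Hyperparameters of the feature-selection forest (fit on the training
        partition only, so the holdout never influences which families enter
        the model).
    """
    if grid is None:
        grid = {
            "n_estimators": [100, 500],
            "max_depth": [5, 10],
            "max_features": ["sqrt"],
        }
    y_all = table["class"]
    X_all = table.drop(columns="class")

    rows, confusions, tprs = [], [], []
    selected_all, best_all = [], []
    for r in range(n_replicates):
        seed = base_seed + r
        plan = make_split(table, holdout_frac=holdout_frac, k=k, seed=seed)
        train_species = plan.train_species
        X_train = X_all.loc[train_species]
        y_train = y_all.loc[train_species].to_numpy()

        selected = select_top_features(
            X_train, y_train, n_select=min(n_select, X_train.shape[1]),
            params=selection_params, seed=seed,
        )
        Xs_train = X_train.loc[:, selected]

        pos = {sp: i for i, sp in enumerate(train_species)}
        fold_idx = [np.array([pos[s] for s in fold]) for fold in plan.folds]
        # the winning cell's pooled out-of-fold scores ARE the validation
        # predictions (same folds, same seed), so no refit is needed
        best_params, _, val_scores = grid_search(
            Xs_train, y_train, fold_idx, grid, seed=seed, return_oof=True
        )

        final = fit_forest(Xs_train, y_train, params=best_params, seed=seed)
        X_test = X_all.loc[list(plan.test_species), selected]
        y_test = y_all.loc[list(plan.test_species)].to_numpy()
        test_scores = predict_proba(final, X_test)

        val_row = _partition_metrics(y_train, val_scores, "validation", r)
        fold_aucs = [
            auc_roc(val_scores[fold], y_train[fold])
            for fold in fold_idx
            if len(np.unique(y_train[fold])) == 2
        ]
        val_row["auc_roc_fold_mean"] = float(np.mean(fold_aucs)) if fold_aucs else np.nan
        rows.append(val_row)
        rows.append(_partition_metrics(y_test, test_scores, "test", r))

        confusions.append(
            confusion_matrix(y_train, (val_scores >= 0.5).astype(int),
                             normalize=True)
        )
        tprs.append(_interp_roc(val_scores, y_train, FPR_GRID))
        selected_all.append(selected)
        best_all.append(best_params)
        logger.info("replicate %d/%d done (seed %d)", r + 1, n_replicates, seed)

    tprs = np.asarray(tprs)
    return EvaluationReport(
        metrics=pd.DataFrame(rows),
        mean_confusion=np.mean(confusions, axis=0),
        roc_fpr_grid=FPR_GRID.copy(),
        roc_tpr_mean=tprs.mean(axis=0),
        roc_tpr_sd=tprs.std(axis=0),
        n_replicates=n_replicates,
        selected_features=selected_all,
        best_params=best_all,
    )
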