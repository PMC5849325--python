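"""Multi-seed, cross-validated evolutionary runs and their metrics.

Each random seed drives one 5-fold cross-validated run: a program is
evolved on four folds and scored on the held-out fold, so a batch of
``n_seeds`` runs yields ``n_seeds x 5`` best models, each with
leakage-free test metrics (MCE, sensitivity, specificity, AUC, ROC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .evolution import EvolutionConfig, evolve
from .lgp_core import (
    Program,
    effective_features,
    execute_matrix,
    program_from_json,
    program_to_json,
    sigmoid,
)
from .synthetic_data import Dataset

__all__ = [
    "FoldResult",
    "ModelCollection",
    "stratified_kfold",
    "holdout_metrics",
    "run_cv",
    "run_batch",
    "summarize",
    "fold_seed",
]

SUMMARY_ROWS = ("Mean", "Median", "Min", "Max", "Std dev",
                "5% confidence", "95% confidence")


def fold_seed(run_seed: int, fold: int) -> int:
    """Deterministic per-fold seed derived from the run seed (< 2^31)."""
    return (run_seed * 1_000_003 + fold * 7919 + 17) % (2**31)


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Class-stratified fold assignment: per-class fold sizes differ by
    at most one; folds partition the samples."""
    y = np.asarray(labels, dtype=int)
    n_case, n_ctrl = int((y == 1).sum()), int((y == 0).sum())
    if min(n_case, n_ctrl) < k:
        raise ValueError(f"need at least {k} samples per class, "
                         f"got {n_case} cases / {n_ctrl} controls")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = f
    return assignment


def scores_for(program: Program, X: np.ndarray) -> np.ndarray:
    return sigmoid(execute_matrix(program, X))


def holdout_metrics(program: Program, X: np.ndarray, y: np.ndarray) -> dict:
    """Held-out metrics at the 0.5 decision threshold plus the ROC.

    Sensitivity/specificity are None when the fold lacks the relevant
    class; AUC is None for a single-class fold.
    """
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty test fold")
    scores = scores_for(program, X)
    pred = (scores >= 0.5).astype(int)
    mce = float(np.mean(pred != y))
    pos, neg = y == 1, y == 0
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else None
    spec = float(np.mean(pred[neg] == 0)) if neg.any() else None
    if pos.any() and neg.any():
        fpr, tpr, _ = roc_curve(y, scores)
        auc = float(_trapezoid_auc(fpr, tpr))
        roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    else:
        auc, roc = None, None
    return {"mce": mce, "sensitivity": sens, "specificity": spec, "auc": auc, "roc": roc}


@dataclass
class FoldResult:
    seed: int
    fold: int
    program: Program
    train_mce: float
    metrics: dict
    test_index: list  # provenance: samples this model was scored on

    @property
    def effective_feature_indices(self) -> set[int]:
        return effective_features(self.program)


@dataclass
class ModelCollection:
    """The best-of-run models of a batch, with their held-out metrics."""

    models: list[FoldResult]
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.models)

    def effective_feature_names(self, model: FoldResult) -> set[str]:
        return {self.feature_names[i] for i in model.effective_feature_indices}

    def metric_values(self, key: str) -> list[float]:
        return [m.metrics[key] for m in self.models if m.metrics.get(key) is not None]

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"seed": m.seed, "fold": m.fold, "mce": m.metrics["mce"],
              "sensitivity": m.metrics["sensitivity"],
              "specificity": m.metrics["specificity"], "auc": m.metrics["auc"],
              "n_effective_features": len(m.effective_feature_indices)}
             for m in self.models])

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"feature_names": self.feature_names}) + "\n")
            for m in self.models:
                rec = {"seed": m.seed, "fold": m.fold, "train_mce": m.train_mce,
                       "metrics": {k: v for k, v in m.metrics.items() if k != "roc"},
                       "roc": m.metrics.get("roc"),
                       "test_index": list(m.test_index),
                       "program": program_to_json(m.program)}
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ModelCollection":
        with open(path) as fh:
            header = json.loads(fh.readline())
            models = []
            for line in fh:
                rec = json.loads(line)
                metrics = dict(rec["metrics"])
                metrics["roc"] = rec.get("roc")
                models.append(FoldResult(rec["seed"], rec["fold"],
                                         program_from_json(rec["program"]),
                                         rec["train_mce"], metrics,
                                         rec["test_index"]))
        return cls(models, header["feature_names"])


def run_cv(data: Dataset, config: EvolutionConfig, seed: int) -> list[FoldResult]:
    """One cross-validated run: evolve per fold, score on the held-out
    fold.  Fully deterministic given (data, config, seed)."""
    X, y = data.X, data.y
    assignment = stratified_kfold(y, config.n_folds, seed)
    results = []
    for f in range(config.n_folds):
        test_mask = assignment == f
        rng = np.random.default_rng(fold_seed(seed, f))
        best = evolve(X[~test_mask], y[~test_mask], config, rng)
        metrics = holdout_metrics(best.program, X[test_mask], y[test_mask])
        results.append(FoldResult(
            seed=seed, fold=f, program=best.program, train_mce=best.fitness,
            metrics=metrics,
            test_index=list(np.asarray(data.features.index)[test_mask])))
    return results


def run_batch(data: Dataset, config: EvolutionConfig, n_seeds: int,
              base_seed: int = 0) -> ModelCollection:
    """Independent runs with seeds base_seed+1 .. base_seed+n_seeds;
    the collection holds n_seeds x n_folds best models."""
    models: list[FoldResult] = []
    for s in range(1, n_seeds + 1):
        models.extend(run_cv(data, config, base_seed + s))
    return ModelCollection(models, data.feature_names)


def summarize(collection_or_frame) -> pd.DataFrame:
    """Summary table (mean/median/min/max/sd and mean +/- 1.96 sd rows)
    for the MCE/sensitivity/specificity/AUC columns."""
    if isinstance(collection_or_frame, ModelCollection):
        frame = collection_or_frame.metrics_frame()
    else:
        frame = pd.DataFrame(collection_or_frame)
    cols = [c for c in ("mce", "sensitivity", "specificity", "auc") if c in frame.columns]
    if frame.empty:
        raise ValueError("nothing to summarize")
    out = {}
    for c in cols:
        v = frame[c].dropna().to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        mean = float(np.mean(v))
        out[c] = [mean, float(np.median(v)), float(np.min(v)), float(np.max(v)),
                  sd, mean - 1.96 * sd, mean + 1.96 * sd]
    return pd.DataFrame(out, index=list(SUMMARY_ROWS))
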