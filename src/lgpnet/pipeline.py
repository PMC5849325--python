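"""End-to-end two-round procedure and the logistic-regression baseline.

Round one evolves models on the full feature set of the discovery
data, counts effective-feature occurrences and co-occurrences, builds
the synergy network from the top co-occurring pairs, and takes the
network's vertex set as the reduced feature set.  Round two re-runs
the evolutionary batch on the reduced columns of both the discovery
and replication data and reports the intersection of their top-20
occurrence rankings — the replicated key features.  A logistic
regression trained on the same folds serves as the linear baseline.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .evolution import EvolutionConfig
from .experiment import (
    ModelCollection,
    run_batch,
    stratified_kfold,
    summarize,
)
from .feature_analysis import (
    OccurrenceTable,
    count_occurrences,
    intersect_top,
    top_k,
)
from .network import build_network
from .synthetic_data import Dataset

__all__ = [
    "RoundReport",
    "stage_seed",
    "round_one",
    "round_two",
    "logistic_baseline",
    "run_two_round_pipeline",
]

logger = logging.getLogger("lgpnet")

_STAGES = {"round1": 1, "round2_discovery": 2, "round2_replication": 3,
           "baseline": 4, "split": 5, "generate": 6}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed schedule (always < 2^31)."""
    return (master_seed * 1_000_003 + _STAGES[stage] * 65_537) % (2**31)


@dataclass
class RoundReport:
    collection: ModelCollection
    summary: pd.DataFrame
    occurrence: OccurrenceTable
    top_features: pd.DataFrame
    top_pairs: pd.DataFrame
    network: Optional[nx.Graph] = None
    reduced_features: Optional[list[str]] = None   # round 1
    key_features: Optional[list[str]] = None       # round 2 intersection
    replication: Optional["RoundReport"] = None


def _analyze(collection: ModelCollection, top_n: int = 20) -> tuple:
    occ = count_occurrences(collection)
    return occ, top_k(occ, top_n, "features"), top_k(occ, top_n, "pairs")


def round_one(discovery: Dataset, config: EvolutionConfig, n_seeds: int,
              base_seed: int = 0, top_fraction: float = 0.01,
              denominator: str = "n_squared", top_n: int = 20) -> RoundReport:
    """Full-feature batch run, occurrence analysis and network; the
    reduced feature set is exactly the network's vertex set."""
    t0 = time.perf_counter()
    collection = run_batch(discovery, config, n_seeds, base_seed=base_seed)
    occ, feats, pairs = _analyze(collection, top_n)
    net = build_network(occ, top_fraction=top_fraction, denominator=denominator)
    reduced = sorted(net.nodes)
    logger.info("round 1: %d models, %d reduced features, %.1fs",
                len(collection), len(reduced), time.perf_counter() - t0)
    return RoundReport(collection, summarize(collection), occ, feats, pairs,
                       network=net, reduced_features=reduced)


def round_two(discovery: Dataset, replication: Dataset,
              reduced_features: Sequence[str], config: EvolutionConfig,
              n_seeds: int, base_seed: int = 0, top_n: int = 20) -> RoundReport:
    """Restricted-feature batch runs on both datasets; key features are
    the intersection of the two top-``top_n`` occurrence rankings,
    ordered by discovery rank."""
    if not reduced_features:
        raise ValueError("reduced feature set is empty")
    t0 = time.perf_counter()
    disc = discovery.subset_features(reduced_features)
    repl = replication.subset_features(reduced_features)
    col_d = run_batch(disc, config, n_seeds, base_seed=base_seed)
    col_r = run_batch(repl, config, n_seeds,
                      base_seed=stage_seed(base_seed, "round2_replication"))
    occ_d, feats_d, pairs_d = _analyze(col_d, top_n)
    occ_r, feats_r, pairs_r = _analyze(col_r, top_n)
    key = intersect_top(feats_d, feats_r, top_n)
    logger.info("round 2: 2x%d models, %d key features, %.1fs",
                len(col_d), len(key), time.perf_counter() - t0)
    repl_report = RoundReport(col_r, summarize(col_r), occ_r, feats_r, pairs_r)
    return RoundReport(col_d, summarize(col_d), occ_d, feats_d, pairs_d,
                       key_features=key, replication=repl_report)


def logistic_baseline(data: Dataset, feature_subset: Sequence[str],
                      seed: int, n_folds: int = 5, C: float = 1.0) -> dict:
    """Cross-validated logistic regression on the reduced feature set,
    using the same stratified fold assignment as an evolutionary run
    with the same seed (verifiable by fold hash).

    Returns per-fold AUC/ROC/MCE records, their mean AUC, and the fold
    assignment hash.  Non-converging folds are flagged and skipped.
    """
    ds = data.subset_features(feature_subset)
    X, y = ds.X, ds.y
    assignment = stratified_kfold(y, n_folds, seed)
    folds = []
    from sklearn.metrics import auc as _auc, roc_curve
    for f in range(n_folds):
        test = assignment == f
        clf = LogisticRegression(C=C, max_iter=2000)
        try:
            clf.fit(X[~test], y[~test])
        except Exception as exc:  # separation / non-convergence
            logger.warning("baseline fold %d skipped: %s", f, exc)
            folds.append({"fold": f, "skipped": True})
            continue
        scores = clf.predict_proba(X[test])[:, 1]
        pred = (scores >= 0.5).astype(int)
        fpr, tpr, _ = roc_curve(y[test], scores)
        folds.append({"fold": f, "skipped": False,
                      "mce": float(np.mean(pred != y[test])),
                      "auc": float(_auc(fpr, tpr)),
                      "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()}})
    aucs = [fo["auc"] for fo in folds if not fo.get("skipped")]
    return {"folds": folds,
            "mean_auc": float(np.mean(aucs)) if aucs else None,
            "best_auc": float(np.max(aucs)) if aucs else None,
            "fold_hash": int(hash(tuple(assignment.tolist())) % (2**31))}


def run_two_round_pipeline(discovery: Dataset, replication: Dataset,
                           config: EvolutionConfig, n_seeds: int,
                           master_seed: int = 0, top_fraction: float = 0.01,
                           denominator: str = "n_squared",
                           top_n: int = 20,
                           n_seeds_round2: int | None = None) -> dict:
    """The whole procedure from preprocessed splits to key features and
    baseline comparison; reproducible from (data, config, master_seed).

    ``n_seeds_round2`` defaults to ``n_seeds``; the restricted round-2
    search space is smaller, so fewer restarts may suffice there.
    """
    r1 = round_one(discovery, config, n_seeds,
                   base_seed=stage_seed(master_seed, "round1"),
                   top_fraction=top_fraction, denominator=denominator, top_n=top_n)
    if not r1.reduced_features:
        logger.warning("empty synergy network; skipping round 2")
        return {"round1": r1, "round2": None, "baseline": None}
    r2 = round_two(discovery, replication, r1.reduced_features, config,
                   n_seeds_round2 if n_seeds_round2 is not None else n_seeds,
                   base_seed=stage_seed(master_seed, "round2_discovery"), top_n=top_n)
    # the baseline reuses the fold partition of the first round-2 run per dataset
    baseline = {
        "discovery": logistic_baseline(discovery, r1.reduced_features,
                                       stage_seed(master_seed, "round2_discovery") + 1,
                                       config.n_folds),
        "replication": logistic_baseline(
            replication, r1.reduced_features,
            stage_seed(stage_seed(master_seed, "round2_discovery"),
                       "round2_replication") + 1,
            config.n_folds),
    }
    return {"round1": r1, "round2": r2, "baseline": baseline}
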