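"""Occurrence and co-occurrence statistics of effective features.

Across a collection of best-of-run models, each model contributes a
*set* of effective features (introns never count, and repeats within a
model count once).  Singleton occurrence and unordered-pair
co-occurrence frequencies over the collection are the raw material for
the synergy network and the top-k rankings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import ModelCollection

__all__ = [
    "OccurrenceTable",
    "count_occurrences",
    "top_k",
    "fitness_feature_correlation",
    "intersect_top",
]


@dataclass
class OccurrenceTable:
    """Per-feature and per-pair membership counts over a model collection.

    ``features``: DataFrame(feature, count, frequency);
    ``pairs``: DataFrame(feature_a, feature_b, count, frequency) with
    feature_a < feature_b (one row per unordered pair);
    frequencies are counts divided by the number of models.
    """

    features: pd.DataFrame
    pairs: pd.DataFrame
    n_models: int
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_csv(self, feature_path, pair_path) -> None:
        self.features.to_csv(feature_path, index=False)
        self.pairs.to_csv(pair_path, index=False)


def count_occurrences(models: ModelCollection) -> OccurrenceTable:
    """Count, per feature and per unordered pair, in how many models it
    appears as effective; a model with an empty effective set
    contributes nothing."""
    if len(models) == 0:
        raise ValueError("empty model collection")
    singles: Counter = Counter()
    pairs: Counter = Counter()
    for m in models.models:
        feats = sorted(models.effective_feature_names(m))
        singles.update(feats)
        pairs.update(combinations(feats, 2))
    n = len(models)
    fdf = pd.DataFrame(
        [(f, c, c / n) for f, c in singles.items()],
        columns=["feature", "count", "frequency"],
    ).sort_values(["frequency", "feature"], ascending=[False, True], ignore_index=True)
    pdf = pd.DataFrame(
        [(a, b, c, c / n) for (a, b), c in pairs.items()],
        columns=["feature_a", "feature_b", "count", "frequency"],
    ).sort_values(["frequency", "feature_a", "feature_b"],
                  ascending=[False, True, True], ignore_index=True)
    return OccurrenceTable(fdf, pdf, n, list(models.feature_names))


def top_k(table: OccurrenceTable, k: int, which: str = "features") -> pd.DataFrame:
    """Top-k rows by descending frequency; ties broken lexicographically
    by feature name so the ranking is deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if which == "features":
        return table.features.head(k).reset_index(drop=True)
    if which == "pairs":
        return table.pairs.head(k).reset_index(drop=True)
    raise ValueError(f"which must be 'features' or 'pairs', got {which!r}")


def fitness_feature_correlation(models: ModelCollection) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-model fitness
    (MCE) and effective-feature count."""
    mce = np.array([m.metrics["mce"] for m in models.models], dtype=float)
    nfeat = np.array([len(m.effective_feature_indices) for m in models.models], dtype=float)
    if len(mce) < 3:
        raise ValueError("need at least 3 models")
    if np.std(mce) == 0 or np.std(nfeat) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(mce, nfeat)
    return float(r), float(p)


def intersect_top(discovery: pd.DataFrame, replication: pd.DataFrame,
                  k: int) -> list[str]:
    """Features present in both top-k rankings, ordered by discovery rank."""
    disc = list(discovery["feature"].head(k))
    repl = set(replication["feature"].head(k))
    return [f for f in disc if f in repl]
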