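"""Case/control metabolomics data: container, generator, preprocessing.

The generator emulates the statistical structure of a targeted
metabolomics case/control study: log-normal base concentrations,
multiplicative batch effects, additive covariate (age/sex/BMI)
contributions, and disease labels drawn from a logistic model over a
small set of planted features — a few main effects plus feature groups
whose effect is purely synergistic (product interactions, or an
XOR-threshold rule with negligible marginal signal per member).

The preprocessing chain mirrors standard practice and runs in a fixed
order: mean-ratio batch correction, OLS covariate residualization, a
stratified discovery/replication split, then per-split z-scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SynergySpec",
    "SyntheticConfig",
    "generate",
    "batch_correct",
    "adjust_covariates",
    "split_discovery_replication",
    "normalize",
]

COVARIATE_COLUMNS = ("age", "sex", "bmi")


@dataclass
class Dataset:
    """A labeled sample-by-metabolite matrix with optional annotations.

    ``features``: DataFrame (samples x metabolites, unique named columns);
    ``labels``: int Series (1 = case, 0 = control) sharing the index;
    ``batch``: optional batch id per sample; ``covariates``: optional
    DataFrame with columns age (years), sex (0/1), bmi (kg/m^2).
    """

    features: pd.DataFrame
    labels: pd.Series
    batch: Optional[pd.Series] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the sample index")
        if self.features.isna().any().any():
            raise ValueError("missing values are not allowed")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    # -- convenience views ------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    def subset_features(self, names: Sequence[str]) -> "Dataset":
        missing = set(names) - set(self.features.columns)
        if missing:
            raise KeyError(f"features not in dataset: {sorted(missing)}")
        return Dataset(self.features[list(names)].copy(), self.labels.copy(),
                       None if self.batch is None else self.batch.copy(),
                       None if self.covariates is None else self.covariates.copy())

    def subset_samples(self, index) -> "Dataset":
        return Dataset(self.features.loc[index].copy(), self.labels.loc[index].copy(),
                       None if self.batch is None else self.batch.loc[index].copy(),
                       None if self.covariates is None else self.covariates.loc[index].copy())

    # -- CSV dialect ------------------------------------------------------
    def to_csv(self, path) -> None:
        out = pd.DataFrame({"sample_id": self.features.index, "label": self.labels.values})
        if self.batch is not None:
            out["batch"] = self.batch.values
        if self.covariates is not None:
            for c in COVARIATE_COLUMNS:
                out[c] = self.covariates[c].values
        for col in self.features.columns:
            out[col] = self.features[col].values
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        df = df.set_index("sample_id")
        labels = df.pop("label").astype(int)
        batch = df.pop("batch") if "batch" in df.columns else None
        cov = None
        if set(COVARIATE_COLUMNS) <= set(df.columns):
            cov = df[list(COVARIATE_COLUMNS)].copy()
            df = df.drop(columns=list(COVARIATE_COLUMNS))
        return cls(df.astype(float), labels, batch, cov)


@dataclass(frozen=True)
class SynergySpec:
    """A planted interaction: feature indices, its functional form
    ("product" or "xor"), and the log-odds coefficient."""

    indices: tuple[int, ...]
    form: str  # "product" | "xor"
    coefficient: float

    def __post_init__(self) -> None:
        if self.form not in ("product", "xor"):
            raise ValueError(f"unknown synergy form {self.form!r}")
        if self.form == "xor" and len(self.indices) != 2:
            raise ValueError("xor synergy takes exactly two features")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative recipe.  Defaults emulate a 153-case / 236-control
    cohort measured on a 167-metabolite targeted panel in 3 batches."""

    n_cases: int = 153
    n_controls: int = 236
    n_features: int = 167
    n_batches: int = 3
    batch_scale: float = 0.15          # sd of log multiplicative batch factor
    covariate_effect_scale: float = 0.3  # sd of per-feature covariate coefs
    noise_scale: float = 0.3           # sd of per-feature log-concentration
    main_effects: dict = field(default_factory=lambda: {0: 0.9, 1: -0.7, 2: 0.5})
    synergies: tuple[SynergySpec, ...] = (
        SynergySpec((3, 4), "product", 1.5),
        SynergySpec((5, 6), "xor", 2.0),
    )

    def __post_init__(self) -> None:
        planted: list[int] = list(self.main_effects)
        for s in self.synergies:
            planted.extend(s.indices)
        if len(planted) != len(set(planted)):
            raise ValueError("planted feature indices must be disjoint")
        if planted and max(planted) >= self.n_features:
            raise ValueError("planted feature index out of range")

    @property
    def planted_indices(self) -> list[int]:
        out = sorted(self.main_effects)
        for s in self.synergies:
            out.extend(s.indices)
        return out


def _feature_names(n: int) -> list[str]:
    return [f"M{i:03d}" for i in range(n)]


def _planted_logits(Z: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Linear predictor (without intercept) of the label model, over the
    standardized latent signal matrix Z."""
    eta = np.zeros(Z.shape[0])
    for idx, beta in config.main_effects.items():
        eta += beta * Z[:, idx]
    for syn in config.synergies:
        if syn.form == "product":
            eta += syn.coefficient * np.prod(Z[:, list(syn.indices)], axis=1)
        else:  # xor: +coef iff exactly one member above its median
            i, j = syn.indices
            above_i = Z[:, i] > np.median(Z[:, i])
            above_j = Z[:, j] > np.median(Z[:, j])
            eta += syn.coefficient * np.where(above_i ^ above_j, 1.0, -1.0)
    return eta


def generate(config: SyntheticConfig, rng: np.random.Generator) -> tuple[Dataset, dict]:
    """Draw a dataset plus a truth record of the planted effects.

    Concentrations are built as exp(mu_f + noise) x batch factor + covariate
    terms; labels come from a logistic model over the standardized latent
    (pre-batch, pre-covariate) values of the planted features, with the
    intercept calibrated so the expected case fraction matches the
    requested one, then rejection-sampled to the exact counts.
    """
    n_target = config.n_cases + config.n_controls
    target_frac = config.n_cases / n_target
    names = _feature_names(config.n_features)

    # per-feature log-scale location, shared across the pool
    mu = rng.normal(1.0, 0.5, size=config.n_features)

    for _attempt in range(5):
        n_pool = max(4 * n_target, 400)
        noise = rng.normal(0.0, config.noise_scale, size=(n_pool, config.n_features))
        latent = mu + noise                      # log-concentration signal
        Z = (latent - latent.mean(axis=0)) / latent.std(axis=0)
        eta = _planted_logits(Z, config)

        # calibrate the intercept by bisection on the empirical mean probability
        lo, hi = -30.0, 30.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if np.mean(1.0 / (1.0 + np.exp(-(eta + mid)))) < target_frac:
                lo = mid
            else:
                hi = mid
        labels_pool = (rng.random(n_pool) < 1.0 / (1.0 + np.exp(-(eta + (lo + hi) / 2)))).astype(int)

        case_idx = np.flatnonzero(labels_pool == 1)
        ctrl_idx = np.flatnonzero(labels_pool == 0)
        if len(case_idx) >= config.n_cases and len(ctrl_idx) >= config.n_controls:
            break
    else:
        raise RuntimeError("could not reach the requested case/control balance")

    keep = np.concatenate([case_idx[: config.n_cases], ctrl_idx[: config.n_controls]])
    keep = rng.permutation(keep)
    n = len(keep)

    conc = np.exp(latent[keep])
    labels = labels_pool[keep]

    batch = rng.integers(config.n_batches, size=n)
    batch_factor = np.exp(rng.normal(0.0, config.batch_scale,
                                     size=(config.n_batches, config.n_features)))
    conc = conc * batch_factor[batch]

    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.integers(2, size=n).astype(float)
    bmi = rng.normal(28.0, 4.0, size=n)
    cov = np.column_stack([(age - 60.0) / 10.0, sex - 0.5, (bmi - 28.0) / 4.0])
    # covariate effects scale with each metabolite's own spread so that
    # low-abundance features are not drowned by nuisance variation
    cov_coefs = rng.normal(0.0, config.covariate_effect_scale,
                           size=(3, config.n_features)) * conc.std(axis=0)
    conc = conc + cov @ cov_coefs

    index = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    ds = Dataset(
        features=pd.DataFrame(conc, index=index, columns=names),
        labels=pd.Series(labels, index=index, name="label"),
        batch=pd.Series(batch, index=index, name="batch"),
        covariates=pd.DataFrame({"age": age, "sex": sex, "bmi": bmi}, index=index),
    )
    truth = {
        "main_effects": {names[i]: float(b) for i, b in config.main_effects.items()},
        "synergies": [
            {"features": [names[i] for i in s.indices], "form": s.form,
             "coefficient": s.coefficient}
            for s in config.synergies
        ],
    }
    return ds, truth


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# preprocessing chain (fixed order: batch -> covariates -> split -> normalize)


def batch_correct(data: Dataset) -> Dataset:
    """Rescale each (feature, batch) cell by overall mean / batch mean."""
    if data.batch is None:
        raise ValueError("dataset has no batch labels")
    X = data.features.copy()
    overall = X.mean(axis=0)
    for b, idx in X.groupby(data.batch).groups.items():
        bmean = X.loc[idx].mean(axis=0)
        tiny = bmean.abs() < 1e-12
        if tiny.any():
            raise ValueError(
                f"batch {b}: near-zero batch mean for {list(bmean.index[tiny])}")
        X.loc[idx] = X.loc[idx] * (overall / bmean)
    return Dataset(X, data.labels.copy(), data.batch.copy(),
                   None if data.covariates is None else data.covariates.copy())


def adjust_covariates(data: Dataset) -> Dataset:
    """Replace each feature by its OLS residual on [1, age, sex, bmi]."""
    if data.covariates is None:
        raise ValueError("dataset has no covariates")
    C = data.covariates[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    D = np.column_stack([np.ones(len(C)), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear covariate design")
    Y = data.X
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    X = pd.DataFrame(resid, index=data.features.index, columns=data.features.columns)
    return Dataset(X, data.labels.copy(),
                   None if data.batch is None else data.batch.copy(),
                   data.covariates.copy())


def split_discovery_replication(data: Dataset,
                                rng: np.random.Generator) -> tuple[Dataset, Dataset]:
    """Random halves with cases and controls each divided as evenly as
    possible; disjoint and exhaustive."""
    y = data.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two samples per class to split")
    disc_rows: list[int] = []
    repl_rows: list[int] = []
    for cls in (1, 0):
        rows = np.flatnonzero(y == cls)
        rows = rng.permutation(rows)
        half = (len(rows) + 1) // 2
        disc_rows.extend(rows[:half])
        repl_rows.extend(rows[half:])
    disc = data.subset_samples(data.features.index[sorted(disc_rows)])
    repl = data.subset_samples(data.features.index[sorted(repl_rows)])
    return disc, repl


def normalize(data: Dataset) -> Dataset:
    """Per-feature z-score (mean 0, unit sample variance, n-1 denominator)."""
    X = data.features
    std = X.std(axis=0, ddof=1)
    dead = std < 1e-12
    if dead.any():
        raise ValueError(f"zero-variance features: {list(std.index[dead])}")
    Xz = (X - X.mean(axis=0)) / std
    return Dataset(Xz, data.labels.copy(),
                   None if data.batch is None else data.batch.copy(),
                   None if data.covariates is None else data.covariates.copy())
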