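"""Dataset splitting, k-fold cross-validation, and exhaustive grid search.

The hyperparameter grid spans four optimizers (sgd, rmsprop, adam,
adadelta), four learning rates (0.001, 0.01, 0.005, 0.05), and three batch
sizes (32, 64, 128) — 48 cells.  Each cell is scored by the mean validation
MSE over k folds; the best cell attains the minimal mean, ties broken by
lower SD and then grid order.

Splitting uses floor rounding on both the train and the test fraction with
any remainder discarded, then carves the validation set out of the train
share.  Splits are segment-level by default; subject-level splitting (the
methodologically safer option when segments of one subject are highly
correlated) is available via ``subject_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .models import ModelSpec, TrainConfig, build_model, predict_bp, train_model
from .optimizers import OPTIMIZER_IDS

__all__ = [
    "HyperParams",
    "GridSearchResult",
    "DEFAULT_LEARNING_RATES",
    "DEFAULT_BATCH_SIZES",
    "split_dataset",
    "kfold_indices",
    "enumerate_grid",
    "grid_search",
]

DEFAULT_LEARNING_RATES = (0.001, 0.01, 0.005, 0.05)
DEFAULT_BATCH_SIZES = (32, 64, 128)


@dataclass(frozen=True)
class HyperParams:
    optimizer: str
    learning_rate: float
    batch_size: int


@dataclass
class GridSearchResult:
    table: pd.DataFrame          # one row per cell: fold scores, mean, sd, rank
    best: HyperParams
    seed: int
    runs: int                    # number of training runs performed


def split_dataset(
    n_segments: int,
    train_fraction: float = 0.8,
    test_fraction: float = 0.2,
    val_fraction_of_train: float = 0.2,
    seed: int = 0,
    subject_ids=None,
):
    """Disjoint (train, validation, test) index arrays.

    ``|train+val| = floor(train_fraction * n)`` and ``|test| =
    floor(test_fraction * n)``; leftover indices are discarded.  The
    validation set is ``floor(val_fraction_of_train * |train+val|)`` indices
    carved from the train share.  With ``subject_ids`` given, whole subjects
    are assigned to one side of the train/test divide (sizes then only
    approximate the fractions).
    """
    for frac in (train_fraction, test_fraction, val_fraction_of_train):
        if not 0 < frac < 1:
            raise InvalidArgumentError("fractions must lie in (0, 1)")
    if train_fraction + test_fraction > 1 + 1e-12:
        raise InvalidArgumentError("train_fraction + test_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * n_segments))
    n_test = int(np.floor(test_fraction * n_segments))
    n_val = int(np.floor(val_fraction_of_train * n_train))
    if n_val == 0 or n_train - n_val == 0 or n_test == 0:
        raise InvalidArgumentError("n_segments too small for three nonempty sets")

    if subject_ids is None:
        ids = rng.permutation(n_segments)
        train_all = ids[:n_train]
        test = ids[n_train : n_train + n_test]
    else:
        subject_ids = np.asarray(subject_ids)
        if len(subject_ids) != n_segments:
            raise InvalidArgumentError("subject_ids length must equal n_segments")
        subjects = rng.permutation(np.unique(subject_ids))
        train_all = []
        for s in subjects:
            idx = np.flatnonzero(subject_ids == s)
            if len(train_all) + len(idx) <= n_train:
                train_all.extend(idx)
        train_all = np.asarray(train_all, dtype=int)
        rest = np.setdiff1d(np.arange(n_segments), train_all)
        test = rng.permutation(rest)[:n_test]
        n_val = int(np.floor(val_fraction_of_train * len(train_all)))
        if n_val == 0 or len(train_all) - n_val == 0 or len(test) == 0:
            raise InvalidArgumentError("n_segments too small for three nonempty sets")
    val = train_all[:n_val]
    train = train_all[n_val:]
    return train, val, test


def kfold_indices(n: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint validation folds partitioning 0..n-1, sizes differing by <= 1."""
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if n < k:
        raise InvalidArgumentError("need n >= k")
    perm = np.random.default_rng(seed).permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = []
    start = 0
    for size in sizes:
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return folds


def enumerate_grid(
    optimizers=OPTIMIZER_IDS,
    learning_rates=DEFAULT_LEARNING_RATES,
    batch_sizes=DEFAULT_BATCH_SIZES,
) -> list[HyperParams]:
    """Cartesian product in (optimizer, learning_rate, batch_size) order."""
    if not optimizers or not learning_rates or not batch_sizes:
        raise InvalidArgumentError("grid axes must be nonempty")
    return [
        HyperParams(o, lr, int(b))
        for o, lr, b in product(optimizers, learning_rates, batch_sizes)
    ]


def _default_train_fn(architecture: str, budget: TrainConfig | None, spec: ModelSpec | None):
    spec = spec or ModelSpec(architecture=architecture)
    base = budget or TrainConfig(max_epochs=10, early_stop_patience=3)

    def run(cell: HyperParams, train_data, val_data, fold_seed: int) -> float:
        config = TrainConfig(
            optimizer=cell.optimizer,
            learning_rate=cell.learning_rate,
            batch_size=cell.batch_size,
            max_epochs=base.max_epochs,
            early_stop_patience=base.early_stop_patience,
            seed=fold_seed,
        )
        model = build_model(spec, seed=fold_seed)
        trained = train_model(model, train_data, val_data, config, spec=spec)
        X_val, y_val = val_data
        pred = predict_bp(trained, np.asarray(X_val))
        return float(np.mean((pred - np.asarray(y_val)) ** 2))

    return run


def grid_search(
    architecture: str,
    X,
    y,
    grid: list[HyperParams] | None = None,
    k: int = 5,
    budget: TrainConfig | None = None,
    seed: int = 0,
    spec: ModelSpec | None = None,
    train_fn=None,
) -> GridSearchResult:
    """Score every grid cell by k-fold cross-validated validation MSE.

    ``train_fn(cell, (X_tr, y_tr), (X_va, y_va), fold_seed) -> val_mse`` may
    be injected (tests use a stub); by default each cell trains ``k`` models
    of ``architecture`` under a reduced epoch budget.  A cell whose training
    raises a training failure is kept with an infinite score and the search
    continues.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if grid is None:
        grid = enumerate_grid()
    if not grid:
        raise InvalidArgumentError("grid must be nonempty")
    if len(X) < k:
        raise InvalidArgumentError("need at least k segments")
    folds = kfold_indices(len(X), k, seed)
    all_idx = np.arange(len(X))
    if train_fn is None:
        train_fn = _default_train_fn(architecture, budget, spec)

    rows = []
    runs = 0
    for cell_order, cell in enumerate(grid):
        scores = []
        for fold_id, val_idx in enumerate(folds):
            tr_idx = np.setdiff1d(all_idx, val_idx)
            runs += 1
            try:
                score = float(
                    train_fn(
                        cell,
                        (X[tr_idx], y[tr_idx]),
                        (X[val_idx], y[val_idx]),
                        seed + fold_id,
                    )
                )
            except Exception:
                score = np.inf
            scores.append(score)
        scores = np.asarray(scores)
        finite = np.all(np.isfinite(scores))
        rows.append(
            {
                "optimizer": cell.optimizer,
                "learning_rate": cell.learning_rate,
                "batch_size": cell.batch_size,
                **{f"fold{i}": s for i, s in enumerate(scores)},
                "mean_mse": float(np.mean(scores)) if finite else np.inf,
                "sd_mse": float(np.std(scores, ddof=1)) if finite and k > 1 else np.nan,
                "order": cell_order,
            }
        )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        ["mean_mse", "sd_mse", "order"], na_position="last", kind="stable"
    )
    table["rank"] = 0
    table.loc[ranked.index, "rank"] = np.arange(1, len(table) + 1)
    best_row = ranked.iloc[0]
    best = HyperParams(
        str(best_row["optimizer"]),
        float(best_row["learning_rate"]),
        int(best_row["batch_size"]),
    )
    return GridSearchResult(table=table, best=best, seed=seed, runs=runs)
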