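"""Feedforward network regression with back-propagation, from scratch.

A single-hidden-layer network (tanh hidden units, linear output) is
trained by full-batch gradient descent with momentum on the mean squared
error, with early stopping on a validation partition.  Samples are split
70/15/15 into training / validation / test sets.  Model quality is
reported as the published determination coefficient

    R2 = 1 - sum (W_i - W_i1)^2 / sum (W_i - W_i2)^2,

where W_i is the *predicted* intensity, W_i1 the actual value and W_i2
the mean of the predictions — note the denominator centres on the mean
of the predictions, not of the actuals, so this only coincides with the
conventional coefficient of determination when the predictor is unbiased
(:func:`conventional_r_squared` is provided for comparison) — and as the
mean squared error MSE = (1/N) sum (T_i - Y_i)^2 in original target
units.  :func:`screen_combinations` trains one network per factor
combination and ranks them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import COMBINATIONS, COMBO_FEATURE_ORDER, select_combination, standardize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes and weight-initialisation seed."""

    n_input: int
    n_hidden: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.n_input < 1:
            raise ValueError("layer sizes must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 3000
    learning_rate: float = 0.05
    momentum: float = 0.9
    patience: int = 20
    min_delta: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.fractions) <= 0:
            raise ValueError("split fractions must be positive")
        if self.max_epochs < 1 or self.learning_rate <= 0 or self.patience < 1:
            raise ValueError("invalid training configuration")


@dataclass
class FitResult:
    combo_id: str | None
    r2: float  # published-form R2 on the test partition
    mse: float  # test MSE in original target units
    metrics: dict  # per-partition r2/mse
    history: list[tuple[float, float]]  # (train MSE, validation MSE) per epoch
    weights: dict  # W1, b1, W2, b2 (on standardized scales)
    feature_columns: list[str]
    target_mean: float
    target_std: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict targets (original units) from standardized features."""
        h = np.tanh(X @ self.weights["W1"] + self.weights["b1"])
        z = h @ self.weights["W2"] + self.weights["b2"]
        return z.ravel() * self.target_std + self.target_mean


# -- metrics --------------------------------------------------------------

def r_squared(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Published determination coefficient (denominator centred on the
    prediction mean).  Rejects constant predictions (zero denominator)."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if predicted.shape != actual.shape or predicted.size < 2:
        raise ValueError("predicted/actual must be equal-length vectors of size >= 2")
    denom = float(np.sum((predicted - predicted.mean()) ** 2))
    if denom == 0:
        raise ValueError("R2 undefined for constant predictions")
    return 1.0 - float(np.sum((predicted - actual) ** 2)) / denom


def conventional_r_squared(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Conventional coefficient of determination (denominator centred on
    the mean of the actual values)."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    denom = float(np.sum((actual - actual.mean()) ** 2))
    if denom == 0:
        raise ValueError("R2 undefined for constant actuals")
    return 1.0 - float(np.sum((actual - predicted) ** 2)) / denom


def mse(expected: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared error between expected and actual values."""
    expected = np.asarray(expected, float)
    actual = np.asarray(actual, float)
    if expected.shape != actual.shape:
        raise ValueError(f"length mismatch: {expected.shape} vs {actual.shape}")
    if expected.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((expected - actual) ** 2))


# -- data split -----------------------------------------------------------

def split_data(
    n: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled disjoint train/validation/test index sets.

    Training and validation sizes are rounded half-up from the fractions;
    the test set takes the remainder, so the three always partition
    0..n-1.  With n = 780 at 70/15/15 this gives 546/117/117.
    """
    if n < 3:
        raise ValueError("need n >= 3 for three nonempty partitions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(n * fractions[0] + 0.5))
    n_val = int(np.floor(n * fractions[1] + 0.5))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for nonempty partitions at {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


# -- training -------------------------------------------------------------

def _forward(X, W1, b1, W2, b2):
    h = np.tanh(X @ W1 + b1)
    return h, h @ W2 + b2


def train(
    table: pd.DataFrame,
    spec: NetworkSpec | None = None,
    cfg: TrainConfig = TrainConfig(),
    combo_id: str | None = None,
) -> FitResult:
    """Fit the network on a feature table with a ``target`` column.

    Features are assumed already standardized; the target is standardized
    internally on the training partition and metrics are reported on the
    original target scale.  Fully reproducible from the configured seeds.
    """
    if "target" not in table:
        raise ValueError("table must contain a 'target' column")
    feature_cols = [c for c in table.columns if c != "target"]
    X = table[feature_cols].to_numpy(float)
    y = table["target"].to_numpy(float)
    n = len(table)
    if spec is None:
        spec = NetworkSpec(n_input=len(feature_cols), seed=cfg.seed)
    if spec.n_input != len(feature_cols):
        raise ValueError(f"spec.n_input={spec.n_input} but table has {len(feature_cols)} features")
    idx_tr, idx_va, idx_te = split_data(n, cfg.fractions, cfg.seed)

    t_mean = float(y[idx_tr].mean())
    t_std = float(y[idx_tr].std(ddof=1))
    if t_std == 0:
        t_std = 1.0
    ys = (y - t_mean) / t_std

    rng = np.random.default_rng(spec.seed)
    W1 = rng.uniform(-1, 1, (spec.n_input, spec.n_hidden)) / np.sqrt(spec.n_input)
    b1 = np.zeros(spec.n_hidden)
    W2 = rng.uniform(-1, 1, (spec.n_hidden, 1)) / np.sqrt(spec.n_hidden)
    b2 = np.zeros(1)
    vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]

    Xtr, ytr = X[idx_tr], ys[idx_tr].reshape(-1, 1)
    Xva, yva = X[idx_va], ys[idx_va].reshape(-1, 1)
    best = None
    best_val = np.inf
    wait = 0
    history: list[tuple[float, float]] = []
    m = len(Xtr)
    for epoch in range(cfg.max_epochs):
        h, z = _forward(Xtr, W1, b1, W2, b2)
        err = z - ytr
        train_mse = float(np.mean(err**2))
        if not np.isfinite(train_mse):
            raise FloatingPointError(
                f"NaN/inf training loss at epoch {epoch}; learning_rate={cfg.learning_rate}"
            )
        gz = 2.0 * err / m
        gW2 = h.T @ gz
        gb2 = gz.sum(axis=0)
        gh = gz @ W2.T * (1.0 - h**2)
        gW1 = Xtr.T @ gh
        gb1 = gh.sum(axis=0)
        for p, v, g in zip((W1, b1, W2, b2), vel, (gW1, gb1, gW2, gb2)):
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            p += v
        _, zva = _forward(Xva, W1, b1, W2, b2)
        val_mse = float(np.mean((zva - yva) ** 2))
        history.append((train_mse, val_mse))
        if val_mse < best_val - cfg.min_delta:
            best_val = val_mse
            best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    if best is not None:
        W1, b1, W2, b2 = best
    weights = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}

    metrics: dict[str, dict[str, float]] = {}
    for name, idx in (("train", idx_tr), ("validation", idx_va), ("test", idx_te)):
        _, zp = _forward(X[idx], W1, b1, W2, b2)
        pred = zp.ravel() * t_std + t_mean
        part: dict[str, float] = {"mse": mse(y[idx], pred)}
        try:
            part["r2"] = r_squared(pred, y[idx])
        except ValueError:
            part["r2"] = np.nan
        metrics[name] = part
    return FitResult(
        combo_id=combo_id,
        r2=metrics["test"]["r2"],
        mse=metrics["test"]["mse"],
        metrics=metrics,
        history=history,
        weights=weights,
        feature_columns=feature_cols,
        target_mean=t_mean,
        target_std=t_std,
    )


# -- combination screening ------------------------------------------------

def screen_combinations(
    table: pd.DataFrame,
    combos: Sequence[str] | None = None,
    cfg: TrainConfig = TrainConfig(),
    n_hidden: int = 10,
    aspect_encoding: str = "sincos",
) -> pd.DataFrame:
    """Train one network per factor combination and rank them.

    ``table`` holds the eight raw features plus ``target``.  For each
    combination the relevant columns are selected, standardized, and a
    network is trained with a seed derived from the shared schedule
    (cfg.seed + combination index), so the whole screen is reproducible.
    Returns one row per combination with inclusion flags, R2 and MSE
    (test partition), with the best model flagged — highest R2, ties
    broken by lowest MSE then lowest combination index.
    """
    combos = list(combos) if combos is not None else list(COMBINATIONS)
    rows = []
    results: dict[str, FitResult] = {}
    for k, combo in enumerate(combos):
        sub = select_combination(table, combo, aspect_encoding=aspect_encoding)
        feat_cols = [c for c in sub.columns if c != "target"]
        # a constant feature (e.g. segment duration at a fixed fix interval)
        # carries no information and cannot be z-scored; drop it
        constant = [c for c in feat_cols if sub[c].std(ddof=1) <= 0]
        if constant:
            logger.info("screen %s: dropping constant feature(s) %s", combo, constant)
            feat_cols = [c for c in feat_cols if c not in constant]
            sub = sub[feat_cols + (["target"] if "target" in sub else [])]
        if not feat_cols:
            raise ValueError(f"combination {combo} has no non-constant features")
        sub_std, _ = standardize(sub, feat_cols)
        combo_cfg = TrainConfig(
            fractions=cfg.fractions,
            max_epochs=cfg.max_epochs,
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            patience=cfg.patience,
            min_delta=cfg.min_delta,
            seed=cfg.seed + k,
        )
        fit = train(
            sub_std,
            NetworkSpec(n_input=len(feat_cols), n_hidden=n_hidden, seed=combo_cfg.seed),
            combo_cfg,
            combo_id=combo,
        )
        results[combo] = fit
        row = {"combo": combo}
        row.update(dict(zip(COMBO_FEATURE_ORDER, COMBINATIONS[combo])))
        row["R2"] = fit.r2
        row["MSE"] = fit.mse
        rows.append(row)
    report = pd.DataFrame(rows)
    order = report.sort_values(
        ["R2", "MSE", "combo"], ascending=[False, True, True], kind="stable"
    )
    best_combo = order.iloc[0]["combo"]
    report["best"] = report["combo"] == best_combo
    report.attrs["fits"] = results
    return report
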