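"""Nested two-fold cross-validated ridge prediction of brain maturity.

Age is predicted from the multivariate pattern of regional control energy
with ridge regression (closed form ``beta = (X'X + lambda I)^-1 X'y`` on a
centered design; the intercept is unpenalized).  The outer split assigns
age-sorted subjects with odd rank to subset 1 and even rank to subset 2;
each subset serves once as training set.  Features are min-max scaled to
[0, 1] using training-set parameters only.  Inside each training set an
inner two-fold CV (same odd/even rule) picks lambda from the 16-value grid
``2^-10 ... 2^5``: per lambda the mean correlation r and mean MAE over the
two inner folds are computed, the 16 mean-r values and the 16 mean-(1/MAE)
values are each min-max normalized to [0, 1], and lambda maximizing their
sum is selected (ties toward stronger regularization).  Generalizability is
summarized per fold by the MAE and the partial correlation of predicted and
true age controlling for the nuisance covariates; significance comes from
permutation of the feature-to-age correspondence, and an optional
random-split mode repeats the whole procedure on random halves.

Model weights are interpreted through the Haufe activation pattern
``a = Sigma_X w`` (feature covariance times weight vector), which converts
decoding weights into an encoding pattern whose magnitude ranks regional
importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .stats import DEFAULT_COVARIATES, partial_correlation

logger = logging.getLogger(__name__)

LAMBDA_GRID = tuple(2.0 ** np.arange(-10, 6))  # 16 values


@dataclass
class PredictionConfig:
    lambda_grid: tuple[float, ...] = LAMBDA_GRID
    split_mode: str = "age_rank"  # or "random"
    n_random_repeats: int = 100
    n_permutations: int = 1000
    seed: int = 0
    inner_normalization: str = "minmax"  # or "zscore"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if not np.all(np.diff(grid) > 0):
            raise ParameterError("lambda_grid must be strictly increasing")
        if self.split_mode not in ("age_rank", "random"):
            raise ParameterError("split_mode must be 'age_rank' or 'random'")
        if self.inner_normalization not in ("minmax", "zscore"):
            raise ParameterError("inner_normalization must be 'minmax' or 'zscore'")


@dataclass
class FoldMetrics:
    fold: int
    lambda_star: float
    r: float
    partial_r: float
    mae: float


@dataclass
class PredictionResult:
    predictions: np.ndarray  # per-subject out-of-sample predicted age
    fold_metrics: list[FoldMetrics]
    mean_partial_r: float
    mean_mae: float
    raw_weights: np.ndarray
    haufe_weights: np.ndarray
    lambda_full: float
    perm_p_r: float = field(default=np.nan)
    perm_p_mae: float = field(default=np.nan)


def split_by_age_rank(ages) -> tuple[np.ndarray, np.ndarray]:
    """Odd age ranks -> subset 1, even ranks -> subset 2 (stable sort)."""
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 4:
        raise ParameterError("split requires at least 4 subjects")
    order = np.argsort(ages, kind="stable")
    return order[0::2], order[1::2]


def _minmax_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    constant = rng == 0
    if constant.any():
        logger.warning("%d constant training feature(s) scaled to 0", int(constant.sum()))
        rng = np.where(constant, 1.0, rng)
        lo = np.where(constant, x.min(axis=0), lo)
    return lo, rng


def ridge_train_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max scale on train, fit closed-form ridge, predict test.

    Returns (test predictions, weight vector, scaled training design).
    Test values outside the training range map outside [0, 1].
    """
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    lo, rng = _minmax_fit(train_x)
    xs = (train_x - lo) / rng
    xt = (test_x - lo) / rng
    x_mean = xs.mean(axis=0)
    y_mean = train_y.mean()
    xc = xs - x_mean
    yc = train_y - y_mean
    p = xc.shape[1]
    gram = xc.T @ xc + lam * np.eye(p)
    try:
        w = np.linalg.solve(gram, xc.T @ yc)
    except np.linalg.LinAlgError:
        w, *_ = np.linalg.lstsq(gram, xc.T @ yc, rcond=None)
    pred = (xt - x_mean) @ w + y_mean
    return pred, w, xs


def inner_select_lambda(
    train_x: np.ndarray,
    train_y: np.ndarray,
    config: PredictionConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Inner 2-fold CV over the lambda grid; see module docstring."""
    if len(train_y) < 4:
        raise ParameterError("inner CV requires at least 4 training subjects")
    if config.split_mode == "age_rank" or rng is None:
        i1, i2 = split_by_age_rank(train_y)
    else:
        perm = rng.permutation(len(train_y))
        i1, i2 = perm[0::2], perm[1::2]
    grid = np.asarray(config.lambda_grid)
    mean_r = np.empty(len(grid))
    mean_mae = np.empty(len(grid))
    for g, lam in enumerate(grid):
        rs, maes = [], []
        for tr, te in ((i1, i2), (i2, i1)):
            pred, _, _ = ridge_train_predict(train_x[tr], train_y[tr], train_x[te], lam)
            if np.std(pred) == 0 or np.std(train_y[te]) == 0:
                rs.append(0.0)
            else:
                rs.append(np.corrcoef(pred, train_y[te])[0, 1])
            maes.append(np.mean(np.abs(pred - train_y[te])))
        mean_r[g] = np.mean(rs)
        mean_mae[g] = np.mean(maes)

    score = combine_inner_accuracy(mean_r, mean_mae, config.inner_normalization)
    best = np.flatnonzero(score == score.max())[-1]  # ties -> larger lambda
    return float(grid[best])


def combine_inner_accuracy(
    mean_r: np.ndarray, mean_mae: np.ndarray, normalization: str = "minmax"
) -> np.ndarray:
    """Inner prediction accuracy per lambda: normalized mean r plus
    normalized reciprocal mean MAE (each rescaled across the grid)."""

    def _norm(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if normalization == "zscore":
            sd = v.std()
            return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    return _norm(np.asarray(mean_r, dtype=float)) + _norm(1.0 / np.asarray(mean_mae, dtype=float))


def haufe_transform(weights: np.ndarray, train_x: np.ndarray) -> np.ndarray:
    """Activation pattern ``a = Sigma_X w`` from decoding weights."""
    sigma = np.cov(train_x, rowvar=False)
    return sigma @ np.asarray(weights, dtype=float)


def _one_nested_run(x, y, cov, config, rng):
    n = len(y)
    if config.split_mode == "age_rank":
        i1, i2 = split_by_age_rank(y)
    else:
        perm = rng.permutation(n)
        i1, i2 = perm[0::2], perm[1::2]
    predictions = np.full(n, np.nan)
    fold_metrics = []
    for fold, (tr, te) in enumerate(((i1, i2), (i2, i1)), start=1):
        lam = inner_select_lambda(x[tr], y[tr], config, rng)
        pred, _, _ = ridge_train_predict(x[tr], y[tr], x[te], lam)
        predictions[te] = pred
        r = float(np.corrcoef(pred, y[te])[0, 1]) if np.std(pred) > 0 else 0.0
        try:
            pr, _, _ = partial_correlation(pred, y[te], cov[te] if cov is not None else None)
        except Exception:
            pr = 0.0
        mae = float(np.mean(np.abs(pred - y[te])))
        fold_metrics.append(
            FoldMetrics(fold=fold, lambda_star=lam, r=r, partial_r=pr, mae=mae)
        )
    return predictions, fold_metrics


def nested_prediction(
    features: np.ndarray | pd.DataFrame,
    cohort: pd.DataFrame,
    config: PredictionConfig | None = None,
    *,
    run_permutations: bool = False,
) -> PredictionResult:
    """Full nested 2F-CV ridge prediction of age from the feature pattern."""
    config = config or PredictionConfig()
    x = np.asarray(features, dtype=float)
    y = cohort["age"].to_numpy(dtype=float)
    if len(x) != len(y):
        raise ParameterError("features must align with the cohort")
    cov = (
        cohort[list(config.covariates)].to_numpy(dtype=float)
        if all(c in cohort.columns for c in config.covariates)
        else None
    )
    rng = np.random.default_rng(config.seed)

    if config.split_mode == "random":
        all_pr, all_mae = [], []
        last = None
        for _ in range(config.n_random_repeats):
            preds, fm = _one_nested_run(x, y, cov, config, rng)
            all_pr.append(np.mean([f.partial_r for f in fm]))
            all_mae.append(np.mean([f.mae for f in fm]))
            last = (preds, fm)
        predictions, fold_metrics = last
        mean_pr, mean_mae = float(np.mean(all_pr)), float(np.mean(all_mae))
    else:
        predictions, fold_metrics = _one_nested_run(x, y, cov, config, rng)
        mean_pr = float(np.mean([f.partial_r for f in fold_metrics]))
        mean_mae = float(np.mean([f.mae for f in fold_metrics]))

    # interpretive model: lambda by inner CV on the full sample, fit on all subjects
    lam_full = inner_select_lambda(x, y, config, rng)
    _, w, xs = ridge_train_predict(x, y, x, lam_full)
    haufe = haufe_transform(w, xs)

    perm_p_r = perm_p_mae = np.nan
    if run_permutations:
        if config.n_permutations < 100:
            raise ParameterError("n_permutations must be >= 100 for significance")
        k_r = k_mae = 0
        for _ in range(config.n_permutations):
            perm = rng.permutation(len(y))
            _, fm = _one_nested_run(x[perm], y, cov, config, rng)
            if np.mean([f.partial_r for f in fm]) >= mean_pr:
                k_r += 1
            if np.mean([f.mae for f in fm]) <= mean_mae:
                k_mae += 1
        perm_p_r = (k_r + 1) / (config.n_permutations + 1)
        perm_p_mae = (k_mae + 1) / (config.n_permutations + 1)

    return PredictionResult(
        predictions=predictions,
        fold_metrics=fold_metrics,
        mean_partial_r=mean_pr,
        mean_mae=mean_mae,
        raw_weights=w,
        haufe_weights=haufe,
        lambda_full=lam_full,
        perm_p_r=perm_p_r,
        perm_p_mae=perm_p_mae,
    )
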