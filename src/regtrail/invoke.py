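"""INVOKE: penalized linear models of gene expression from gene-TF scores.

Gene-TF affinity scores serve as features, per-gene expression as the
response; observations are genes. A lasso, ridge or elastic-net model is
selected by nested cross-validation: the outer loop measures held-out
performance (Pearson, Spearman, MSE), the inner loop picks the elastic-net
mixing parameter (grid 0, step, ..., 1) and the regularization strength
lambda (log-spaced path from lambda_max down to lambda_max * 1e-4) by
minimizing inner-fold mean squared error. The final coefficients come from a
full-data fit at the hyperparameters the inner CV selects on all genes; TFs
with large absolute coefficients are the candidate key regulators.

:class:`InvokeRegressor` is a scikit-learn compatible estimator (``fit`` /
``predict`` / ``get_params``) whose ``fit`` performs the inner model
selection; :func:`nested_cv_fit` wraps it in the outer evaluation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from ._errors import InputError, NumericalError
from .affinity import GeneTFScoreMatrix

PENALTIES = ("lasso", "ridge", "elastic_net")
MIN_COMMON_GENES = 50
DEFAULT_DISPLAY_THRESHOLD = 0.025


@dataclass
class ModelConfig:
    penalty: str = "elastic_net"
    outer_folds: int = 6
    inner_folds: int = 6
    alpha_step: float = 0.1
    lambda_path_size: int = 100
    log_transform: bool = True
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.penalty not in PENALTIES:
            raise InputError(f"penalty must be one of {PENALTIES}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise InputError("outer_folds and inner_folds must be >= 2")
        if not 0 < self.alpha_step <= 1:
            raise InputError("alpha_step must lie in (0, 1]")
        if self.lambda_path_size < 2:
            raise InputError("lambda_path_size must be >= 2")

    def alpha_grid(self) -> np.ndarray:
        """Elastic-net mixing grid; lasso and ridge pin it to {1} and {0}."""
        if self.penalty == "lasso":
            return np.array([1.0])
        if self.penalty == "ridge":
            return np.array([0.0])
        n_steps = int(round(1.0 / self.alpha_step))
        return np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)


@dataclass
class AlignedDataset:
    gene_ids: list[str]
    feature_names: list[str]
    X: np.ndarray  # genes x TFs, preprocessed
    y: np.ndarray  # centered response
    dropped_features: list[str] = field(default_factory=list)
    y_offset: float = 0.0


@dataclass
class FoldResult:
    fold: int
    alpha: float
    lam: float
    pearson: float
    spearman: float
    mse: float
    coefficients: dict[str, float]


@dataclass
class FitReport:
    feature_names: list[str]
    fold_results: list[FoldResult]
    mean_pearson: float
    mean_spearman: float
    mean_mse: float
    final_alpha: float
    final_lambda: float
    coefficients: dict[str, float]
    nonzero_features: list[str]
    dropped_features: list[str]
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def align_and_preprocess(
    scores: GeneTFScoreMatrix,
    expr: pd.Series,
    config: ModelConfig,
) -> AlignedDataset:
    """Intersect gene sets, transform, standardize, center.

    With ``log_transform`` both features and response go through
    ``log2(x + 1)``; with ``standardize_features`` each feature column is
    z-scored and zero-variance columns are dropped with a warning recorded
    in the dataset. The response is always centered.
    """
    expr = expr.copy()
    expr.index = expr.index.astype(str)
    common = [g for g in scores.gene_ids if g in set(expr.index)]
    if len(common) < MIN_COMMON_GENES:
        raise InputError(
            f"only {len(common)} genes shared between scores and expression "
            f"(need >= {MIN_COMMON_GENES}); score IDs look like "
            f"{scores.gene_ids[:3]}, expression IDs like {list(expr.index[:3])}"
        )
    X = scores.scores.loc[common].to_numpy(float)
    y = expr.loc[common].to_numpy(float)
    names = list(scores.tf_names)
    if config.log_transform:
        if (X < 0).any() or (y < 0).any():
            raise InputError("log transform requires non-negative inputs")
        X = np.log2(X + 1.0)
        y = np.log2(y + 1.0)
    dropped: list[str] = []
    if config.standardize_features:
        sd = X.std(axis=0, ddof=0)
        # tolerance: summing identical floats leaves ~1e-16 residual spread
        keep = sd > 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
        dropped = [n for n, k in zip(names, keep) if not k]
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] == 0:
        raise InputError("no informative feature columns remain")
    y_offset = float(y.mean())
    return AlignedDataset(common, names, X, y - y_offset, dropped, y_offset)


# ---------------------------------------------------------------------------
# penalized fits along a lambda path
# ---------------------------------------------------------------------------

def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, size: int) -> np.ndarray:
    n = X.shape[0]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    lam_max = np.max(np.abs(Xc.T @ yc)) / (n * max(alpha, 1e-3))
    if lam_max <= 0 or not np.isfinite(lam_max):
        raise NumericalError("degenerate data: zero correlation with response")
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), size)


def _fit_path(
    X: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients along a descending lambda path (features x lambdas),
    with intercepts; alpha is the L1 mixing proportion."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if alpha > 0:
        _, coefs, _ = enet_path(Xc, yc, l1_ratio=alpha, alphas=lambdas)
    else:
        # closed-form ridge via SVD, exact for every lambda at once
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        uty = U.T @ yc
        n = X.shape[0]
        shrink = s[:, None] / (s[:, None] ** 2 + n * lambdas[None, :])
        coefs = Vt.T @ (shrink * uty[:, None])
    intercepts = y_mean - x_mean @ coefs
    return coefs, intercepts, lambdas


def _inner_select(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    inner_folds: int,
    path_size: int,
    seed: int,
) -> tuple[float, float]:
    """Pick (alpha, lambda) minimizing inner-CV mean MSE. Ties break toward
    the earlier alpha grid point and the larger (more regularized) lambda."""
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best: tuple[float, float, float] | None = None  # (mse, alpha, lambda)
    for alpha in alphas:
        lambdas = _lambda_path(X, y, alpha, path_size)
        fold_mse = np.zeros((len(splits), path_size))
        for f, (tr, te) in enumerate(splits):
            coefs, intercepts, _ = _fit_path(X[tr], y[tr], alpha, lambdas)
            pred = X[te] @ coefs + intercepts[None, :]
            fold_mse[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
        mean_mse = fold_mse.mean(axis=0)
        idx = int(np.argmin(mean_mse))  # first (largest-lambda) minimum
        if best is None or mean_mse[idx] < best[0]:
            best = (float(mean_mse[idx]), float(alpha), float(lambdas[idx]))
    assert best is not None
    return best[1], best[2]


class InvokeRegressor(RegressorMixin, BaseEstimator):
    """Penalized linear regression with inner-CV hyperparameter selection.

    Parameters mirror :class:`ModelConfig`. ``fit`` selects the elastic-net
    mixing parameter ``alpha_`` and regularization strength ``lambda_`` by
    ``inner_folds``-fold cross-validation minimizing MSE, then refits on all
    supplied observations.

    Attributes set by ``fit``: ``coef_``, ``intercept_``, ``alpha_``,
    ``lambda_``, ``n_features_in_``.
    """

    def __init__(self, penalty: str = "elastic_net", inner_folds: int = 6,
                 alpha_step: float = 0.1, lambda_path_size: int = 100,
                 random_state: int = 0):
        self.penalty = penalty
        self.inner_folds = inner_folds
        self.alpha_step = alpha_step
        self.lambda_path_size = lambda_path_size
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            penalty=self.penalty,
            inner_folds=self.inner_folds,
            alpha_step=self.alpha_step,
            lambda_path_size=self.lambda_path_size,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        cfg = self._config()
        if X.shape[0] < cfg.inner_folds:
            raise InputError(
                f"{X.shape[0]} observations cannot be split into "
                f"{cfg.inner_folds} inner folds"
            )
        alphas = cfg.alpha_grid()
        self.alpha_, self.lambda_ = _inner_select(
            X, y, alphas, cfg.inner_folds, cfg.lambda_path_size, cfg.seed
        )
        coefs, intercepts, _ = _fit_path(X, y, self.alpha_, np.array([self.lambda_]))
        self.coef_ = coefs[:, 0]
        self.intercept_ = float(intercepts[0])
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X @ self.coef_ + self.intercept_


def _test_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    if np.std(y_pred) < 1e-12 or np.std(y_true) < 1e-12:
        pear = spear = 0.0
    else:
        pear = float(stats.pearsonr(y_true, y_pred)[0])
        spear = float(stats.spearmanr(y_true, y_pred)[0])
    mse = float(((y_true - y_pred) ** 2).mean())
    return pear, spear, mse


def nested_cv_fit(data: AlignedDataset, config: ModelConfig) -> FitReport:
    """Outer-CV performance estimate plus a final full-data model.

    Genes are shuffled into ``outer_folds`` partitions from the configured
    seed; per fold an :class:`InvokeRegressor` is fit on the training genes
    and evaluated on the held-out genes. The reported coefficients come from
    a final fit on all genes at inner-CV-selected hyperparameters.
    """
    X, y = data.X, data.y
    if X.shape[0] < config.outer_folds:
        raise InputError("fewer genes than outer folds")
    outer = KFold(n_splits=config.outer_folds, shuffle=True, random_state=config.seed)
    fold_results: list[FoldResult] = []
    for f, (tr, te) in enumerate(outer.split(X)):
        est = InvokeRegressor(
            penalty=config.penalty,
            inner_folds=config.inner_folds,
            alpha_step=config.alpha_step,
            lambda_path_size=config.lambda_path_size,
            random_state=config.seed,
        ).fit(X[tr], y[tr])
        pear, spear, mse = _test_metrics(y[te], est.predict(X[te]))
        fold_results.append(FoldResult(
            f, est.alpha_, est.lambda_, pear, spear, mse,
            {n: float(c) for n, c in zip(data.feature_names, est.coef_)},
        ))

    final = InvokeRegressor(
        penalty=config.penalty,
        inner_folds=config.inner_folds,
        alpha_step=config.alpha_step,
        lambda_path_size=config.lambda_path_size,
        random_state=config.seed,
    ).fit(X, y)
    coefficients = {n: float(c) for n, c in zip(data.feature_names, final.coef_)}
    nonzero = [n for n, c in coefficients.items() if abs(c) > 1e-10]
    return FitReport(
        feature_names=list(data.feature_names),
        fold_results=fold_results,
        mean_pearson=float(np.mean([r.pearson for r in fold_results])),
        mean_spearman=float(np.mean([r.spearman for r in fold_results])),
        mean_mse=float(np.mean([r.mse for r in fold_results])),
        final_alpha=final.alpha_,
        final_lambda=final.lambda_,
        coefficients=coefficients,
        nonzero_features=nonzero,
        dropped_features=list(data.dropped_features),
    )


def select_features(
    report: FitReport, threshold: float = DEFAULT_DISPLAY_THRESHOLD
) -> list[tuple[str, float]]:
    """Features with |coefficient| >= threshold, largest magnitude first;
    ties break by name."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    chosen = [
        (n, c) for n, c in report.coefficients.items()
        if abs(c) >= threshold and abs(c) > 0
    ]
    chosen.sort(key=lambda nc: (-abs(nc[1]), nc[0]))
    return chosen


def coefficient_plot(
    report: FitReport,
    path: str | Path,
    threshold: float = DEFAULT_DISPLAY_THRESHOLD,
) -> None:
    """Horizontal bar plot of the selected coefficients, signed, ranked by
    magnitude (largest at the top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    selected = select_features(report, threshold)
    if not selected:
        raise InputError(
            f"no coefficient reaches |coef| >= {threshold}; lower the threshold"
        )
    names = [n for n, _ in selected][::-1]
    values = [c for _, c in selected][::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(selected) + 1)))
    colors = ["#b2182b" if v > 0 else "#2166ac" for v in values]
    ax.barh(names, values, color=colors)
    ax.axvline(0, color="black", linewidth=0.8)
    ax.set_xlabel("regression coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
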