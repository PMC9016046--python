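"""Boosted-regression-tree attribution of forest change to its drivers.

For every response (an indicator's annual change) and period, a gradient-
boosted regression-tree model (squared-error loss) is evaluated by k-fold
cross-validation, covariates are eliminated backward one at a time (dropping
the least important), and the candidate model with the lowest cross-validated
RMSE is retained.  Relative influence is the normalized split-improvement
importance; covariates eliminated before the selected model contribute zero.
Influences are aggregated across models weighted by each model's cross-
validated variance explained, and final-model residuals are screened for
spatial autocorrelation with Moran's I on k-nearest-neighbor weights.

Categorical covariates are one-hot encoded internally; dummy importances are
summed back to the parent covariate, and elimination always removes a parent
covariate with all of its dummies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import spatial
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

__all__ = [
    "BRTConfig",
    "BRTFitResult",
    "SelectionPath",
    "AggregatedImportance",
    "fit_brt_cv",
    "backward_select",
    "aggregate_importance",
    "morans_i",
]


@dataclass
class BRTConfig:
    learning_rate: float = 0.01
    tree_depth: int = 3
    bag_fraction: float = 0.5
    max_trees: int = 5000
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "BRTConfig":
        """Faster setting for a few hundred plots: fewer, coarser boosting steps."""
        return cls(learning_rate=0.2, max_trees=45, seed=seed)


@dataclass
class BRTFitResult:
    influence: pd.Series          # % per covariate, sums to 100 (or all zero if degenerate)
    cv_rmse: float
    cv_variance_explained: float
    selected_n_trees: int
    residuals: np.ndarray         # held-out residuals, observation order
    degenerate: bool = False


@dataclass
class SelectionPath:
    steps: list                   # [(tuple of covariates, cv_rmse), ...] one per set size
    best_index: int

    @property
    def final_covariates(self) -> tuple:
        return self.steps[self.best_index][0]


def _encode(X: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """One-hot encode categorical/boolean columns; map encoded -> parent."""
    enc = pd.get_dummies(X, dtype=float)
    parents = []
    for col in enc.columns:
        parent = col if col in X.columns else next(
            c for c in sorted(X.columns, key=len, reverse=True) if col.startswith(c + "_")
        )
        parents.append(parent)
    return enc.to_numpy(dtype=float), list(enc.columns), parents


def _make_folds(n: int, config: BRTConfig) -> list:
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    return list(kf.split(np.arange(n)))


def fit_brt_cv(X: pd.DataFrame, y: np.ndarray, config: BRTConfig,
               folds: list | None = None) -> BRTFitResult:
    """Cross-validated boosted regression trees for one response.

    The ensemble size is chosen to minimize the pooled held-out squared error
    over the staged predictions; influence comes from a final fit on all data
    at that size.  A constant response yields a degenerate result with all
    influences zero.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    covariates = list(X.columns)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return BRTFitResult(
            pd.Series(0.0, index=covariates), 0.0, 0.0, 0,
            np.zeros(len(y)), degenerate=True,
        )
    Xe, enc_cols, parents = _encode(X)
    if folds is None:
        folds = _make_folds(len(y), config)

    cv_sse = np.zeros(config.max_trees)
    staged = []  # (test_idx, matrix n_test x max_trees)
    for i, (train, test) in enumerate(folds):
        gbr = GradientBoostingRegressor(
            learning_rate=config.learning_rate, max_depth=config.tree_depth,
            subsample=config.bag_fraction, n_estimators=config.max_trees,
            random_state=config.seed + i,
        )
        gbr.fit(Xe[train], y[train])
        preds = np.stack(list(gbr.staged_predict(Xe[test])), axis=1)
        cv_sse += ((preds - y[test, None]) ** 2).sum(axis=0)
        staged.append((test, preds))
    best = int(np.argmin(cv_sse))
    residuals = np.empty(len(y))
    for test, preds in staged:
        residuals[test] = y[test] - preds[:, best]
    cv_rmse = float(np.sqrt(cv_sse[best] / len(y)))
    r2 = 1.0 - cv_sse[best] / sst

    final = GradientBoostingRegressor(
        learning_rate=config.learning_rate, max_depth=config.tree_depth,
        subsample=config.bag_fraction, n_estimators=best + 1,
        random_state=config.seed,
    )
    final.fit(Xe, y)
    imp = pd.Series(final.feature_importances_, index=enc_cols)
    influence = imp.groupby(pd.Index(parents, name="covariate")).sum()
    influence = influence.reindex(covariates).fillna(0.0)
    total = influence.sum()
    influence = influence * (100.0 / total) if total > 0 else influence
    return BRTFitResult(influence, cv_rmse, float(r2), best + 1, residuals)


def backward_select(X: pd.DataFrame, y: np.ndarray, config: BRTConfig
                    ) -> tuple[SelectionPath, BRTFitResult]:
    """Backward covariate elimination with minimum-CV-RMSE model selection.

    At each step the single least-influential covariate is dropped (ties in
    influence broken alphabetically) and the model refitted on the same CV
    folds, down to one covariate.  The returned model is the candidate with
    the lowest cv_rmse; RMSE ties go to the smaller covariate set.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one covariate")
    folds = _make_folds(len(X), config)
    current = list(X.columns)
    steps, fits = [], []
    while current:
        fit = fit_brt_cv(X[current], y, config, folds=folds)
        steps.append((tuple(current), fit.cv_rmse))
        fits.append(fit)
        if len(current) == 1:
            break
        ranked = fit.influence.loc[current].sort_values(kind="stable")
        weakest = sorted(ranked.index[ranked == ranked.iloc[0]])[0]
        current = [c for c in current if c != weakest]
    best_index = min(range(len(steps)), key=lambda i: (steps[i][1], len(steps[i][0])))
    return SelectionPath(steps, best_index), fits[best_index]


@dataclass
class AggregatedImportance:
    covariate_pct: pd.Series      # per covariate, sums to 100
    category_pct: pd.Series       # rollup over driver categories, sums to 100
    weights: pd.Series            # per model weight used (variance explained, clipped)
    unweighted: bool = False


def aggregate_importance(fits: dict, all_covariates, categories: dict) -> AggregatedImportance:
    """Variance-explained-weighted mean relative influence across models.

    ``fits`` maps a model key (e.g. (response, period)) to its final
    BRTFitResult.  Influence vectors are expanded to the full covariate list
    with zeros for covariates eliminated from that model, weighted by
    max(cv_variance_explained, 0), averaged, and renormalized to 100.  If all
    weights are zero an unweighted mean is used (flagged).
    """
    if not fits:
        raise ValueError("no fitted models to aggregate")
    all_covariates = list(all_covariates)
    mat = pd.DataFrame(
        {k: f.influence.reindex(all_covariates).fillna(0.0) for k, f in fits.items()}
    )
    weights = pd.Series({k: max(f.cv_variance_explained, 0.0) for k, f in fits.items()})
    unweighted = False
    if weights.sum() == 0:
        weights = pd.Series(1.0, index=weights.index)
        unweighted = True
    agg = mat.mul(weights, axis=1).sum(axis=1) / weights.sum()
    total = agg.sum()
    if total > 0:
        agg = agg * (100.0 / total)
    cat = agg.groupby(pd.Series(categories).reindex(all_covariates)).sum()
    return AggregatedImportance(agg, cat, weights, unweighted)


def morans_i(residuals: np.ndarray, coords: np.ndarray, k_neighbors: int = 8
             ) -> tuple[float, float]:
    """Global Moran's I with row-standardized k-nearest-neighbor weights.

    Returns (I, E[I]) where E[I] = -1/(n-1) is the no-autocorrelation
    expectation.  Raises on constant residuals (undefined statistic).
    """
    r = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(r)
    if n < 10:
        raise ValueError("Moran's I needs at least 10 observations")
    z = r - r.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("residual variance is zero; Moran's I undefined")
    tree = spatial.cKDTree(coords)
    _, nbr = tree.query(coords, k=k_neighbors + 1)
    nbr = nbr[:, 1:]  # drop self
    # row-standardized weights: each neighbor contributes 1/k
    num = (z[:, None] * z[nbr]).sum() / k_neighbors
    s0 = float(n)  # each row's weights sum to 1
    return float((n / s0) * num / denom), -1.0 / (n - 1)
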