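"""Bootstrap-lasso stability selection with MAPE screening.

The engine behind the driving-metric / connectivity association: for a
given response, repeat ``n_iterations`` times —

1. draw a random 2/3 training subsample (without replacement by
   default; the held-out 1/3 is the test set),
2. standardize features on the training split only,
3. pick the lasso penalty by 10-fold cross-validation on the training
   split (CV-minimum rule over a 100-point log grid from lambda_max
   down to lambda_max/1000),
4. fit at the selected penalty, record which features have nonzero
   coefficients and the mean absolute percentage error (MAPE) of the
   held-out predictions.

Features retained often across iterations are stable predictors; a
response whose mean MAPE falls below 10% is flagged as predictable.
The whole procedure is a deterministic function of (data, parameters,
seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _lasso

DEFAULT_N_ITERATIONS = 1000
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0
DEFAULT_N_FOLDS = 10
DEFAULT_MAPE_THRESHOLD = 10.0
N_LAMBDAS = 100
LAMBDA_MIN_RATIO = 1e-3


class ZeroResponseError(ValueError):
    """MAPE is undefined when the response contains zeros."""


@dataclass
class LassoFit:
    """One penalized fit: coefficients on the standardized scale, the
    intercept (training response mean), the penalty, and the
    standardization applied."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    feature_means: np.ndarray
    feature_scales: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_scales
        return self.intercept + Xs @ self.coefficients


@dataclass
class StabilityResult:
    response_name: str
    n_iterations: int
    feature_names: list[str]
    retention_counts: np.ndarray
    per_iteration_mape: np.ndarray
    mape_threshold: float
    selected_lambdas: np.ndarray = field(repr=False, default=None)

    @property
    def mean_mape(self) -> float:
        return float(np.mean(self.per_iteration_mape))

    @property
    def predictive_flag(self) -> bool:
        return self.mean_mape < self.mape_threshold

    def ranking(self) -> pd.DataFrame:
        """Features sorted by retention count (descending; name as
        tie-break for determinism)."""
        df = pd.DataFrame(
            {"feature": self.feature_names, "retention_count": self.retention_counts}
        )
        df["retention_fraction"] = df["retention_count"] / self.n_iterations
        return df.sort_values(
            ["retention_count", "feature"], ascending=[False, True]
        ).reset_index(drop=True)

    def top_features(self, k: int = 10) -> list[str]:
        return self.ranking()["feature"].head(k).tolist()

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "n_iterations": self.n_iterations,
            "retention_counts": {
                f: int(c) for f, c in zip(self.feature_names, self.retention_counts)
            },
            "per_iteration_mape": [float(x) for x in self.per_iteration_mape],
            "mean_mape": self.mean_mape,
            "mape_threshold": self.mape_threshold,
            "predictive_flag": self.predictive_flag,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize with population (1/n) variances; constant
    columns get scale 1 so they standardize to all-zero (and can never
    be selected)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, means, scales


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: max_j |X_j.y| / n for
    centered y (KKT condition at beta = 0)."""
    n = X.shape[0]
    yc = y - y.mean()
    return float(np.max(np.abs(X.T @ yc)) / n)


def lambda_grid(lam_max: float, n: int = N_LAMBDAS, min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    standardize_inputs: bool = True,
    tol: float = _lasso.TOL,
) -> LassoFit:
    """Single lasso fit of (1/2n)||y - b0 - X beta||^2 + lam*||beta||_1
    by cyclic coordinate descent with soft-thresholding.

    With ``standardize_inputs=False`` the features are assumed already
    standardized and the response centered (intercept = mean(y)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if X.shape[0] < 2:
        raise ValueError("need n >= 2")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if standardize_inputs:
        Xs, means, scales = standardize(X)
    else:
        Xs, means, scales = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    intercept = float(y.mean())
    yc = y - intercept
    beta = np.zeros(X.shape[1])
    _lasso.cd_lasso(np.asfortranarray(Xs), yc, lam, beta, tol, _lasso.MAX_ITER)
    return LassoFit(beta, intercept, lam, means, scales)


def mape(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute percentage error, in percent:
    100 * mean(|y_true - y_pred| / |y_true|). Scale-invariant; undefined
    (raises) when any true value is zero."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    zeros = np.flatnonzero(y_true == 0)
    if zeros.size:
        raise ZeroResponseError(
            f"MAPE undefined: y_true is zero at rows {zeros.tolist()}"
        )
    return float(100.0 * np.mean(np.abs(y_true - y_pred) / np.abs(y_true)))


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = DEFAULT_N_FOLDS,
    lambdas: np.ndarray | None = None,
    rng: np.random.Generator | int | None = 0,
    rule: str = "min",
) -> float:
    """Penalty minimizing mean cross-validated squared error.

    Folds are a seeded random partition; the grid defaults to 100
    log-spaced points from lambda_max down to lambda_max/1000. Ties go
    to the larger (sparser) penalty. ``rule="1se"`` picks the largest
    penalty within one standard error of the minimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"n={n} smaller than n_folds={n_folds}")
    if lambdas is None:
        lambdas = lambda_grid(lambda_max(X, y))
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be descending")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    fold_mse = np.empty((n_folds, lambdas.size))
    for k, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        fold_mse[k] = _lasso.path_test_mse(
            np.asfortranarray(X[mask]),
            np.ascontiguousarray(y[mask]),
            np.asfortranarray(X[test_idx]),
            np.ascontiguousarray(y[test_idx]),
            lambdas,
            _lasso.TOL,
            _lasso.PATH_MAX_SWEEPS,
        )
    mean_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(mean_mse))  # grid descends => argmin's first hit is sparser
    if rule == "min":
        return float(lambdas[best])
    if rule == "1se":
        se = fold_mse.std(axis=0, ddof=1)[best] / np.sqrt(n_folds)
        ok = np.flatnonzero(mean_mse <= mean_mse[best] + se)
        return float(lambdas[int(ok[0])])
    raise ValueError(f"unknown rule {rule!r}")


def run_stability(
    features: pd.DataFrame,
    response: pd.Series | np.ndarray,
    response_name: str | None = None,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_folds: int = DEFAULT_N_FOLDS,
    mape_threshold: float = DEFAULT_MAPE_THRESHOLD,
    seed: int = 0,
    with_replacement: bool = False,
    lambda_rule: str = "min",
) -> StabilityResult:
    """Repeated-split lasso with retention counting and MAPE screening.

    ``features``: drivers-by-features DataFrame; ``response``: aligned
    response vector (all nonzero — MAPE is undefined otherwise, and the
    response is ineligible for screening). ``with_replacement=True``
    draws classical bootstrap training samples instead of 2/3
    subsamples; the test set is always the untouched remainder.
    """
    X_all = features.to_numpy(dtype=float)
    if isinstance(response, pd.Series):
        response = response.reindex(features.index)
        if response_name is None:
            response_name = str(response.name)
        y_all = response.to_numpy(dtype=float)
    else:
        y_all = np.asarray(response, dtype=float)
    if response_name is None:
        response_name = "response"
    n, p = X_all.shape
    if n < 12:
        raise ValueError("need >= 12 observations for 2/3 splits with 10-fold CV")
    if not np.all(np.isfinite(X_all)) or not np.all(np.isfinite(y_all)):
        raise ValueError("non-finite values in features or response")
    if np.std(y_all) == 0:
        raise ValueError(f"response {response_name!r} has zero variance")
    if np.any(y_all == 0):
        raise ZeroResponseError(
            f"response {response_name!r} contains zeros; MAPE screening undefined"
        )

    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    retention = np.zeros(p, dtype=np.int64)
    mapes = np.empty(n_iterations)
    lams = np.empty(n_iterations)
    for it in range(n_iterations):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if with_replacement:
            train_idx = rng.choice(train_idx, size=n_train, replace=True)
        Xtr_raw, ytr = X_all[train_idx], y_all[train_idx]
        Xtr, means, scales = standardize(Xtr_raw)
        # tiny cohorts: cap folds at the training size (leave-one-out limit)
        folds = min(n_folds, len(train_idx))
        lam = cv_select_lambda(Xtr, ytr, n_folds=folds, rng=rng, rule=lambda_rule)
        fit = lasso_fit(Xtr, ytr, lam, standardize_inputs=False)
        fit.feature_means, fit.feature_scales = means, scales
        retention += fit.coefficients != 0.0
        mapes[it] = mape(y_all[test_idx], fit.predict(X_all[test_idx]))
        lams[it] = lam
    return StabilityResult(
        response_name=response_name,
        n_iterations=n_iterations,
        feature_names=list(features.columns),
        retention_counts=retention,
        per_iteration_mape=mapes,
        mape_threshold=mape_threshold,
        selected_lambdas=lams,
    )
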