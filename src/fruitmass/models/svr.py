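"""Epsilon-insensitive support vector regression over (L, D) features.

Features are z-standardized internally; the dual problem is solved by the
libsvm SMO engine (via scikit-learn, with a precomputed kernel matrix so the
package's own kernel implementations — including PUK — are used throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR as _SkSVR

from fruitmass.errors import FitError
from fruitmass.models.forms import records_to_arrays
from fruitmass.models.kernels import KERNELS, kernel_matrix

_DEFAULT_EPSILON = 0.001
_SOLVER_TOL = 1e-8


@dataclass
class SVRModel:
    """A fitted SVR: kernel name/params, scaling, support set and duals."""

    kernel: str
    c: float
    epsilon: float
    kernel_params: Dict[str, float]
    x_mean: np.ndarray
    x_sd: np.ndarray
    support_vectors: np.ndarray  # standardized features, (n_sv, 2)
    dual_coef: np.ndarray  # beta = alpha - alpha*, (n_sv,)
    bias: float
    support_: np.ndarray = field(default=None)  # indices into training set

    def __post_init__(self):
        if np.any(np.abs(self.dual_coef) > self.c * (1 + 1e-9)):
            raise FitError("dual coefficients violate the box constraint")

    def _standardize(self, L, D) -> np.ndarray:
        X = np.column_stack(
            [np.asarray(L, dtype=float).ravel(), np.asarray(D, dtype=float).ravel()]
        )
        return (X - self.x_mean) / self.x_sd

    def predict(self, L, D):
        Xs = self._standardize(L, D)
        K = kernel_matrix(self.kernel, Xs, self.support_vectors, **self.kernel_params)
        out = K @ self.dual_coef + self.bias
        return out if out.size > 1 else float(out[0])

    @property
    def label(self) -> str:
        return f"c = {self.c:g}, {self.kernel} kernel"


def _feature_matrix(records) -> Tuple[np.ndarray, np.ndarray]:
    L, D, FW = records_to_arrays(records)
    if FW is None:
        raise FitError("records lack a weight_g column")
    return np.column_stack([L, D]), FW


def fit_svr(
    records,
    kernel: str = "PUK",
    c: float = 1.0,
    epsilon: float = _DEFAULT_EPSILON,
    omega: float = 1.0,
    sigma: float = 1.0,
    gamma: Optional[float] = None,
    tol: float = _SOLVER_TOL,
) -> SVRModel:
    """Fit epsilon-SVR with the chosen kernel and penalty c.

    Kernel defaults: PUK omega=1, sigma=1; RBF gamma = 1/(2*n_features) on
    standardized features; POLY2 is the inhomogeneous (u.v + 1)^2 kernel.
    """
    if kernel not in KERNELS:
        raise FitError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    if c <= 0:
        raise FitError("penalty c must be positive")
    X, y = _feature_matrix(records)
    if X.shape[0] < 2:
        raise FitError("need at least 2 records")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    params: Dict[str, float] = {}
    if kernel == "PUK":
        params = {"omega": omega, "sigma": sigma}
    elif kernel == "RBF":
        params = {"gamma": gamma if gamma is not None else 1.0 / (2.0 * X.shape[1])}
    K = kernel_matrix(kernel, Xs, Xs, **params)
    solver = _SkSVR(kernel="precomputed", C=c, epsilon=epsilon, tol=tol, max_iter=2_000_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        solver.fit(K, y)
    if getattr(solver, "fit_status_", 0) != 0:
        raise FitError("SVR solver did not converge within its iteration cap")
    support = solver.support_.copy()
    return SVRModel(
        kernel=kernel,
        c=c,
        epsilon=epsilon,
        kernel_params=params,
        x_mean=x_mean,
        x_sd=x_sd,
        support_vectors=Xs[support],
        dual_coef=solver.dual_coef_.ravel().copy(),
        bias=float(solver.intercept_[0]),
        support_=support,
    )


def dual_objective(model: SVRModel, records) -> float:
    """Value of the SVR dual objective at the model's solution.

    obj(beta) = -1/2 beta' K beta - epsilon * sum|beta| + y' beta, with beta
    supported on the model's support set. Used for solver verification.
    """
    X, y = _feature_matrix(records)
    Xs = (X - model.x_mean) / model.x_sd
    beta = np.zeros(X.shape[0])
    beta[model.support_] = model.dual_coef
    K = kernel_matrix(model.kernel, Xs, Xs, **model.kernel_params)
    return float(
        -0.5 * beta @ K @ beta - model.epsilon * np.abs(beta).sum() + y @ beta
    )


def grid_search_svr(
    records,
    kernels=KERNELS,
    c_values=(0.1, 1.0, 10.0),
    epsilon: float = _DEFAULT_EPSILON,
    k: int = 10,
    seed: int = 0,
    **kernel_kwargs,
) -> Tuple[SVRModel, pd.DataFrame]:
    """Exhaustive kernel x c search scored by k-fold cross-validated RMSE.

    Returns the winning model refitted on all records plus the full grid
    report (one row per kernel/c cell; solver failures are recorded in the
    ``status`` column rather than aborting the search).
    """
    from fruitmass.evaluation import kfold_indices  # cycle guard

    X, y = _feature_matrix(records)
    n = X.shape[0]
    if n < 20:
        raise FitError("grid search needs at least 20 records")
    folds = kfold_indices(n, k=k, seed=seed)
    rows = []
    for kernel in kernels:
        for c in c_values:
            errs = np.full(n, np.nan)
            status = "ok"
            try:
                for val_idx in folds:
                    train_mask = np.ones(n, dtype=bool)
                    train_mask[val_idx] = False
                    sub = records.iloc[np.nonzero(train_mask)[0]]
                    model = fit_svr(sub, kernel=kernel, c=c, epsilon=epsilon, **kernel_kwargs)
                    pred = model.predict(X[val_idx, 0], X[val_idx, 1])
                    errs[val_idx] = np.atleast_1d(pred) - y[val_idx]
                cv_rmse = float(np.sqrt(np.mean(errs**2)))
            except FitError as exc:
                status = f"error: {exc}"
                cv_rmse = np.nan
            rows.append({"kernel": kernel, "c": c, "cv_rmse": cv_rmse, "status": status})
    report = pd.DataFrame(rows)
    if report["cv_rmse"].isna().all():
        raise FitError("every grid cell failed")
    best_row = report.loc[report["cv_rmse"].idxmin()]
    best = fit_svr(
        records, kernel=best_row["kernel"], c=float(best_row["c"]), epsilon=epsilon, **kernel_kwargs
    )
    return best, report
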