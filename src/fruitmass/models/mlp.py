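"""One-hidden-layer perceptron regressor (2-h-1, tanh hidden, linear output).

Training uses full-batch backpropagation (Adam step sizing) on z-standardized
features and target, with early stopping on a held-out 15% of the training
data. The fitted network is stored as plain weight matrices so prediction and
serialization are framework-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from fruitmass._rng import substream_seed
from fruitmass.errors import FitError
from fruitmass.models.forms import records_to_arrays

_MAX_EPOCHS = 2000
_PATIENCE = 50
_VALIDATION_FRACTION = 0.15


@dataclass
class MLPModel:
    """Fitted 2-h-1 network with input/output standardization."""

    hidden: int
    W1: np.ndarray  # (2, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    @property
    def topology(self) -> str:
        return f"2-{self.hidden}-1"

    @property
    def label(self) -> str:
        return f"Topology: {self.topology}"

    def predict(self, L, D):
        X = np.column_stack(
            [np.asarray(L, dtype=float).ravel(), np.asarray(D, dtype=float).ravel()]
        )
        Xs = (X - self.x_mean) / self.x_sd
        hidden = np.tanh(Xs @ self.W1 + self.b1)
        ys = hidden @ self.W2 + self.b2
        out = ys * self.y_sd + self.y_mean
        return out if out.size > 1 else float(out[0])


def fit_mlp(records, hidden_neurons: int, seed: int = 0) -> MLPModel:
    """Train a 2-h-1 tanh network on a cohort; h must be in [1, 20]."""
    if not 1 <= hidden_neurons <= 20:
        raise FitError("hidden_neurons must be in [1, 20]")
    L, D, FW = records_to_arrays(records)
    if FW is None:
        raise FitError("records lack a weight_g column")
    n = L.size
    if n < 10:
        raise FitError("need at least 10 records")
    X = np.column_stack([L, D])
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(FW.mean()), float(FW.std())
    if y_sd == 0 or not np.isfinite(y_sd):
        raise FitError("degenerate target scaling")
    Xs = (X - x_mean) / x_sd
    ys = (FW - y_mean) / y_sd
    if not np.all(np.isfinite(Xs)):
        raise FitError("non-finite standardized features")
    reg = MLPRegressor(
        hidden_layer_sizes=(hidden_neurons,),
        activation="tanh",
        solver="adam",
        learning_rate_init=0.01,
        batch_size=max(1, int(np.floor(n * (1 - _VALIDATION_FRACTION)))),
        max_iter=_MAX_EPOCHS,
        early_stopping=True,
        validation_fraction=_VALIDATION_FRACTION,
        n_iter_no_change=_PATIENCE,
        tol=1e-6,
        random_state=substream_seed(seed, "mlp"),
        alpha=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are expected at the cap
        reg.fit(Xs, ys)
    return MLPModel(
        hidden=hidden_neurons,
        W1=reg.coefs_[0].copy(),
        b1=reg.intercepts_[0].copy(),
        W2=reg.coefs_[1].ravel().copy(),
        b2=float(reg.intercepts_[1][0]),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def sweep_hidden_neurons(
    records, h_values=range(1, 21), seed: int = 0
) -> Tuple[MLPModel, pd.DataFrame]:
    """Select the hidden-layer width by held-out validation RMSE.

    15% of the records are held out (seeded shuffle); each width is trained
    on the remainder and scored on the holdout. The winning width is refit on
    all records. Returns (best model, report with h / topology / val_rmse).
    """
    n = len(records)
    rng = np.random.default_rng(substream_seed(seed, "mlp-sweep"))
    perm = rng.permutation(n)
    n_val = max(1, int(round(_VALIDATION_FRACTION * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train = records.iloc[train_idx]
    val = records.iloc[val_idx]
    Lv, Dv, FWv = records_to_arrays(val)
    rows = []
    for h in h_values:
        model = fit_mlp(train, h, seed=seed)
        pred = np.atleast_1d(model.predict(Lv, Dv))
        rows.append(
            {"h": h, "topology": f"2-{h}-1", "val_rmse": float(np.sqrt(np.mean((pred - FWv) ** 2)))}
        )
    report = pd.DataFrame(rows)
    best_h = int(report.loc[report["val_rmse"].idxmin(), "h"])
    best = fit_mlp(records, best_h, seed=seed)
    return best, report
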