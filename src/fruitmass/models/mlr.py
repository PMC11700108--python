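"""Multiple linear regression FW = b0 + b1*L + b2*D."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fruitmass.errors import FitError
from fruitmass.models.forms import records_to_arrays


@dataclass(frozen=True)
class MLRModel:
    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self):
        if not all(np.isfinite([self.beta0, self.beta1, self.beta2])):
            raise FitError("non-finite coefficients")

    def predict(self, L, D):
        return self.beta0 + self.beta1 * np.asarray(L, dtype=float) + self.beta2 * np.asarray(D, dtype=float)

    @property
    def label(self) -> str:
        return f"FW = {self.beta1:.3f} L + {self.beta2:.3f} D + {self.beta0:.3f}"


def fit_mlr(records) -> MLRModel:
    """Ordinary least squares for (beta0, beta1, beta2).

    Raises FitError on fewer than 3 records or a rank-deficient design
    (e.g. L perfectly collinear with D).
    """
    L, D, FW = records_to_arrays(records)
    if FW is None:
        raise FitError("records lack a weight_g column")
    if L.size < 3:
        raise FitError("need at least 3 records")
    X = np.column_stack([np.ones_like(L), L, D])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        raise FitError(f"design matrix rank {rank} < 3 (collinear predictors)")
    beta, *_ = np.linalg.lstsq(X, FW, rcond=None)
    return MLRModel(beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]))
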