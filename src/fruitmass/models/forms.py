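"""Allometric two-parameter weight models FW = a + b * f(L, D).

Five basis functions are supported: L*D, L^3, D^3, L*D^2 and L^2*D. Each fit
is the exact closed-form simple-regression solution of weight on the chosen
basis value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from fruitmass.errors import FitError

# Basis functions f(L, D) keyed by form name.
FORM_BASIS: Dict[str, Callable] = {
    "LD": lambda L, D: L * D,
    "L3": lambda L, D: L**3,
    "D3": lambda L, D: D**3,
    "LD2": lambda L, D: L * D**2,
    "L2D": lambda L, D: L**2 * D,
}

FORM_LABELS: Dict[str, str] = {
    "LD": "FW = a + b(LxD)",
    "L3": "FW = a + b(L^3)",
    "D3": "FW = a + b(D^3)",
    "LD2": "FW = a + b(LxD^2)",
    "L2D": "FW = a + b(L^2xD)",
}


def records_to_arrays(records):
    """Extract (L, D, FW) float arrays from a cohort table.

    Accepts a pandas DataFrame with columns length_mm, diameter_mm, weight_g
    (weight may be absent, in which case FW is None).
    """
    L = np.asarray(records["length_mm"], dtype=float)
    D = np.asarray(records["diameter_mm"], dtype=float)
    FW = None
    if "weight_g" in records:
        FW = np.asarray(records["weight_g"], dtype=float)
    return L, D, FW


@dataclass(frozen=True)
class FittedForm:
    """A fitted allometric form FW = a + b * f(L, D)."""

    form: str
    a: float
    b: float

    def __post_init__(self):
        if self.form not in FORM_BASIS:
            raise FitError(f"unknown form {self.form!r}")

    def predict(self, L, D):
        """Evaluate the model at length(s) L and diameter(s) D (mm)."""
        f = FORM_BASIS[self.form]
        return self.a + self.b * f(np.asarray(L, dtype=float), np.asarray(D, dtype=float))

    @property
    def label(self) -> str:
        return FORM_LABELS[self.form]


def fit_form(records, form: str) -> FittedForm:
    """Least-squares fit of one allometric form to a cohort.

    (a, b) is the exact closed-form solution of the simple regression of
    weight on the basis value f(L, D); minimizing RMSE and minimizing the sum
    of squared residuals coincide.

    Raises
    ------
    FitError
        If fewer than 2 records are given or the basis values are constant.
    """
    if form not in FORM_BASIS:
        raise FitError(f"unknown form {form!r}")
    L, D, FW = records_to_arrays(records)
    if FW is None:
        raise FitError("records lack a weight_g column")
    if L.size < 2:
        raise FitError("need at least 2 records")
    x = FORM_BASIS[form](L, D)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0.0:
        raise FitError("constant basis values: singular system")
    b = float(np.sum((x - x.mean()) * (FW - FW.mean())) / sxx)
    a = float(FW.mean() - b * x.mean())
    return FittedForm(form=form, a=a, b=b)
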