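"""Weight-estimator families: allometric forms, MLR, SVR, MLP, model tree."""

import numpy as np

from fruitmass.models.forms import FORM_BASIS, FORM_LABELS, FittedForm, fit_form
from fruitmass.models.kernels import (
    KERNELS,
    kernel_matrix,
    poly2_matrix,
    puk_kernel,
    puk_matrix,
    rbf_matrix,
)
from fruitmass.models.m5p import ModelTree, fit_m5p
from fruitmass.models.mlp import MLPModel, fit_mlp, sweep_hidden_neurons
from fruitmass.models.mlr import MLRModel, fit_mlr
from fruitmass.models.svr import SVRModel, dual_objective, fit_svr, grid_search_svr
from fruitmass.models.serialize import load_model, model_from_dict, model_to_dict, save_model


def predict(model, L, D):
    """Evaluate any fitted model at length(s) L and diameter(s) D (mm)."""
    if not hasattr(model, "predict"):
        raise TypeError(f"{type(model).__name__} is not a fitted model")
    L = np.asarray(L, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(L <= 0) or np.any(D <= 0):
        raise ValueError("L and D must be positive")
    return model.predict(L, D)


__all__ = [
    "FORM_BASIS",
    "FORM_LABELS",
    "KERNELS",
    "FittedForm",
    "MLRModel",
    "SVRModel",
    "MLPModel",
    "ModelTree",
    "fit_form",
    "fit_mlr",
    "fit_svr",
    "fit_mlp",
    "fit_m5p",
    "grid_search_svr",
    "sweep_hidden_neurons",
    "dual_objective",
    "predict",
    "puk_kernel",
    "puk_matrix",
    "rbf_matrix",
    "poly2_matrix",
    "kernel_matrix",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]
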