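"""JSON (de)serialization for every fitted model family."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from fruitmass.models.forms import FittedForm
from fruitmass.models.m5p import ModelTree, _LinearModel, _Node
from fruitmass.models.mlp import MLPModel
from fruitmass.models.mlr import MLRModel
from fruitmass.models.svr import SVRModel


def _node_to_dict(node: _Node) -> dict:
    d = {"n": node.n, "coef": node.model.coef.tolist(), "est_err": node.est_err}
    if not node.is_leaf:
        d.update(
            attr=node.attr,
            threshold=node.threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> _Node:
    node = _Node(n=d["n"], model=_LinearModel(coef=np.asarray(d["coef"])), est_err=d["est_err"])
    if "attr" in d:
        node.attr = d["attr"]
        node.threshold = d["threshold"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def model_to_dict(model) -> dict:
    if isinstance(model, FittedForm):
        return {"family": "form", "form": model.form, "a": model.a, "b": model.b}
    if isinstance(model, MLRModel):
        return {
            "family": "mlr",
            "beta0": model.beta0,
            "beta1": model.beta1,
            "beta2": model.beta2,
        }
    if isinstance(model, SVRModel):
        return {
            "family": "svr",
            "kernel": model.kernel,
            "c": model.c,
            "epsilon": model.epsilon,
            "kernel_params": model.kernel_params,
            "x_mean": model.x_mean.tolist(),
            "x_sd": model.x_sd.tolist(),
            "support_vectors": model.support_vectors.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "bias": model.bias,
            "support": None if model.support_ is None else np.asarray(model.support_).tolist(),
        }
    if isinstance(model, MLPModel):
        return {
            "family": "mlp",
            "hidden": model.hidden,
            "W1": model.W1.tolist(),
            "b1": model.b1.tolist(),
            "W2": model.W2.tolist(),
            "b2": model.b2,
            "x_mean": model.x_mean.tolist(),
            "x_sd": model.x_sd.tolist(),
            "y_mean": model.y_mean,
            "y_sd": model.y_sd,
        }
    if isinstance(model, ModelTree):
        return {
            "family": "m5p",
            "min_instances": model.min_instances,
            "smoothing": model.smoothing,
            "smoothing_k": model.smoothing_k,
            "root": _node_to_dict(model.root),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(d: dict):
    family = d.get("family")
    if family == "form":
        return FittedForm(form=d["form"], a=d["a"], b=d["b"])
    if family == "mlr":
        return MLRModel(beta0=d["beta0"], beta1=d["beta1"], beta2=d["beta2"])
    if family == "svr":
        return SVRModel(
            kernel=d["kernel"],
            c=d["c"],
            epsilon=d["epsilon"],
            kernel_params=d["kernel_params"],
            x_mean=np.asarray(d["x_mean"]),
            x_sd=np.asarray(d["x_sd"]),
            support_vectors=np.asarray(d["support_vectors"]),
            dual_coef=np.asarray(d["dual_coef"]),
            bias=d["bias"],
            support_=None if d.get("support") is None else np.asarray(d["support"]),
        )
    if family == "mlp":
        return MLPModel(
            hidden=d["hidden"],
            W1=np.asarray(d["W1"]),
            b1=np.asarray(d["b1"]),
            W2=np.asarray(d["W2"]),
            b2=d["b2"],
            x_mean=np.asarray(d["x_mean"]),
            x_sd=np.asarray(d["x_sd"]),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
        )
    if family == "m5p":
        return ModelTree(
            root=_node_from_dict(d["root"]),
            min_instances=d["min_instances"],
            smoothing=d["smoothing"],
            smoothing_k=d["smoothing_k"],
        )
    raise ValueError(f"unknown model family {family!r}")


def save_model(model, path, **extra) -> None:
    payload = model_to_dict(model)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path):
    return model_from_dict(json.loads(Path(path).read_text()))
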