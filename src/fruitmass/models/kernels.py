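"""Kernel functions for support vector regression.

Three kernels are exposed: a Gaussian RBF, the Pearson-VII universal kernel
(PUK), and an inhomogeneous degree-2 polynomial. The PUK form is

    k(u, v) = 1 / [1 + (2 * ||u - v|| * sqrt(2^(1/omega) - 1) / sigma)^2]^omega

which interpolates between Gaussian-like (large omega) and Lorentzian-like
(omega = 1) similarity profiles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

KERNELS = ("RBF", "PUK", "POLY2")


def puk_kernel(u, v, omega: float = 1.0, sigma: float = 1.0) -> float:
    """Pearson-VII similarity of two feature vectors, in (0, 1]."""
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    d = float(np.linalg.norm(np.asarray(u, dtype=float) - np.asarray(v, dtype=float)))
    return float(1.0 / (1.0 + (2.0 * d * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma) ** 2) ** omega)


def puk_matrix(U: np.ndarray, V: np.ndarray, omega: float = 1.0, sigma: float = 1.0) -> np.ndarray:
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    d = cdist(np.atleast_2d(U), np.atleast_2d(V))
    return 1.0 / (1.0 + (2.0 * d * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma) ** 2) ** omega


def rbf_matrix(U: np.ndarray, V: np.ndarray, gamma: float) -> np.ndarray:
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d2 = cdist(np.atleast_2d(U), np.atleast_2d(V), "sqeuclidean")
    return np.exp(-gamma * d2)


def poly2_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(U) @ np.atleast_2d(V).T + 1.0) ** 2


def kernel_matrix(name: str, U: np.ndarray, V: np.ndarray, **params) -> np.ndarray:
    """Dispatch a pairwise kernel matrix by kernel name."""
    if name == "PUK":
        return puk_matrix(U, V, omega=params.get("omega", 1.0), sigma=params.get("sigma", 1.0))
    if name == "RBF":
        gamma = params.get("gamma")
        if gamma is None:
            gamma = 1.0 / (2.0 * np.atleast_2d(U).shape[1])
        return rbf_matrix(U, V, gamma=gamma)
    if name == "POLY2":
        return poly2_matrix(U, V)
    raise ValueError(f"unknown kernel {name!r}; choose from {KERNELS}")
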