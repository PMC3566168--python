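"""Gaussian radial-basis-function network with all training points as centers.

The classifier realizes g_j(x) = sum_i w_ij * phi(||x - mu_i||), with
phi(r) = exp(-r^2 / (2 sigma^2)), a fixed bandwidth sigma shared by all
kernels, and every training vector kept as a center mu_i.  Output
weights are the ridge-regularized least-squares solution of
(Phi^T Phi + lambda I) W = Phi^T T against one-hot class targets; with
lambda = 0 and distinct training points the square system interpolates
the targets exactly.  Two output nodes are used, in the order
(binding, non-binding); exact ties at prediction resolve to
non-binding, keeping false positives conservative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

FORMAT_VERSION = 1

#: Output node order: column 0 scores "binding", column 1 "non-binding".
OUTPUT_NODES = ("binding", "non-binding")

DEFAULT_BANDWIDTH = 5.0
DEFAULT_RIDGE = 1e-8


def kernel(x: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||x - mu||^2 / (2 sigma^2)), Euclidean norm."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {mu.shape}")
    if sigma <= 0:
        raise ValueError("bandwidth must be positive")
    return float(np.exp(-np.sum((x - mu) ** 2) / (2.0 * sigma**2)))


def kernel_matrix(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel evaluations of every row of X against every center."""
    if sigma <= 0:
        raise ValueError("bandwidth must be positive")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(centers), "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass
class RbfnModel:
    """Trained network: centers, bandwidth, ridge and output weights."""

    centers: np.ndarray
    weights: np.ndarray  # (k, 2), columns in OUTPUT_NODES order
    sigma: float = DEFAULT_BANDWIDTH
    ridge: float = DEFAULT_RIDGE
    feature_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.centers.shape[0], len(OUTPUT_NODES)):
            raise ValueError(
                f"weights shape {self.weights.shape} inconsistent with "
                f"{self.centers.shape[0]} centers"
            )

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]


def solve_weights(
    Phi: np.ndarray, T: np.ndarray, ridge: float
) -> np.ndarray:
    """Ridge least-squares weights for a design matrix and targets.

    With ridge = 0 the minimum-norm least-squares solution is returned,
    which on a nonsingular square design interpolates T exactly.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge == 0:
        return np.linalg.lstsq(Phi, T, rcond=None)[0]
    A = Phi.T @ Phi + ridge * np.eye(Phi.shape[1])
    return np.linalg.solve(A, Phi.T @ T)


def one_hot_targets(labels: np.ndarray) -> np.ndarray:
    """(n, 2) targets: row [1, 0] for binding (label 1), [0, 1] otherwise."""
    y = np.asarray(labels, dtype=int).ravel()
    T = np.zeros((y.size, 2))
    T[y == 1, 0] = 1.0
    T[y != 1, 1] = 1.0
    return T


def train(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float = DEFAULT_BANDWIDTH,
    ridge: float = DEFAULT_RIDGE,
    feature_spec: dict | None = None,
) -> RbfnModel:
    """Fit the network on a feature table and 0/1 label vector.

    All n training rows become centers; the design matrix is the n x n
    kernel matrix.  Deterministic for fixed inputs.  Requires both
    classes present and finite features.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise ValueError("feature rows and labels differ in length")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    Phi = kernel_matrix(X, X, sigma)
    W = solve_weights(Phi, one_hot_targets(y), ridge)
    return RbfnModel(
        centers=X.copy(),
        weights=W,
        sigma=sigma,
        ridge=ridge,
        feature_spec=dict(feature_spec or {}),
    )


def decision_values(model: RbfnModel, X: np.ndarray) -> np.ndarray:
    """Output-node values g_j(x) for one vector or a stack of vectors."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != model.n_features:
        raise ValueError(
            f"input length {X2.shape[1]} != model feature length {model.n_features}"
        )
    G = kernel_matrix(X2, model.centers, model.sigma) @ model.weights
    return G[0] if single else G


def predict(model: RbfnModel, X: np.ndarray) -> np.ndarray | int:
    """Predicted label(s): 1 = binding, 0 = non-binding.

    The class of the maximal output node wins; an exact tie resolves to
    non-binding.
    """
    G = decision_values(model, X)
    if G.ndim == 1:
        return int(G[0] > G[1])
    return (G[:, 0] > G[:, 1]).astype(int)


def save_model(model: RbfnModel, path: str | Path) -> None:
    """Persist to a self-describing JSON archive (bit-exact round-trip)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "output_nodes": list(OUTPUT_NODES),
        "sigma": model.sigma,
        "ridge": model.ridge,
        "feature_spec": model.feature_spec,
        "centers": model.centers.tolist(),
        "weights": model.weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> RbfnModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return RbfnModel(
        centers=np.asarray(payload["centers"], dtype=float),
        weights=np.asarray(payload["weights"], dtype=float),
        sigma=float(payload["sigma"]),
        ridge=float(payload["ridge"]),
        feature_spec=payload.get("feature_spec", {}),
    )
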