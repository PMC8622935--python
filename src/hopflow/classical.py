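"""Classical Hopfield trainers for comparison: outer-product, perceptron, delta.

These are the standard one-line principles made concrete: Hebbian correlation
on +/-1-mapped states (outer-product rule, OPR), per-node perceptron
memorisation, and logistic least-mean-square (delta rule). Each trainer emits
a valid network (exact symmetry, zero diagonal); perceptron and delta
symmetrise after every epoch since their raw per-node updates are not
symmetric. The learning-curve harness treats trainers as pluggable via
:data:`TRAINERS`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import HopfieldNetwork, PatternSet
from .mef import train as train_mef

__all__ = ["train_opr", "train_perceptron", "train_delta", "TRAINERS"]


def _as_data(data) -> PatternSet:
    return data if isinstance(data, PatternSet) else PatternSet(data)


def train_opr(data) -> HopfieldNetwork:
    """Outer-product (Hebb) rule: W = sum_x q_x s(x) s(x)^T on s = 2x - 1.

    With q the empirical distribution this is the (1/m)-scaled correlation
    over the raw pattern list, duplicates included.
    """
    data = _as_data(data)
    S = 2.0 * data.patterns - 1.0
    W = S.T @ (data.weights[:, None] * S)
    np.fill_diagonal(W, 0.0)
    return HopfieldNetwork(W, np.zeros(data.n))


def train_perceptron(data, epochs: int = 100, lr: float = 0.1) -> HopfieldNetwork:
    """Per-node perceptron memorisation of the patterns.

    Each node i runs perceptron updates on the linear problem
    H(W_i^T x - theta_i) vs target x_i over all patterns; after every epoch the
    weight matrix is symmetrised and its diagonal zeroed. If some pattern is
    still misclassified after the epoch budget the best iterate is returned
    with a warning.
    """
    data = _as_data(data)
    X = data.patterns
    n = data.n
    W = np.zeros((n, n))
    theta = np.zeros(n)
    best = (W, theta, np.inf)
    for _ in range(epochs):
        pred = (X @ W - theta > 0.0).astype(float)
        err = X - pred  # (m, n); +1 means node should fire but does not
        if not err.any():
            return HopfieldNetwork(W, theta)
        W = W + lr * (err.T @ X)
        theta = theta - lr * err.sum(axis=0)
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        n_err = float(np.abs(err).sum())
        if n_err < best[2]:
            best = (W.copy(), theta.copy(), n_err)
    W, theta, n_err = best
    pred = (X @ W - theta > 0.0).astype(float)
    if np.any(pred != X):
        warnings.warn("perceptron did not memorise all patterns within the "
                      "epoch budget; returning best iterate")
    return HopfieldNetwork(W, theta)


def train_delta(data, epochs: int = 200, lr: float = 0.5) -> HopfieldNetwork:
    """Delta rule: gradient descent on sum_x sum_i (x_i - sigma(F_i(x)))^2
    with the logistic sigma, symmetrising each epoch."""
    data = _as_data(data)
    X, q = data.patterns, data.weights
    n = data.n
    W = np.zeros((n, n))
    theta = np.zeros(n)
    for _ in range(epochs):
        F = X @ W - theta
        s = 1.0 / (1.0 + np.exp(-F))
        dF = -2.0 * q[:, None] * (X - s) * s * (1.0 - s)  # dLoss/dF
        gW = dF.T @ X
        gW = gW + gW.T
        np.fill_diagonal(gW, 0.0)
        W = W - lr * gW
        theta = theta + lr * dF.sum(axis=0)
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
    return HopfieldNetwork(W, theta)


def delta_objective(net: HopfieldNetwork, data) -> float:
    """The least-mean-square objective the delta rule descends."""
    data = _as_data(data)
    F = data.patterns @ net.weights - net.thresholds
    s = 1.0 / (1.0 + np.exp(-F))
    return float(data.weights @ ((data.patterns - s) ** 2).sum(axis=1))


#: Pluggable trainer registry used by the learning-curve experiments.
TRAINERS = {
    "mef": lambda data, **kw: train_mef(data, **kw),
    "opr": lambda data, **kw: train_opr(data),
    "perceptron": lambda data, **kw: train_perceptron(data, **kw),
    "delta": lambda data, **kw: train_delta(data, **kw),
}
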