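"""Binary Hopfield networks: energy, threshold dynamics, and bit-flip corruption.

A network is a pair (W, theta): a symmetric zero-diagonal weight matrix and a
threshold vector. States live in {0,1}^n and evolve under deterministic
(zero-temperature) linear-threshold dynamics; each asynchronous sweep can only
lower the energy

    E(x) = -1/2 x^T W x + x^T theta,

so every initial state reaches a fixed point x* = H(W x* - theta) in finitely
many sweeps (H is the Heaviside step with H(0) = 0, i.e. ties switch off).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HopfieldNetwork",
    "PatternSet",
    "corrupt",
    "as_pattern",
    "converge_many",
    "fixed_point_mask",
]

#: A full asynchronous sweep with zero bit changes means a fixed point was
#: reached; the cap is a safety device only (energy monotonicity guarantees
#: termination for valid symmetric networks).
MAX_PASSES = 10_000


def as_pattern(x, n: int | None = None) -> np.ndarray:
    """Validate and return a binary state vector as a float array."""
    x = np.asarray(x, dtype=float).ravel()
    if not np.all((x == 0.0) | (x == 1.0)):
        raise ValueError("pattern entries must be 0 or 1")
    if n is not None and x.size != n:
        raise ValueError(f"pattern length {x.size} does not match network size {n}")
    return x


class HopfieldNetwork:
    """Symmetric zero-diagonal binary Hopfield network.

    Parameters
    ----------
    weights : (n, n) array_like
        Symmetric coupling matrix W with zero diagonal.
    thresholds : (n,) array_like
        Node thresholds theta.
    """

    def __init__(self, weights, thresholds):
        W = np.array(weights, dtype=float)
        theta = np.asarray(thresholds, dtype=float).ravel()
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if W.shape[0] != theta.size:
            raise ValueError("weights and thresholds disagree in size")
        if not np.array_equal(W, W.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("weight diagonal must be zero")
        if not np.all(np.isfinite(W)) or not np.all(np.isfinite(theta)):
            raise ValueError("weights and thresholds must be finite")
        self.weights = W
        self.thresholds = theta

    @property
    def n(self) -> int:
        return self.thresholds.size

    @classmethod
    def zeros(cls, n: int) -> "HopfieldNetwork":
        return cls(np.zeros((n, n)), np.zeros(n))

    # ------------------------------------------------------------------ energy
    def energy(self, x) -> float:
        """E(x) = -1/2 x^T W x + x^T theta."""
        x = as_pattern(x, self.n)
        return float(-0.5 * x @ self.weights @ x + x @ self.thresholds)

    def feedforward(self, x, i: int) -> float:
        """Feedforward input F_i = W_i^T x - theta_i to node ``i``."""
        x = as_pattern(x, self.n)
        if not 0 <= i < self.n:
            raise IndexError(f"node index {i} out of range for n={self.n}")
        return float(self.weights[i] @ x - self.thresholds[i])

    # ---------------------------------------------------------------- dynamics
    def async_pass(self, x, order=None) -> np.ndarray:
        """One asynchronous sweep through all nodes in ``order``.

        Each node is set to H(F_i) using the *running* state; ties (F_i = 0)
        switch the node off. Energy never increases across a sweep.
        """
        x = as_pattern(x, self.n).copy()
        order = self._check_order(order)
        for i in order:
            x[i] = 1.0 if self.weights[i] @ x - self.thresholds[i] > 0.0 else 0.0
        return x

    def converge(self, x, order=None, max_passes: int = MAX_PASSES) -> np.ndarray:
        """Iterate asynchronous sweeps until a full sweep changes nothing."""
        x = as_pattern(x, self.n)
        order = self._check_order(order)
        for _ in range(max_passes):
            nxt = self.async_pass(x, order)
            if np.array_equal(nxt, x):
                return nxt
            x = nxt
        raise RuntimeError(f"no fixed point reached within {max_passes} sweeps")

    def sync_update(self, x) -> np.ndarray:
        """One parallel pass: x'_i = H(F_i(x)) for all nodes simultaneously."""
        x = as_pattern(x, self.n)
        return (self.weights @ x - self.thresholds > 0.0).astype(float)

    def is_fixed_point(self, x) -> bool:
        """True iff x = H(Wx - theta) elementwise."""
        x = as_pattern(x, self.n)
        return bool(np.array_equal(self.sync_update(x), x))

    def _check_order(self, order):
        if order is None:
            return np.arange(self.n)
        order = np.asarray(order, dtype=int).ravel()
        if not np.array_equal(np.sort(order), np.arange(self.n)):
            raise ValueError("order must be a permutation of 0..n-1")
        return order

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"HopfieldNetwork(n={self.n})"


def corrupt(x, p: float, rng: np.random.Generator) -> np.ndarray:
    """p-corruption: flip each bit independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"corruption probability must be in [0, 1], got {p}")
    x = as_pattern(x)
    flips = rng.random(x.size) < p
    return np.abs(x - flips.astype(float))


class PatternSet:
    """A weighted collection of binary patterns (an empirical distribution q).

    Duplicate patterns are merged and their weights accumulated, so
    ``patterns`` holds unique rows and ``weights`` sums to one.
    """

    def __init__(self, patterns, weights=None):
        X = np.atleast_2d(np.asarray(patterns, dtype=float))
        if X.size == 0:
            raise ValueError("pattern set must contain at least one pattern")
        if not np.all((X == 0.0) | (X == 1.0)):
            raise ValueError("pattern entries must be 0 or 1")
        if weights is None:
            w = np.full(X.shape[0], 1.0 / X.shape[0])
        else:
            w = np.asarray(weights, dtype=float).ravel()
            if w.size != X.shape[0]:
                raise ValueError("one weight per pattern required")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            total = w.sum()
            if not np.isclose(total, 1.0, atol=1e-8):
                w = w / total
        # merge duplicates into frequencies
        uniq, inv = np.unique(X, axis=0, return_inverse=True)
        merged = np.zeros(uniq.shape[0])
        np.add.at(merged, inv, w)
        self.patterns = uniq
        self.weights = merged

    @classmethod
    def uniform_over_unique(cls, patterns) -> "PatternSet":
        """Weight unique patterns uniformly, ignoring duplication counts."""
        uniq = np.unique(np.atleast_2d(np.asarray(patterns, dtype=float)), axis=0)
        return cls(uniq)

    @property
    def n(self) -> int:
        return self.patterns.shape[1]

    @property
    def m(self) -> int:
        return self.patterns.shape[0]

    def __len__(self) -> int:
        return self.m


def converge_many(net: HopfieldNetwork, X, order=None, max_passes: int = MAX_PASSES) -> np.ndarray:
    """Converge every row of ``X`` under asynchronous dynamics (vectorised).

    Equivalent to ``net.converge`` applied row by row with the same node
    order, but sweeps all rows simultaneously.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
    order = net._check_order(order)
    W, theta = net.weights, net.thresholds
    active = np.arange(X.shape[0])
    for _ in range(max_passes):
        before = X[active].copy()
        for i in order:
            X[active, i] = (X[active] @ W[i] - theta[i] > 0.0).astype(float)
        changed = np.any(X[active] != before, axis=1)
        active = active[changed]
        if active.size == 0:
            return X
    raise RuntimeError(f"not all rows converged within {max_passes} sweeps")


def fixed_point_mask(net: HopfieldNetwork, X) -> np.ndarray:
    """Boolean mask of which rows of ``X`` satisfy x = H(Wx - theta)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    H = (X @ net.weights - net.thresholds > 0.0).astype(float)
    return np.all(H == X, axis=1)
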