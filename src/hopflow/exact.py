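"""Exact 2^n-state Lenz-Ising computations and the energy-flow projection bound.

For small n the full Boltzmann distribution p_x = e^{-E_x}/Z can be enumerated,
along with the flow matrix M whose off-diagonal entries couple Hamming-1
neighbours,

    M_yx = e^{(E_x - E_y)/2}   for y one bit flip from x,

with diagonal chosen so every column sums to zero. M satisfies detailed
balance with p (hence M p = 0), and its second smallest singular value sigma_2
controls how tightly the energy-flow objective bounds the distance between a
data distribution q and its projection onto the model:

    || q - (<q,p>/<p,p>) p ||_2  <=  (2 / sigma_2) * EF(q).

State ordering convention: state index s encodes x with x_i = bit i of s
(little-endian), shared by all arrays in this module.
"""

from __future__ import annotations

import numpy as np

from .network import HopfieldNetwork

__all__ = [
    "STATE_CAP",
    "all_states",
    "state_energies",
    "boltzmann",
    "flow_matrix",
    "sigma2",
    "projection_residual",
    "energy_flow_exact",
    "check_theorem1",
]

#: Enumeration cap: 2^12 = 4096 states keeps dense SVDs cheap on one CPU.
STATE_CAP = 12


class ExactDistribution:
    """Full Boltzmann distribution over 2^n states, plus the partition function."""

    def __init__(self, n: int, probabilities: np.ndarray, partition_function: float):
        self.n = n
        self.probabilities = probabilities
        self.partition_function = partition_function


class FlowMatrix:
    """Dense 2^n x 2^n flow matrix in the little-endian state ordering."""

    def __init__(self, n: int, entries: np.ndarray):
        self.n = n
        self.entries = entries


def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise ValueError(f"exact enumeration limited to n <= {cap} (got n={n})")


def all_states(n: int) -> np.ndarray:
    """(2^n, n) matrix of states; row s has x_i = bit i of s."""
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def state_energies(net: HopfieldNetwork) -> np.ndarray:
    X = all_states(net.n)
    return -0.5 * np.einsum("si,ij,sj->s", X, net.weights, X) + X @ net.thresholds


def boltzmann(net: HopfieldNetwork, cap: int = STATE_CAP) -> ExactDistribution:
    """Exact Lenz-Ising distribution p_x = e^{-E_x} / Z by enumeration.

    Energies are shifted by their minimum before exponentiation, so the
    largest exponent is zero and overflow cannot occur.
    """
    _check_cap(net.n, cap)
    E = state_energies(net)
    shift = E.min()
    unnorm = np.exp(-(E - shift))
    Z = unnorm.sum() * np.exp(-shift) if np.isfinite(np.exp(-shift)) else np.inf
    p = unnorm / unnorm.sum()
    return ExactDistribution(net.n, p, float(Z))


def flow_matrix(net: HopfieldNetwork, cap: int = STATE_CAP) -> FlowMatrix:
    _check_cap(net.n, cap)
    n = net.n
    E = state_energies(net)
    N = 2**n
    M = np.zeros((N, N))
    xs = np.arange(N)
    for i in range(n):
        ys = xs ^ (1 << i)
        M[ys, xs] = np.exp((E[xs] - E[ys]) / 2.0)
    M[xs, xs] = -M.sum(axis=0)  # exact zero column sums
    return FlowMatrix(n, M)


def sigma2(M: FlowMatrix) -> float:
    """Second smallest singular value of the flow matrix (positive: the
    one-flip graph on states is connected, so only one singular value is ~0)."""
    s = np.linalg.svd(M.entries, compute_uv=False)
    return float(s[-2])


def projection_residual(q, p: ExactDistribution) -> float:
    """l2 norm of q minus its scalar projection onto the model distribution p."""
    q = np.asarray(q, dtype=float).ravel()
    pv = p.probabilities
    if q.size != pv.size:
        raise ValueError("q and p must share the state space")
    proj = (q @ pv) / (pv @ pv) * pv
    return float(np.linalg.norm(q - proj))


def energy_flow_exact(net: HopfieldNetwork, q, cap: int = STATE_CAP) -> float:
    """EF computed from the flow matrix's off-diagonal column mass.

    EF = sum_x q_x sum_{x' in N1(x)} M_{x'x} = <q, -diag(M)>; an independent
    code path from the data-side objective in :mod:`hopflow.mef`.
    """
    _check_cap(net.n, cap)
    M = flow_matrix(net, cap).entries
    q = np.asarray(q, dtype=float).ravel()
    if q.size != M.shape[0]:
        raise ValueError("q must have one entry per state")
    return float(q @ (-np.diag(M)))


def check_theorem1(net: HopfieldNetwork, q, cap: int = STATE_CAP):
    """Numerically evaluate the projection bound for a data distribution q.

    Returns ``(lhs, rhs, holds)`` with lhs the projection residual and
    rhs = (2/sigma_2) * EF.
    """
    _check_cap(net.n, cap)
    p = boltzmann(net, cap)
    M = flow_matrix(net, cap)
    lhs = projection_residual(q, p)
    rhs = 2.0 * energy_flow_exact(net, q, cap) / sigma2(M)
    return lhs, rhs, bool(lhs <= rhs + 1e-9)
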