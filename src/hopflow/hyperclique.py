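"""Hyperclique attractor codes: exponential-capacity Hopfield networks.

Nodes of the network are the (d+1)-element subsets of a v-element vertex set
(n = C(v, d+1) nodes). A d-uniform hypergraph G is encoded as the indicator
x(G) of its hypercliques: node i fires iff every d-subset of V_i is a
hyperedge of G. Two nodes are coupled (i ~ j) when their subsets share
exactly d vertices, all coupled pairs carry the same weight x >= 0, and every
node the same threshold z, so a node's decision compares x * (number of
active neighbours) against z. With the energy-flow-optimal ratio

    x / z = 2^{d+1} / ((2d+1) v)

almost every random hypergraph (each d-subset present independently with
probability 1/2) is robustly stored, giving 2^{Theta(v^d)} memories on
n = Theta(v^{d+1}) nodes — exponential capacity with error correction.

The set S of "typical" hypergraphs is certified by counting, for each node,
its complete neighbours w(G, i): complete nodes must have w at least
(1-eps)(d+1)v/2^d, incomplete nodes at most (1+eps) d v / 2^d, and the total
number of complete nodes must be within (1 +/- eps) of 2^-(d+1) C(v, d+1).
The first two bounds are one-sided — exactly what the fixed-point and
recovery margins consume; with both vertices of a pair absent (d=1) a node
legitimately has w near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from .network import HopfieldNetwork, corrupt

__all__ = [
    "HypergraphSpec",
    "CodeNetwork",
    "SToleranceParams",
    "node_subsets",
    "adjacent",
    "build_code",
    "analytic_weight",
    "analytic_weights",
    "robustness_index",
    "random_hypergraph",
    "sample_hypergraph_in_S",
    "robustness_sim",
    "fit_weight_ratio",
]

#: Dense-matrix cap on the node count C(v, d+1).
NODE_CAP = 20_000


@dataclass(frozen=True)
class HypergraphSpec:
    """A d-uniform hypergraph on vertices {0..v-1}."""

    v: int
    d: int
    hyperedges: frozenset

    def __post_init__(self):
        for e in self.hyperedges:
            if len(set(e)) != self.d or not all(0 <= u < self.v for u in e):
                raise ValueError(f"hyperedge {e} is not a d-subset of the vertex set")

    @classmethod
    def from_edges(cls, v: int, d: int, edges) -> "HypergraphSpec":
        return cls(v, d, frozenset(tuple(sorted(e)) for e in edges))


def node_subsets(v: int, d: int) -> list:
    """All (d+1)-subsets of {0..v-1} in colexicographic order."""
    if v <= d + 1:
        raise ValueError(f"need v > d+1 (got v={v}, d={d})")
    return sorted(combinations(range(v), d + 1), key=lambda t: tuple(reversed(t)))


def adjacent(Vi, Vj) -> bool:
    """Coupling test: subsets of equal size d+1 sharing exactly d vertices.

    For d = 1 this is the familiar "pairs sharing exactly one vertex".
    """
    Vi, Vj = set(Vi), set(Vj)
    if len(Vi) != len(Vj):
        raise ValueError("subsets must have equal size")
    return len(Vi & Vj) == len(Vi) - 1


@dataclass
class SToleranceParams:
    """Slack schedule implementing the (1 +/- o(1)) factors of the S conditions.

    eps(v) = min(eps_max, c log v / sqrt(v)). The ceiling eps_max = 0.22 is
    what makes S-membership *certify* the fixed-point margins: the complete-
    node bound needs eps < 1/(2(d+1)) (0.25 at d=1), and the strict-inequality
    tie rule consumes a little headroom on top.
    """

    c: float = 3.0
    eps_max: float = 0.22

    def epsilon(self, v: int) -> float:
        eps = min(self.eps_max, self.c * math.log(v) / math.sqrt(v))
        if not 0.0 < eps < 1.0:
            raise ValueError("tolerance must land in (0, 1)")
        return eps


class CodeNetwork:
    """The two-parameter (x, z) network on (d+1)-subset nodes."""

    def __init__(self, v: int, d: int, weight_value: float, threshold_value: float = 1.0):
        if weight_value < 0:
            raise ValueError("weight_value must be nonnegative")
        n = math.comb(v, d + 1)
        if n > NODE_CAP:
            raise ValueError(f"node count C({v},{d + 1}) = {n} exceeds cap {NODE_CAP}")
        self.v = v
        self.d = d
        self.weight_value = float(weight_value)
        self.threshold_value = float(threshold_value)
        self.subsets = node_subsets(v, d)
        self.n = n
        S = np.zeros((n, v))
        for i, s in enumerate(self.subsets):
            S[i, list(s)] = 1.0
        self._S = S
        inter = np.rint(S @ S.T).astype(np.int64)
        A = (inter == d)
        np.fill_diagonal(A, False)
        self.adjacency = A
        # index of each node's (d+1) constituent d-subsets into the edge list
        edges = list(combinations(range(v), d))
        self._edge_index = {e: k for k, e in enumerate(edges)}
        self.n_edges = len(edges)
        self._sub_edges = np.array(
            [[self._edge_index[e] for e in combinations(s, d)] for s in self.subsets]
        )

    # ------------------------------------------------------------------ codec
    def _edge_flags(self, G: HypergraphSpec) -> np.ndarray:
        if (G.v, G.d) != (self.v, self.d):
            raise ValueError("hypergraph (v, d) does not match the code network")
        flags = np.zeros(self.n_edges, dtype=bool)
        for e in G.hyperedges:
            flags[self._edge_index[e]] = True
        return flags

    def complete_mask(self, G: HypergraphSpec) -> np.ndarray:
        """Which nodes are hypercliques of G."""
        return self._edge_flags(G)[self._sub_edges].all(axis=1)

    def encode(self, G: HypergraphSpec) -> np.ndarray:
        """The codeword x(G): hyperclique indicator over the nodes."""
        return self.complete_mask(G).astype(float)

    def w_counts(self, G: HypergraphSpec) -> np.ndarray:
        """w(G, i): number of complete neighbours of each node.

        The companion count w'(G, i) of incomplete neighbours satisfies
        w + w' = (d+1)(v - (d+1)).
        """
        return self.adjacency @ self.complete_mask(G).astype(np.int64)

    def w_count(self, G: HypergraphSpec, i: int) -> int:
        if not 0 <= i < self.n:
            raise IndexError(f"node index {i} out of range")
        return int(self.w_counts(G)[i])

    def in_S(self, G: HypergraphSpec, tol: SToleranceParams | None = None) -> bool:
        """Membership in the robustly-stored set S (see module docstring)."""
        tol = tol or SToleranceParams()
        eps = tol.epsilon(self.v)
        comp = self.complete_mask(G)
        w = self.adjacency @ comp.astype(np.int64)
        base = self.v / 2**self.d
        if comp.any() and w[comp].min() < (1.0 - eps) * (self.d + 1) * base:
            return False
        if (~comp).any() and w[~comp].max() > (1.0 + eps) * self.d * base:
            return False
        expected = 2.0 ** -(self.d + 1) * self.n
        return abs(int(comp.sum()) - expected) <= eps * expected

    # --------------------------------------------------------------- dynamics
    def decode(self, y, mode: str = "single_sync") -> np.ndarray:
        """Run the attractor dynamics on a (possibly corrupted) word."""
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.n:
            raise ValueError("word length does not match node count")
        if mode == "single_sync":
            drive = self.weight_value * (self.adjacency @ y)
            return (drive > self.threshold_value).astype(float)
        if mode == "converge":
            return self.to_network().converge(y)
        raise ValueError(f"unknown decode mode {mode!r}")

    def to_network(self) -> HopfieldNetwork:
        W = self.weight_value * self.adjacency.astype(float)
        return HopfieldNetwork(W, np.full(self.n, self.threshold_value))


def analytic_weight(v: int, d: int, z: float = 1.0) -> float:
    """The energy-flow-optimal coupling x = 2^{d+1} z / ((2d+1) v)."""
    if z <= 0:
        raise ValueError("z must be positive")
    return 2.0 ** (d + 1) * z / ((2 * d + 1) * v)


def analytic_weights(v: int, d: int, z: float = 1.0) -> CodeNetwork:
    """Build the code network with the analytic (x, z) setting."""
    return CodeNetwork(v, d, analytic_weight(v, d, z), z)


def build_code(v: int, d: int, weight_value: float | None = None, z: float = 1.0) -> CodeNetwork:
    if weight_value is None:
        return analytic_weights(v, d, z)
    return CodeNetwork(v, d, weight_value, z)


def robustness_index(d: int, variant: str = "constructed") -> float:
    """Asymptotic index of robustness alpha for the hyperclique construction.

    "constructed": alpha = 1 / (2^d (d+1) - 2d), the best achievable by
    choosing (x, z) freely; "mef_trained": alpha = 1 / (2^{d+1}(d+1) - 4d),
    what the energy-flow-optimal (x, z) attains.
    """
    if d < 1:
        raise ValueError("d must be at least 1")
    if variant == "constructed":
        return 1.0 / (2**d * (d + 1) - 2 * d)
    if variant == "mef_trained":
        return 1.0 / (2 ** (d + 1) * (d + 1) - 4 * d)
    raise ValueError(f"unknown variant {variant!r}")


def random_hypergraph(v: int, d: int, rng: np.random.Generator) -> HypergraphSpec:
    """Each d-subset of the vertex set is a hyperedge independently w.p. 1/2."""
    if v <= d:
        raise ValueError("need v > d")
    edges = [e for e in combinations(range(v), d) if rng.random() < 0.5]
    return HypergraphSpec.from_edges(v, d, edges)


def sample_hypergraph_in_S(
    code: CodeNetwork,
    rng: np.random.Generator,
    tol: SToleranceParams | None = None,
    cap: int = 1000,
) -> HypergraphSpec:
    """Rejection-sample a random hypergraph lying in S."""
    for _ in range(cap):
        G = random_hypergraph(code.v, code.d, rng)
        if code.in_S(G, tol):
            return G
    raise RuntimeError(
        f"no hypergraph accepted into S within {cap} draws; "
        "consider a looser tolerance (larger eps)"
    )


def robustness_sim(
    v: int,
    d: int,
    p_grid,
    trials: int,
    mode: str = "single_sync",
    rng: np.random.Generator | None = None,
    tol: SToleranceParams | None = None,
    z: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo recovery fractions of p-corrupted codewords.

    For each corruption rate p: draw a hypergraph in S, corrupt its codeword,
    run the dynamics, and record whether the exact codeword is recovered.
    """
    if trials < 1:
        raise ValueError("trials must be at least 1")
    rng = rng or np.random.default_rng()
    code = analytic_weights(v, d, z)
    rows = []
    for p in p_grid:
        hits = 0
        for _ in range(trials):
            G = sample_hypergraph_in_S(code, rng, tol)
            x = code.encode(G)
            y = corrupt(x, p, rng)
            hits += int(np.array_equal(code.decode(y, mode), x))
        rows.append({"p": float(p), "recovery_fraction": hits / trials, "trials": trials})
    return pd.DataFrame(rows)


def fit_weight_ratio(
    v: int,
    d: int,
    n_samples: int = 50,
    z: float = 10.0,
    rng: np.random.Generator | None = None,
    tol: SToleranceParams | None = None,
):
    """Recover the coupling by constrained energy-flow minimisation.

    Holds the network on its two-parameter family (uniform coupling x on
    adjacent pairs, uniform threshold z) and minimises the empirical energy
    flow of sampled S-codewords over x with z fixed. Flipping node i of a
    codeword changes the energy by -w(G,i) x + z when i is complete and
    w(G,i) x - z when incomplete, so EF reduces to a scalar convex function
    of x. The minimiser's ratio x/z approaches 2^{d+1}/((2d+1) v); the fixed
    z defaults to 10 because the exact stationarity condition carries an
    additive log-term offset to z that only vanishes relative to a large z.

    Returns ``(x_hat, z, ratio)``.
    """
    rng = rng or np.random.default_rng()
    code = analytic_weights(v, d, z)
    w_complete, w_incomplete = [], []
    for _ in range(n_samples):
        G = sample_hypergraph_in_S(code, rng, tol)
        comp = code.complete_mask(G)
        w = code.adjacency @ comp.astype(np.int64)
        w_complete.append(w[comp])
        w_incomplete.append(w[~comp])
    wc = np.concatenate(w_complete).astype(float)
    wi = np.concatenate(w_incomplete).astype(float)

    def ef(x):
        return (np.exp((-wc * x + z) / 2.0).sum() + np.exp((wi * x - z) / 2.0).sum()) / n_samples

    hi = 10.0 * analytic_weight(v, d, z)
    res = optimize.minimize_scalar(ef, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-10})
    x_hat = float(res.x)
    return x_hat, z, x_hat / z
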