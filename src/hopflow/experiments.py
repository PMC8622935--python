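"""Computational experiments: cluster-entropy estimation, hidden-clique
learning curves, and critical-ratio scaling.

Three simulations exercise the learning machinery end to end:

* *Clustering*: samples from a mixture of K hidden binary cluster centers,
  corrupted by independent bit flips at rate p, are used to train a network;
  converging every sample and taking the Shannon entropy of the resulting
  fixed points estimates the source entropy log2 K. With enough samples and
  moderate noise the attractors are exactly the hidden centers.
* *Hidden cliques*: the k-cliques of a v-vertex graph, encoded as edge
  indicators on n = C(v, 2) nodes, are memorised from a random training
  fraction; storage is evaluated on all cliques, comparing MEF with the
  classical rules.
* *Critical ratio*: the smallest number c(v) of training cliques for which a
  network trained with MEF reaches a target accuracy on unseen test cliques,
  reported as the ratio c(v)/C(v, k); along v = 2k the ratio collapses
  rapidly with v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, islice

import numpy as np
import pandas as pd

from .classical import TRAINERS
from .mef import MinimumEnergyFlow, TrainingOptions
from .network import HopfieldNetwork, PatternSet, converge_many, corrupt, fixed_point_mask
from .hyperclique import node_subsets

__all__ = [
    "ClusterExperimentConfig",
    "CriticalSearchConfig",
    "make_clusters",
    "sample_mixture",
    "attractor_entropy",
    "distinct_attractors",
    "clustering_experiment",
    "clique_patterns",
    "cliques_to_patterns",
    "storage_fraction",
    "learning_curve",
    "critical_ratio",
    "critical_trend",
]


# --------------------------------------------------------------------- mixtures
def make_clusters(K: int, n: int, rng: np.random.Generator, retries: int = 100) -> np.ndarray:
    """K distinct uniform random binary cluster centers in dimension n."""
    if K > 2**min(n, 62):
        raise ValueError("cannot draw K distinct centers in this dimension")
    for _ in range(retries):
        centers = (rng.random((K, n)) < 0.5).astype(float)
        if np.unique(centers, axis=0).shape[0] == K:
            return centers
    raise RuntimeError("failed to draw distinct centers within retry cap")


def sample_mixture(centers, m: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """m samples: a uniformly chosen center with i.i.d. bit flips at rate p."""
    if m < 1:
        raise ValueError("need at least one sample")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    idx = rng.integers(0, centers.shape[0], size=m)
    X = centers[idx]
    flips = rng.random(X.shape) < p
    return np.abs(X - flips.astype(float))


def _attractors(net: HopfieldNetwork, samples) -> tuple[np.ndarray, np.ndarray]:
    fixed = converge_many(net, np.atleast_2d(np.asarray(samples, dtype=float)))
    uniq, counts = np.unique(fixed, axis=0, return_counts=True)
    return uniq, counts


def attractor_entropy(net: HopfieldNetwork, samples) -> float:
    """Shannon entropy (bits) of the fixed points reached from the samples."""
    if isinstance(samples, PatternSet):
        fixed = converge_many(net, samples.patterns)
        uniq, inv = np.unique(fixed, axis=0, return_inverse=True)
        freq = np.zeros(uniq.shape[0])
        np.add.at(freq, inv, samples.weights)
    else:
        _, counts = _attractors(net, samples)
        freq = counts / counts.sum()
    freq = freq[freq > 0]
    return float(-(freq * np.log2(freq)).sum())


def distinct_attractors(net: HopfieldNetwork, samples) -> int:
    """Number of distinct fixed points reached from the samples."""
    X = samples.patterns if isinstance(samples, PatternSet) else samples
    return int(_attractors(net, X)[0].shape[0])


@dataclass
class ClusterExperimentConfig:
    K: int = 64
    n: int = 256
    m: int = 32768
    p: float = 0.1
    rule: str = "mef"
    seed: int = 0
    train_options: TrainingOptions = field(default_factory=lambda: TrainingOptions(max_iterations=300))

    def __post_init__(self):
        if self.K < 1 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid cluster experiment configuration")


def clustering_experiment(cfg: ClusterExperimentConfig):
    """Train on a corrupted mixture and measure the attractor statistics.

    Returns ``(row, details)``: a tidy summary row (p, m, entropy, number of
    attractors) and a dict with the centers, samples, network and attractors.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = make_clusters(cfg.K, cfg.n, rng)
    samples = sample_mixture(centers, cfg.m, cfg.p, rng)
    if cfg.rule == "mef":
        net = MinimumEnergyFlow(samples).fit(cfg.train_options).network
    else:
        net = TRAINERS[cfg.rule](PatternSet(samples))
    uniq, counts = _attractors(net, samples)
    freq = counts / counts.sum()
    entropy = float(-(freq * np.log2(freq)).sum())
    row = {
        "K": cfg.K, "n": cfg.n, "m": cfg.m, "p": cfg.p, "rule": cfg.rule,
        "seed": cfg.seed, "entropy_bits": entropy, "n_attractors": uniq.shape[0],
    }
    details = {"centers": centers, "samples": samples, "network": net,
               "attractors": uniq, "counts": counts}
    return row, details


# ----------------------------------------------------------------- clique tasks
def _pair_matrix(v: int) -> np.ndarray:
    pairs = node_subsets(v, 1)
    S = np.zeros((len(pairs), v))
    for i, (a, b) in enumerate(pairs):
        S[i, a] = S[i, b] = 1.0
    return S


def cliques_to_patterns(v: int, subsets) -> np.ndarray:
    """Edge-indicator patterns of vertex subsets, on the C(v,2) pair nodes."""
    S = _pair_matrix(v)
    out = np.zeros((len(subsets), S.shape[0]))
    for r, sub in enumerate(subsets):
        g = np.zeros(v)
        g[list(sub)] = 1.0
        out[r] = (np.rint(S @ g) == 2).astype(float)
    return out


def clique_patterns(v: int, k: int) -> PatternSet:
    """All C(v, k) k-clique patterns on n = C(v, 2) nodes."""
    if k > v:
        raise ValueError("clique size cannot exceed vertex count")
    subs = list(combinations(range(v), k))
    return PatternSet(cliques_to_patterns(v, subs))


def storage_fraction(net: HopfieldNetwork, patterns) -> float:
    """Fraction of the patterns that are exact fixed points of the network."""
    X = patterns.patterns if isinstance(patterns, PatternSet) else np.atleast_2d(patterns)
    return float(fixed_point_mask(net, X).mean())


def learning_curve(
    rule: str,
    v: int,
    k: int,
    ratio_grid,
    trials: int,
    rng: np.random.Generator,
    train_options: TrainingOptions | None = None,
) -> pd.DataFrame:
    """Storage on all k-cliques vs the fraction of them used for training."""
    if rule not in TRAINERS:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(TRAINERS)}")
    all_patterns = clique_patterns(v, k).patterns
    M = all_patterns.shape[0]
    kwargs = {"options": train_options} if (rule == "mef" and train_options) else {}
    rows = []
    for ratio in ratio_grid:
        if not 0.0 < ratio <= 1.0:
            raise ValueError("training ratios must lie in (0, 1]")
        count = max(1, math.ceil(ratio * M))
        fracs = []
        for _ in range(trials):
            pick = rng.choice(M, size=count, replace=False)
            net = TRAINERS[rule](PatternSet(all_patterns[pick]), **kwargs)
            fracs.append(storage_fraction(net, all_patterns))
        rows.append({
            "rule": rule, "ratio": float(ratio), "n_train": count,
            "mean_fraction": float(np.mean(fracs)), "sd_fraction": float(np.std(fracs)),
            "trials": trials,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------- critical ratio
@dataclass
class CriticalSearchConfig:
    v: int
    k: int
    criterion: float = 0.5
    test_size: int = 1000
    trials: int = 5
    search_rel_tol: float = 0.25
    max_train: int = 4096
    seed: int = 0
    train_options: TrainingOptions = field(default_factory=lambda: TrainingOptions(max_iterations=200))

    def __post_init__(self):
        if not 0.0 < self.criterion < 1.0:
            raise ValueError("accuracy criterion must lie in (0, 1)")


def _sample_distinct_subsets(v: int, k: int, count: int, rng: np.random.Generator) -> list:
    total = math.comb(v, k)
    if count > total:
        raise ValueError("cannot sample more distinct cliques than exist")
    if total <= 200_000:
        allsubs = list(combinations(range(v), k))
        idx = rng.choice(total, size=count, replace=False)
        return [allsubs[i] for i in idx]
    seen: set = set()
    while len(seen) < count:  # collisions vanishingly rare for huge C(v,k)
        seen.add(tuple(sorted(rng.choice(v, size=k, replace=False))))
    return sorted(seen)


def _clique_accuracy(v, k, n_train, cfg: CriticalSearchConfig, rng) -> float:
    train_subs = _sample_distinct_subsets(v, k, n_train, rng)
    net = MinimumEnergyFlow(cliques_to_patterns(v, train_subs)).fit(cfg.train_options).network
    test_subs = [tuple(sorted(rng.choice(v, size=k, replace=False)))
                 for _ in range(cfg.test_size)]
    return storage_fraction(net, cliques_to_patterns(v, test_subs))


def critical_ratio(cfg: CriticalSearchConfig, rng: np.random.Generator | None = None):
    """Smallest training-clique count reaching the accuracy criterion.

    Doubles the training count until the criterion is met on fresh test
    cliques, then bisects the bracket down to ``search_rel_tol``. Returns
    ``(c_v, ratio)`` with ratio = c_v / C(v, k).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    v, k = cfg.v, cfg.k
    total = math.comb(v, k)
    cap = min(cfg.max_train, total)
    lo, hi = 0, 1
    while True:
        acc = _clique_accuracy(v, k, hi, cfg, rng)
        if acc >= cfg.criterion:
            break
        lo = hi
        if hi >= cap:
            raise RuntimeError(
                f"accuracy criterion {cfg.criterion} not reached with "
                f"{cap} training cliques at v={v}, k={k}"
            )
        hi = min(2 * hi, cap)
    while hi - lo > 1 and (hi - lo) > cfg.search_rel_tol * hi:
        mid = (lo + hi) // 2
        if _clique_accuracy(v, k, mid, cfg, rng) >= cfg.criterion:
            hi = mid
        else:
            lo = mid
    return hi, hi / total


def critical_trend(
    vs,
    v_over_k: int = 2,
    trials: int = 5,
    seed: int = 0,
    **cfg_kwargs,
) -> pd.DataFrame:
    """Mean critical ratio across a grid of v at fixed v/k."""
    rows = []
    for v in vs:
        k = v // v_over_k
        counts, ratios = [], []
        for t in range(trials):
            cfg = CriticalSearchConfig(v=v, k=k, seed=seed * 1000 + t, **cfg_kwargs)
            c_v, ratio = critical_ratio(cfg, np.random.default_rng(cfg.seed))
            counts.append(c_v)
            ratios.append(ratio)
        rows.append({
            "v": v, "k": k, "mean_c": float(np.mean(counts)),
            "mean_ratio": float(np.mean(ratios)),
            "log10_ratio": float(np.log10(np.mean(ratios))),
            "trials": trials,
        })
    return pd.DataFrame(rows)
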