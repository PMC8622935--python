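"""Serialization: pattern files, network files, hypergraph files.

Pattern files are plain text, one contiguous '0'/'1' string per line, with
'#' comment lines ignored. Network files are NumPy ``.npz`` archives with a
JSON metadata header (format version, node count, creation seed) plus the
dense weight matrix and threshold vector at full floating precision.
Hypergraph files are text edge lists, one hyperedge per line as space-
separated 0-based vertex indices, with a ``# v=... d=...`` header.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .hyperclique import HypergraphSpec
from .network import HopfieldNetwork, PatternSet

__all__ = [
    "read_patterns",
    "read_pattern_array",
    "write_patterns",
    "read_network",
    "write_network",
    "read_hypergraph",
    "write_hypergraph",
]

NETWORK_FORMAT_VERSION = 1


# ------------------------------------------------------------------- patterns
def read_pattern_array(path) -> np.ndarray:
    """Raw pattern rows (duplicates preserved) from a text file."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if set(line) - {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: non-binary character in pattern")
            if width is None:
                width = len(line)
            elif len(line) != width:
                raise ValueError(f"{path}:{lineno}: ragged pattern length "
                                 f"({len(line)} != {width})")
            rows.append([float(c) for c in line])
    if not rows:
        raise ValueError(f"{path}: no patterns found")
    return np.asarray(rows)


def read_patterns(path) -> PatternSet:
    """Pattern file as an empirical distribution (duplicates merged)."""
    return PatternSet(read_pattern_array(path))


def write_patterns(patterns, path) -> None:
    X = patterns.patterns if isinstance(patterns, PatternSet) else np.atleast_2d(patterns)
    with open(path, "w") as fh:
        for row in X:
            fh.write("".join("1" if b else "0" for b in row) + "\n")


# -------------------------------------------------------------------- networks
def write_network(net: HopfieldNetwork, path, seed: int | None = None) -> None:
    meta = json.dumps({"version": NETWORK_FORMAT_VERSION, "n": net.n, "seed": seed})
    np.savez(path, meta=np.array(meta), weights=net.weights, thresholds=net.thresholds)


def read_network(path):
    """Load a network; returns ``(net, metadata)``. Validates the invariants."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        W = data["weights"]
        theta = data["thresholds"]
    if meta.get("version") != NETWORK_FORMAT_VERSION:
        raise ValueError(f"unsupported network file version {meta.get('version')!r}")
    if not np.array_equal(W, W.T):
        raise ValueError("corrupt network file: stored weights are asymmetric")
    if np.any(np.diag(W) != 0.0):
        raise ValueError("corrupt network file: nonzero weight diagonal")
    return HopfieldNetwork(W, theta), meta


# ------------------------------------------------------------------ hypergraphs
def write_hypergraph(G: HypergraphSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# v={G.v} d={G.d}\n")
        for e in sorted(G.hyperedges):
            fh.write(" ".join(str(u) for u in e) + "\n")


def read_hypergraph(path) -> HypergraphSpec:
    v = d = None
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("v="):
                        v = int(tok[2:])
                    elif tok.startswith("d="):
                        d = int(tok[2:])
                continue
            edge = tuple(sorted(int(t) for t in line.split()))
            if d is not None and len(edge) != d:
                raise ValueError(f"{path}:{lineno}: hyperedge arity {len(edge)} != d={d}")
            edges.append(edge)
    if v is None or d is None:
        raise ValueError(f"{path}: missing '# v=... d=...' header")
    if len(set(edges)) != len(edges):
        warnings.warn(f"{path}: duplicate hyperedges were deduplicated")
    return HypergraphSpec.from_edges(v, d, edges)
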