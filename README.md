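# hopflow

Hopfield attractor networks learned by **minimum energy flow (MEF)** — a
convex objective for turning binary data into fixed-point memories — with
exact small-network Lenz–Ising diagnostics, hyperclique error-correcting
codes with exponential capacity, and the clustering, hidden-clique,
critical-ratio and spike-raster experiments built on top.

## Who this is for

Researchers in computational neuroscience and discrete machine learning who
want binary attractor networks that *learn*: unsupervised clustering and
denoising of binary data, maximum-entropy (Lenz–Ising) parameter estimation,
combinatorial pattern storage (cliques and hypercliques), and motif
discovery in binarised spike rasters.

## The model

A Hopfield network on `n` binary nodes is a symmetric zero-diagonal weight
matrix `W` and thresholds `θ`, with energy

```
E(x) = -½ xᵀWx + xᵀθ,        x ∈ {0,1}ⁿ,
```

and asynchronous threshold dynamics `x_i ← H(W_iᵀx - θ_i)` that never raise
the energy, so every state falls into a fixed point `x* = H(Wx* - θ)` — the
network's memories. Given data with empirical distribution `q`, MEF
minimises the **energy flow**

```
EF(W, θ) = Σ_x q_x Σ_{x' ∈ N₁(x)} e^{(E(x) - E(x'))/2},
```

the sum over all one-bit flips of the exponentiated half energy drop.
EF is convex in `(W, θ)`, costs `O(mn²)` per evaluation, and driving it
small forces the data to be attractors. It also bounds the distance from
`q` to its projection onto the model's Boltzmann distribution `p` by
`(2/σ₂)·EF`, where `σ₂` is the second smallest singular value of an
explicit flow matrix on states — a bound the package verifies numerically
by exact enumeration for small `n`. The gradient of the one-pattern
objective doubles as a local plasticity rule (LTP/LTD plus homeostatic
attenuation), available as `online_step`.

## Worked example: storing all 6-cliques of an 8-vertex graph

```python
import numpy as np
from hopflow import MinimumEnergyFlow
from hopflow.experiments import clique_patterns, storage_fraction

data = clique_patterns(8, 6)        # 28 patterns on C(8,2) = 28 edge-nodes
res = MinimumEnergyFlow(data).fit()
print(res.summary())
print("stored:", storage_fraction(res.network, data))
```

prints

```
Minimum Energy Flow fit
=============================================
nodes (n):            28
unique patterns:      28
parameters:           406
optimizer:            lbfgs
iterations:           19
converged:            True
final energy flow:    0.000130228
gradient inf-norm:    8.4e-07
patterns stored:      1.000
stored: 1.0
```

All 28 six-cliques become exact fixed points (`patterns stored: 1.000`) and
the converged energy flow is near zero, as the theory demands. Training on
a random *half* of the cliques already stores ~64% of all of them — the
generalisation behaviour the learning-curve experiment quantifies against
Hebbian, perceptron and delta baselines.

The same machinery drives the other experiments, e.g.

```python
from hopflow.hyperclique import robustness_sim
import numpy as np
print(robustness_sim(64, 1, [0.0, 0.05, 0.1], trials=20,
                     rng=np.random.default_rng(0)))
```

```
      p  recovery_fraction  trials
0  0.00               1.00      20
1  0.05               0.95      20
2  0.10               0.70      20
```

— codewords of typical hypergraphs are exact fixed points (`p = 0`), and
single-pass error correction degrades gracefully with the corruption rate.

A `hopflow` command-line tool exposes the same operations
(`hopflow train`, `hopflow theorem1-check`, `hopflow hcode simulate`,
`hopflow cluster-exp`, `hopflow raster-label`, ...); every subcommand takes
`--seed` and reruns reproduce outputs byte for byte.

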