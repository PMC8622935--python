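# Methods

## Model

A Hopfield network on `n` binary nodes is a symmetric coupling matrix `W`
(zero diagonal) and a threshold vector `θ`. States `x ∈ {0,1}^n` carry the
energy

    E(x) = -1/2 xᵀWx + xᵀθ,

and evolve by asynchronous linear-threshold updates: node `i` is set to 1
exactly when its feedforward input `F_i = W_iᵀx - θ_i` is strictly positive
(ties switch the node off — the Heaviside convention `H(0) = 0`, frozen
throughout). A sweep never raises the energy, so every initial state reaches
a fixed point `x* = H(Wx* - θ)` in finitely many sweeps; a safety cap of
10,000 sweeps exists but is unreachable for valid symmetric networks. The
same `(W, θ)` parameterize the Lenz–Ising (Boltzmann) distribution
`p_x ∝ e^{-E(x)}`, the maximum-entropy model matching first- and
second-order statistics.

The node order of an asynchronous sweep is an explicit argument everywhere
(ascending index by default), since different orders can reach different
fixed points from the same start; all shipped experiments use the default
order so results are reproducible bit for bit.

## Minimum energy flow

Learning minimises the energy flow of an empirical distribution `q` over
data patterns:

    EF(W, θ) = Σ_x q_x Σ_{x' ∈ N₁(x)} e^{(E(x) - E(x'))/2},

where `N₁(x)` is the Hamming-1 neighbourhood. Using the flip identity
`E(x) - E(x') = (1 - 2x_i) F_i` for the flip at node `i`, EF costs
`O(m n²)` per evaluation — no `2^n` enumeration — and is a positive sum of
exponentials of linear functions of `(W, θ)`, hence convex. Driving EF to
zero forces every data pattern to satisfy the fixed-point equation, so the
data become attractors whenever the architecture permits.

Implementation choices:

* **Parameterisation.** The optimizer works on the strict upper triangle of
  `W` plus `θ`; the full symmetric matrix is rebuilt for the dynamics, so
  symmetry and the zero diagonal are exact by construction.
* **Optimisers.** L-BFGS-B (scipy) with the analytic gradient is the
  default; a line-searched steepest-descent mode is available. The objective
  is convex, so the choice affects speed only — descent crawls on
  ill-conditioned instances but heads to the same optimum.
* **Initialisation.** `W = 0, θ = 0`, the canonical reproducible start.
* **Stopping.** Gradient infinity-norm below `1e-6` or the iteration cap;
  both are reported on the results object. EF need not have a finite
  minimiser (an all-ones data set lets `θ → -∞`); in that case the fit stops
  at the cap and carries a warning rather than silently regularising.
* **Exponent clipping** at ±500 guards wild line-search steps against
  overflow without touching any realistic term.
* **Empirical weights.** Duplicate patterns are merged into frequencies; a
  flag re-weights unique patterns uniformly instead.

The gradient of the singleton objective is the local plasticity rule: the
weight update is `-x_j Δx_i e^{Δx_i F_i/2}` (symmetrised), combining
long-term potentiation when both nodes are active and under-driven,
long-term depression for opposed activity, and a homeostatic attenuation
`e^{-F_i/2}` of potentiation as the drive grows. `online_step` applies
exactly the batch gradient of a one-pattern set, so the online and batch
paths cross-validate each other.

## Exact diagnostics and the projection bound

For `n ≤ 12` the package enumerates all `2^n` states (little-endian: bit `i`
of the state index is `x_i`) and builds the flow matrix

    M_yx = e^{(E_x - E_y)/2}  for y ∈ N₁(x),   M_xx = -Σ_{y≠x} M_yx,

whose columns sum to zero and which satisfies detailed balance with the
Boltzmann vector `p` (hence `Mp = 0`). Energies are shifted by their extreme
value before exponentiation to avoid overflow. With `σ₂` the second smallest
singular value of `M` (positive, because the one-flip graph on states is
connected), the distance between the data distribution `q` and its scalar
projection onto `p` obeys

    ‖q - (⟨q,p⟩/⟨p,p⟩) p‖₂ ≤ ‖Mq‖₂/σ₂ ≤ ‖Mq‖₁/σ₂ ≤ (2/σ₂)·EF.

The right-hand constant is `2/σ₂` — the form forced by the norm chain
(splitting `M` into its diagonal and off-diagonal parts gives
`‖Dq‖₁ = ‖Tq‖₁ = EF`); the tests verify every link separately so the bound
never rests on a single algebraic step. `EF` computed from the flow matrix's
off-diagonal column mass and `EF` computed from the data-side objective are
independent code paths and must agree to `1e-10` relative.

## Classical comparison rules

The comparison trainers are one-line principles made concrete, and the
learning-curve harness treats them as pluggable:

* **Outer-product (Hebb):** `W = Σ_x q_x s(x)s(x)ᵀ` on `s = 2x - 1`, zero
  diagonal, `θ = 0`.
* **Perceptron:** per-node batch perceptron with margin 0 on the linear
  problem `H(F_i) = x_i`, symmetrised after every epoch; non-convergence
  returns the best iterate with a warning.
* **Delta:** gradient descent on the logistic least-mean-square loss
  `Σ_x Σ_i (x_i - σ(F_i))²`, slope 1, symmetrised per epoch.

On the 28 six-cliques of `v = 8` at full training, the outer-product rule
also reaches complete storage; its deficit against energy-flow training
shows at partial training ratios (at ratio 0.5, mean storage 0.64 vs 0.13
over 20 trials), which is where the generalisation claim is asserted.

## Hyperclique codes

Nodes are the `C(v, d+1)` subsets of a `v`-vertex set, in colexicographic
order; two nodes are coupled when their subsets share exactly `d` vertices.
(The neighbour-count identity `w + w' = (d+1)(v-(d+1))` and the expected
complete-neighbour counts only hold under the share-`d` adjacency; for
`d = 1` it coincides with "pairs sharing one vertex".) A `d`-uniform
hypergraph `G` — each `d`-subset a hyperedge independently with probability
1/2, the model under which all expectations hold — is encoded as its
hyperclique indicator. All coupled pairs carry one weight `x ≥ 0` and every
node one threshold `z > 0`, so only the ratio `x/z` matters; minimising the
energy flow of the codeword ensemble over this two-parameter family yields

    x/z = 2^{d+1} / ((2d+1) v)   (up to a 1±o(1) factor),

which places the firing threshold `z/x = (2d+1)v/2^{d+1}` between the
expected complete-neighbour counts of complete nodes ((d+1)v/2^d) and
incomplete nodes (dv/2^d). The exact stationarity condition carries an
additive `ln(d(2^{d+1}-1)/(d+1))` offset to `z`; the parameter-recovery
experiment therefore fixes `z = 10`, large enough for the offset to be
negligible relative to `z` while leaving the dynamics untouched.

**The typical set S.** Membership requires, with slack
`ε(v) = min(0.22, 3·log v/√v)`:
complete nodes have at least `(1-ε)(d+1)v/2^d` complete neighbours,
incomplete nodes at most `(1+ε)dv/2^d`, and the number of complete nodes is
within `(1±ε)` of `2^{-(d+1)}C(v,d+1)`. The first two bounds are one-sided —
exactly what the fixed-point and recovery margins consume; a two-sided lower
bound on incomplete nodes would be violated by every random hypergraph
(a pair with both vertices absent legitimately has `w ≈ 0`). The ceiling
0.22 makes S-membership *certify* exact storage at `d = 1`: the complete-
node margin requires `ε < 1/(2(d+1)) = 1/4`, and the strict-inequality tie
rule consumes a little headroom. At `v = 64, d = 1` roughly half of all
random hypergraphs are accepted.

**Finite-size behaviour.** The robustness indices
`α = 1/(2^d(d+1) - 2d)` (free choice of `x, z`) and
`α = 1/(2^{d+1}(d+1) - 4d)` (the energy-flow-optimal ratio) are asymptotic:
decision margins grow linearly in `v` while corruption noise grows as `√v`.
At `v = 64, d = 1` (2016 nodes) codewords of S-hypergraphs are exact fixed
points and single-pass recovery is essentially perfect for `p ≲ 0.05`, but
at `p = 0.2` the incomplete-node margin is only about one standard deviation
of the corrupted input, so exact single-pass recovery requires `v` in the
thousands. Likewise `d = 2` at `v = 12` sits below the storage threshold
entirely (complete nodes average 6.75 complete neighbours against a firing
threshold of 7.5): reconstruction of graphs from triangles is a genuinely
asymptotic statement. The simulation utilities report full recovery curves
rather than asserting a fixed finite-`v` rate.

## Synthetic data

Three generators define the study conditions; none attempts to mimic
recording artefacts, electrode drift, refractoriness or non-stationarity of
real neural data, so passing tests demonstrate the machinery on clean
mixtures, random hypergraphs, and stationary planted motifs only.

* **Cluster mixtures.** `K` distinct uniform random centers in `{0,1}^n`;
  each sample is a uniformly chosen center with i.i.d. bit flips at rate
  `p`. The reference regime is `K = 64, n = 256, m = 32768, p = 0.1` (with
  a reduced `K = 16, n = 64, m = 4096` variant for quick runs). After
  training, converging every sample and counting distinct fixed points
  estimates the number of sources; the Shannon entropy of the attractor
  frequencies estimates the source entropy `log₂ K`. With scarce, noisy
  data the estimate overshoots — corrupted samples are stored as their own
  memories — and individual outlier samples can persist as rarely-visited
  singleton attractors even in the matched regime (each such singleton
  costs about `(1/m)·log₂ m` bits of entropy excess).
* **Clique tasks.** All `C(v,k)` `k`-cliques as edge indicators on
  `C(v,2)` pair-nodes. The learning-curve experiment trains on a random
  fraction and evaluates exact fixed-point storage on all cliques
  ("accuracy" is storage, not corruption-recovery — matching the use of all
  cliques as a test set). The critical-ratio search doubles then bisects
  the training count until a 50% storage criterion on 1000 uniformly drawn
  test cliques is met (training cliques drawn without replacement, test
  cliques with replacement), stopping when the bracket is within 25% — the
  ratio spans orders of magnitude across `v`, so coarse brackets suffice.
  The desk grid is `v ∈ {16, 24, 32}` at `v/k = 2` with 5 trials; larger
  grids (v up to 80, n = 3160) follow the same code path with more compute.
* **Planted-motif rasters.** Bernoulli background (rate 0.02) with two
  random binary motif blocks (density 0.3) tiled across the raster, each
  placement independently corrupted at 10% bit flips. The reference fixture
  is 50 neurons × 2000 bins with 50×20-bin windows at stride 1.

## Raster labeling and implicit regularisation

Windows are flattened row-major, converged under the trained dynamics, and
identical fixed points share a label (dense integers in first-appearance
order); the pipeline is deterministic given the network and node order. The
window training uses a deliberately small iteration budget (default 10
L-BFGS iterations). This is a real design point, not a shortcut: a single
raster yields fewer windows than the window dimension, so the fully
optimised convex fit has the capacity to make *every* window its own
attractor, which is exactly the memorisation failure mode. Stopping early
keeps the weights dominated by the strongly repeated motif correlations, so
repeated structure shares a basin while one-off background windows do not
carve their own minima. The benchmark score assigns each motif the modal
attractor of its planted occurrences, requires the motifs' attractors to be
distinct, and reports the fraction of occurrences carrying their motif's
label.

## Numerical conventions

* Ties in the threshold dynamics switch a node off (`H(0) = 0`).
* Exact-enumeration modules are capped at `n = 12` (4096-state dense
  matrices keep a dense SVD under a minute on one CPU).
* Dense code-network materialisation is capped at 20,000 nodes.
* All randomness flows through explicitly passed `numpy` generators; every
  experiment configuration carries its seed, and file outputs embed it.

## Problem sizes used by the shipped checks

The test suite runs the reduced clustering regime, the `v ∈ {16,24,32}`
critical-ratio grid, the `v = 64, d = 1` codec, and the 2000-bin raster
benchmark; `scripts/acceptance.py` reruns the full clustering regime
(`K = 64, n = 256, m = 32768`, 300-iteration budget). These sizes were
chosen so each check completes in minutes on a single CPU while remaining
inside the regime its claim describes.

## Known limitations

* Storage-capacity effects make several asymptotic claims invisible at desk
  scale (see "Finite-size behaviour" above); the affected checks report
  curves instead of thresholds.
* Stochastic (finite-temperature) dynamics, larger flip neighbourhoods,
  regularised objectives, Potts and higher-order models are out of scope.
* The raster benchmark's early-stopping budget is calibrated to the
  reference fixture's geometry (windows-to-dimension ratio near one); very
  different raster shapes may need a different budget.
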