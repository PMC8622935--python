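"""Minimum energy flow (MEF): a convex objective for learning Hopfield networks.

Given data with empirical distribution q over binary patterns, the energy flow

    EF(W, theta) = sum_{x in X} q_x sum_{x' in N1(x)} e^{(E_x - E_{x'})/2}

sums, over every pattern and every one-bit flip of it, the exponential of half
the energy drop toward the flipped state. Writing Dx_i = 1 - 2 x_i for the
sign of the flip at node i and F_i = W_i^T x - theta_i for the feedforward
input, each term is e^{Dx_i F_i / 2}, so EF costs O(m n^2) to evaluate — no
2^n enumeration. EF is a positive sum of exponentials of linear functions of
(W, theta), hence convex; driving it down forces the data patterns to become
fixed-point attractors whenever the architecture permits.

The model/results pair below follows the usual estimation idiom:
``MinimumEnergyFlow(data).fit()`` returns an :class:`MEFResults` holding the
trained network, the objective path and convergence diagnostics. The gradient
of a single-pattern objective is the local MEF plasticity rule
(:func:`online_step`), combining LTP/LTD with homeostatic attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .network import HopfieldNetwork, PatternSet, fixed_point_mask

__all__ = [
    "TrainingOptions",
    "MinimumEnergyFlow",
    "MEFResults",
    "energy_flow",
    "ef_gradient",
    "single_pattern_terms",
    "online_step",
    "train",
]

# exponent clip: e^500 is finite in float64; keeps wild line-search steps from
# overflowing while leaving every realistic term untouched
_EXP_CLIP = 500.0


def _as_data(data) -> PatternSet:
    return data if isinstance(data, PatternSet) else PatternSet(data)


def _ef_terms(W, theta, X, q):
    """Shared kernel: exponential terms and their q-weighted flip gains."""
    F = X @ W - theta
    D = 1.0 - 2.0 * X
    E = np.exp(np.clip(D * F / 2.0, -_EXP_CLIP, _EXP_CLIP))
    G = (q[:, None] * E * D) / 2.0  # dEF/dF, shape (m, n)
    return E, G


def energy_flow(net: HopfieldNetwork, data) -> float:
    """Evaluate EF(W, theta) on a pattern set via the feedforward identity."""
    data = _as_data(data)
    if data.n != net.n:
        raise ValueError("data dimension does not match network")
    E, _ = _ef_terms(net.weights, net.thresholds, data.patterns, data.weights)
    return float(data.weights @ E.sum(axis=1))


def ef_gradient(net: HopfieldNetwork, data, symmetrize: bool = True):
    """Analytic gradient of EF with respect to (W, theta).

    With ``symmetrize=True`` (default) the weight part is the gradient under
    the symmetric coupling W_ij = W_ji, i.e. the sum of both unsymmetrised
    contributions, with the diagonal zeroed: the derivative realised when
    W_ij and W_ji move together. ``symmetrize=False`` returns the raw
    independent-entry derivative (the unsymmetrised per-pattern rule).
    """
    data = _as_data(data)
    if data.n != net.n:
        raise ValueError("data dimension does not match network")
    X, q = data.patterns, data.weights
    _, G = _ef_terms(net.weights, net.thresholds, X, q)
    gradW = G.T @ X
    if symmetrize:
        gradW = gradW + gradW.T
    np.fill_diagonal(gradW, 0.0)
    gradT = -G.sum(axis=0)
    return gradW, gradT


def single_pattern_terms(net: HopfieldNetwork, x):
    """Unsymmetrised per-term MEF rule pieces for one pattern.

    Returns ``(dW, dtheta)`` with dW_ij = x_j Dx_i e^{Dx_i F_i / 2} and
    dtheta_i = -Dx_i e^{Dx_i F_i / 2} (the positive-gradient direction whose
    negative is the plasticity update), diagonal of dW zeroed.
    """
    data = PatternSet(np.atleast_2d(x))
    gradW, gradT = ef_gradient(net, data, symmetrize=False)
    return 2.0 * gradW, 2.0 * gradT  # undo the 1/2 and q=1 weighting of _ef_terms


def online_step(net: HopfieldNetwork, x, lr: float) -> HopfieldNetwork:
    """One local MEF plasticity step for a single pattern.

    Descends the singleton energy flow, symmetrising the weight change and
    keeping the diagonal zero. For active pre- and postsynaptic nodes with
    negative feedforward drive the weight strengthens (LTP); the attenuation
    e^{-F_i/2} of that strengthening with growing drive is the homeostatic
    part of the rule.
    """
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    gradW, gradT = ef_gradient(net, PatternSet(np.atleast_2d(x)), symmetrize=True)
    W = net.weights - lr * gradW
    np.fill_diagonal(W, 0.0)
    return HopfieldNetwork(W, net.thresholds - lr * gradT)


@dataclass
class TrainingOptions:
    """Knobs for batch or online EF minimisation."""

    max_iterations: int = 500
    tolerance: float = 1e-6  # gradient infinity-norm stopping criterion
    learning_rate: float = 0.1  # online mode only
    optimizer: str = "lbfgs"  # "lbfgs" (quasi-Newton) or "gd" (line-searched descent)
    seed: int | None = None

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.optimizer not in ("lbfgs", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class MinimumEnergyFlow:
    """Energy-flow model for a set of binary patterns.

    Parameters
    ----------
    data : PatternSet or array_like
        Binary patterns; duplicates are merged into empirical frequencies q.
    uniform_weights : bool
        Re-weight unique patterns uniformly instead of by frequency.
    """

    def __init__(self, data, uniform_weights: bool = False):
        data = _as_data(data)
        if uniform_weights:
            data = PatternSet.uniform_over_unique(data.patterns)
        self.data = data
        self.nobs = data.m
        self.n = data.n
        iu = np.triu_indices(self.n, k=1)
        self._iu = iu
        self.k_params = iu[0].size + self.n

    # -------------------------------------------------------- parameter packing
    def _unpack(self, params) -> HopfieldNetwork:
        n = self.n
        W = np.zeros((n, n))
        W[self._iu] = params[: self._iu[0].size]
        W = W + W.T
        return HopfieldNetwork(W, params[self._iu[0].size:])

    def _pack(self, net: HopfieldNetwork) -> np.ndarray:
        return np.concatenate([net.weights[self._iu], net.thresholds])

    def _objective(self, params):
        n = self.n
        nu = self._iu[0].size
        W = np.zeros((n, n))
        W[self._iu] = params[:nu]
        W = W + W.T
        theta = params[nu:]
        X, q = self.data.patterns, self.data.weights
        E, G = _ef_terms(W, theta, X, q)
        val = float(q @ E.sum(axis=1))
        gradW = G.T @ X
        gradW = gradW + gradW.T
        grad = np.concatenate([gradW[self._iu], -G.sum(axis=0)])
        return val, grad

    def energy_flow(self, net: HopfieldNetwork) -> float:
        return energy_flow(net, self.data)

    # ------------------------------------------------------------------- fitting
    def fit(self, options: TrainingOptions | None = None, **kwargs) -> "MEFResults":
        """Minimise EF from the canonical zero start (W=0, theta=0).

        The objective is convex, so the optimizer choice ("lbfgs" or "gd")
        affects speed, not the optimum reached (up to tolerance).
        """
        opts = options or TrainingOptions(**kwargs)
        x0 = np.zeros(self.k_params)
        path = [self._objective(x0)[0]]
        warn = None
        if opts.optimizer == "lbfgs":
            last = {"f": path[0]}

            def fun(p):
                f, g = self._objective(p)
                last["f"] = f
                return f, g

            res = optimize.minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                callback=lambda p: path.append(last["f"]),
                options={
                    "maxiter": opts.max_iterations,
                    "gtol": opts.tolerance,
                    "ftol": 1e-14,
                    "maxcor": 8,
                },
            )
            params, n_iter = res.x, res.nit
            f_final, g_final = self._objective(params)
            converged = float(np.max(np.abs(g_final))) <= opts.tolerance or res.success
            if not res.success and not converged:
                warn = str(res.message)
        else:
            params, path_gd, n_iter, converged, warn = self._fit_gd(x0, opts)
            path.extend(path_gd)
            f_final, g_final = self._objective(params)
        path.append(f_final)
        return MEFResults(
            model=self,
            network=self._unpack(params),
            objective_path=np.asarray(path),
            n_iter=int(n_iter),
            converged=bool(converged),
            grad_norm=float(np.max(np.abs(g_final))),
            options=opts,
            warning=warn,
        )

    def _fit_gd(self, x0, opts: TrainingOptions):
        """First-order descent with backtracking line search (Armijo)."""
        p = x0
        f, g = self._objective(p)
        step = 1.0
        path = []
        for it in range(opts.max_iterations):
            gnorm = np.max(np.abs(g))
            if gnorm <= opts.tolerance:
                return p, path, it, True, None
            d = -g
            gd = g @ d
            while step > 1e-18:
                f_new, g_new = self._objective(p + step * d)
                if f_new <= f + 1e-4 * step * gd:
                    break
                step *= 0.5
            else:  # pragma: no cover - pathological
                return p, path, it, False, "line search failed"
            p = p + step * d
            f, g = f_new, g_new
            path.append(f)
            step = min(step * 2.0, 1e6)
        converged = np.max(np.abs(g)) <= opts.tolerance
        warn = None if converged else "iteration cap reached; returning best iterate"
        return p, path, opts.max_iterations, converged, warn


class MEFResults:
    """Fit results: the trained network plus optimisation diagnostics."""

    def __init__(self, model, network, objective_path, n_iter, converged,
                 grad_norm, options, warning=None):
        self.model = model
        self.network = network
        self.objective_path = objective_path
        self.n_iter = n_iter
        self.converged = converged
        self.grad_norm = grad_norm
        self.options = options
        self.warning = warning

    @property
    def final_energy_flow(self) -> float:
        return float(self.objective_path[-1])

    def storage_fraction(self) -> float:
        """Fraction of (unique) training patterns that are exact fixed points."""
        return float(fixed_point_mask(self.network, self.model.data.patterns).mean())

    def summary(self) -> str:
        lines = [
            "Minimum Energy Flow fit",
            "=" * 45,
            f"nodes (n):            {self.model.n}",
            f"unique patterns:      {self.model.nobs}",
            f"parameters:           {self.model.k_params}",
            f"optimizer:            {self.options.optimizer}",
            f"iterations:           {self.n_iter}",
            f"converged:            {self.converged}",
            f"final energy flow:    {self.final_energy_flow:.6g}",
            f"gradient inf-norm:    {self.grad_norm:.3g}",
            f"patterns stored:      {self.storage_fraction():.3f}",
        ]
        if self.warning:
            lines.append(f"warning:              {self.warning}")
        return "\n".join(lines)


def train(data, options: TrainingOptions | None = None, **kwargs) -> HopfieldNetwork:
    """Convenience wrapper: fit MEF on ``data`` and return the trained network."""
    return MinimumEnergyFlow(data).fit(options, **kwargs).network
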