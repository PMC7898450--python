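"""Joint multi-context fitting of logic-network edge weights.

The loss is the pooled mean squared error between simulated and measured
output activities plus two optional regularization terms:

* a *pruning* (group partial-norm) penalty discouraging concurrent
  activation of a node by more than one activator — for every node with at
  least two activating in-edges, ``sum(w) - max(w)`` per context;
* a *uniformity* penalty discouraging unsupported differences between
  contexts (cell lines) — for every parameter label,
  ``sum_c |w_c - median_c(w)|``.

Optimization is multi-start projected gradient descent with a
Barzilai–Borwein step and monotone (Armijo) backtracking.  Gradients are
computed analytically by reverse-mode accumulation through the DAG
propagation.  Activator weights are kept on their per-node simplex and
inhibitor weights in [0, 1] by Euclidean projection; cross-context
parameter ties (the "single model", or merged groups of a reduced model)
are handled by collapsing tied coordinates into one free variable, with
Dykstra's alternating projections when tied simplexes overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LogicNetwork, MeasurementSet
from .simulate import CompiledNetwork, ParameterSet

__all__ = [
    "FitConfig",
    "FitResult",
    "mse",
    "pruning_penalty",
    "uniformity_penalty",
    "fit",
    "tie_all_contexts",
]


# smoothing radius for the optimizer's internal |.| in the uniformity term
HUBER_MU = 1e-4


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings for :func:`fit`.

    ``tol`` is the relative total-loss change below which a run is declared
    converged; ``n_starts`` seeded random restarts mitigate non-convexity.
    """

    lambda_pruning: float = 0.0
    lambda_uniformity: float = 0.0
    n_starts: int = 20
    seed: int = 0
    tol: float = 1e-9
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.lambda_pruning < 0 or self.lambda_uniformity < 0:
            raise ValueError("regularization strengths must be nonnegative")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass
class FitResult:
    """Outcome of a multi-start fit."""

    params: ParameterSet
    mse: float
    penalty_pruning: float
    penalty_uniformity: float
    total_loss: float
    n_distinct_params: int
    converged: bool
    best_start: int
    loss_trace: list[float] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------


def mse(simulated, measured) -> float:
    """Pooled mean squared error over all non-missing measured cells.

    Accepts a single (simulated, measured) matrix pair or two equal-length
    lists of pairs (one per context), pooled into one mean.
    """
    if isinstance(simulated, (list, tuple)):
        if len(simulated) != len(measured):
            raise ValueError("need as many simulated as measured matrices")
        pairs = list(zip(simulated, measured))
    else:
        pairs = [(simulated, measured)]
    sq_sum = 0.0
    n = 0
    for sim, meas in pairs:
        sim = np.asarray(sim, dtype=float)
        meas = np.asarray(meas, dtype=float)
        if sim.shape != meas.shape:
            raise ValueError(f"shape mismatch: {sim.shape} vs {meas.shape}")
        mask = np.isfinite(meas)
        sq_sum += float(((sim - meas)[mask] ** 2).sum())
        n += int(mask.sum())
    if n == 0:
        raise ValueError("no non-missing measurements")
    return sq_sum / n


def pruning_penalty(network: LogicNetwork, params: ParameterSet) -> float:
    """Group partial-norm: sum over (node, context) with >= 2 activators of
    ``sum(w) - max(w)``.  Zero iff every node's activation mass sits on a
    single activator in every context."""
    total = 0.0
    for ctx in params.contexts:
        for node in network.node_names:
            labs = [e.param_label for e in network.activators_of(node)]
            if len(labs) < 2:
                continue
            w = np.array([params.values[(l, ctx)] for l in labs])
            total += float(w.sum() - w.max())
    return total


def uniformity_penalty(params: ParameterSet, contexts: list[str] | None = None) -> float:
    """Sum over labels of the absolute deviations from the cross-context
    median.  Zero iff every parameter is identical across contexts."""
    contexts = list(contexts or params.contexts)
    if len(contexts) < 2:
        warnings.warn("uniformity penalty needs >= 2 contexts; returning 0", stacklevel=2)
        return 0.0
    total = 0.0
    for lab in params.labels:
        w = np.array([params.values[(lab, c)] for c in contexts])
        total += float(np.abs(w - np.median(w)).sum())
    return total


# ---------------------------------------------------------------------------
# Free-variable parameterization with ties and projection
# ---------------------------------------------------------------------------


def tie_all_contexts(network: LogicNetwork, contexts: list[str]) -> list[frozenset]:
    """Sharing structure that hard-ties every label across all contexts
    (the "single model")."""
    return [frozenset((lab, c) for c in contexts) for lab in network.param_labels]


class _Parameterization:
    """Maps (label, context) pairs onto a free vector theta, honouring ties,
    and projects theta onto the per-node simplex and inhibitor-box set."""

    def __init__(self, compiled: CompiledNetwork, contexts: list[str], sharing):
        self.compiled = compiled
        self.contexts = list(contexts)
        labels = compiled.labels
        pairs = [(l, c) for l in labels for c in contexts]
        parent = {p: p for p in pairs}

        def find(p):
            while parent[p] != p:
                parent[p] = parent[parent[p]]
                p = parent[p]
            return p

        for group in sharing or []:
            group = list(group)
            for p in group:
                if p not in parent:
                    raise ValueError(f"sharing group mentions unknown pair {p}")
            root = find(group[0])
            for p in group[1:]:
                parent[find(p)] = root
        roots: list = []
        root_index: dict = {}
        for p in pairs:
            r = find(p)
            if r not in root_index:
                root_index[r] = len(roots)
                roots.append(r)
        self.n_theta = len(roots)
        # (n_labels, n_contexts) -> theta coordinate
        self.index = np.empty((len(labels), len(contexts)), dtype=int)
        for i, l in enumerate(labels):
            for j, c in enumerate(contexts):
                self.index[i, j] = root_index[find((l, c))]

        # constraint blocks: deduplicated per-(node, context) simplexes
        lab_idx = {l: i for i, l in enumerate(labels)}
        simplex_sets: list[tuple[int, ...]] = []
        seen: set[tuple[int, ...]] = set()
        for node, labs in compiled.activator_labels_by_node.items():
            for j, _c in enumerate(contexts):
                coords = tuple(sorted(self.index[lab_idx[l], j] for l in labs))
                if len(set(coords)) != len(coords):
                    raise ValueError(
                        f"activator weights into {node!r} tied to each other: "
                        "simplex constraint would be degenerate"
                    )
                if coords not in seen:
                    seen.add(coords)
                    simplex_sets.append(coords)
        self.simplexes = [np.array(s, dtype=int) for s in simplex_sets]
        inh = set()
        for l in compiled.inhibitor_labels:
            for j in range(len(contexts)):
                inh.add(self.index[lab_idx[l], j])
        self.box_idx = np.array(sorted(inh), dtype=int)
        counts = np.zeros(self.n_theta, dtype=int)
        for s in self.simplexes:
            counts[s] += 1
        self.overlapping = bool((counts > 1).any())

    # -- projection -------------------------------------------------------

    def project(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float).copy()
        if not self.overlapping:
            for s in self.simplexes:
                theta[s] = _project_simplex(theta[s])
            if self.box_idx.size:
                theta[self.box_idx] = np.clip(theta[self.box_idx], 0.0, 1.0)
            return theta
        return self._dykstra(theta)

    def _dykstra(self, theta: np.ndarray, max_cycles: int = 500, tol: float = 1e-12) -> np.ndarray:
        blocks = [("s", s) for s in self.simplexes]
        if self.box_idx.size:
            blocks.append(("b", self.box_idx))
        corrections = [np.zeros(len(idx)) for _, idx in blocks]
        x = theta.copy()
        for _ in range(max_cycles):
            max_shift = 0.0
            for k, (kind, idx) in enumerate(blocks):
                y = x[idx] + corrections[k]
                if kind == "s":
                    proj = _project_simplex(y)
                else:
                    proj = np.clip(y, 0.0, 1.0)
                corrections[k] = y - proj
                max_shift = max(max_shift, float(np.abs(x[idx] - proj).max(initial=0.0)))
                x[idx] = proj
            if max_shift < tol:
                break
        return x

    # -- weights & gradient plumbing --------------------------------------

    def weights(self, theta: np.ndarray) -> np.ndarray:
        """(n_labels, n_contexts) weight matrix."""
        return theta[self.index]

    def accumulate(self, dW: np.ndarray) -> np.ndarray:
        """Map a (n_labels, n_contexts) weight gradient onto theta."""
        g = np.zeros(self.n_theta)
        np.add.at(g, self.index.ravel(), dW.ravel())
        return g

    def to_parameter_set(self, theta: np.ndarray, sharing) -> ParameterSet:
        W = self.weights(theta)
        values = {
            (l, c): float(W[i, j])
            for i, l in enumerate(self.compiled.labels)
            for j, c in enumerate(self.contexts)
        }
        return ParameterSet(values=values, sharing=list(sharing or []))


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w >= 0, sum w = 1} (sort-based)."""
    if v.size == 1:
        return np.ones(1)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, v.size + 1) > 0)[0][-1]
    tau = css[rho] / (rho + 1.0)
    return np.maximum(v - tau, 0.0)


# ---------------------------------------------------------------------------
# Loss + gradient
# ---------------------------------------------------------------------------


class _Objective:
    def __init__(
        self,
        compiled: CompiledNetwork,
        datasets: list[MeasurementSet],
        parameterization: _Parameterization,
        lambda_pruning: float,
        lambda_uniformity: float,
    ):
        self.c = compiled
        self.p = parameterization
        self.lp = lambda_pruning
        self.lu = lambda_uniformity
        self.inputs = [compiled.input_matrix(ds.conditions) for ds in datasets]
        # measured matrices as (n_outputs, n_conditions) with NaN mask
        self.measured = []
        self.masks = []
        n_total = 0
        for ds in datasets:
            m = ds.values.to_numpy(dtype=float).T
            mask = np.isfinite(m)
            self.measured.append(np.where(mask, m, 0.0))
            self.masks.append(mask)
            n_total += int(mask.sum())
        self.n_total = n_total
        lab_idx = {l: i for i, l in enumerate(compiled.labels)}
        self.prune_groups = [
            np.array([lab_idx[l] for l in labs], dtype=int)
            for labs in compiled.activator_labels_by_node.values()
            if len(labs) >= 2
        ]
        self.n_contexts = len(parameterization.contexts)

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        W = self.p.weights(theta)  # (labels, contexts)
        dW = np.zeros_like(W)
        sq_sum = 0.0
        for j in range(self.n_contexts):
            w = W[:, j]
            act = self.c.forward(w, self.inputs[j])
            sim = act[self.c.output_idx]
            resid = (sim - self.measured[j]) * self.masks[j]
            sq_sum += float((resid**2).sum())
            dsim = 2.0 * resid / self.n_total
            dW[:, j] += self._backward(w, act, self.inputs[j], dsim)
        loss = sq_sum / self.n_total

        if self.lp > 0:
            for j in range(self.n_contexts):
                for grp in self.prune_groups:
                    w = W[grp, j]
                    loss += self.lp * float(w.sum() - w.max())
                    sub = np.full(grp.size, self.lp)
                    sub[int(np.argmax(w))] = 0.0
                    dW[grp, j] += sub
        if self.lu > 0 and self.n_contexts >= 2:
            # Huber-smoothed |dev| so descent is not blocked at dev = 0:
            # a pure sign subgradient stalls MSE descent along the uniform
            # manifold.  The smoothing radius only affects the optimizer;
            # reported penalties use the exact absolute deviations.
            # radius proportional to lambda keeps the smoothed term's
            # curvature (lambda/mu) bounded, so steps stay well-scaled at
            # any regularization strength; residual deviations settle at
            # O(HUBER_MU * |grad MSE|), far below any merge tolerance
            mu = HUBER_MU * self.lu
            med = np.median(W, axis=1, keepdims=True)
            dev = W - med
            a = np.abs(dev)
            hub = np.where(a <= mu, dev**2 / (2 * mu), a - mu / 2)
            loss += self.lu * float(hub.sum())
            dW += self.lu * np.where(a <= mu, dev / mu, np.sign(dev))
        # averaged gradient: the same shift for every context of a label.
        # The uniformity term is invariant along such shifts, so descent in
        # this subspace is never blocked by the penalty; interleaving it
        # with full steps avoids the crawl along the uniform manifold.
        dW_avg = np.repeat(dW.mean(axis=1, keepdims=True), dW.shape[1], axis=1)
        return loss, self.p.accumulate(dW), self.p.accumulate(dW_avg)

    def mse_only(self, theta: np.ndarray) -> float:
        W = self.p.weights(theta)
        sq_sum = 0.0
        for j in range(self.n_contexts):
            act = self.c.forward(W[:, j], self.inputs[j])
            resid = (act[self.c.output_idx] - self.measured[j]) * self.masks[j]
            sq_sum += float((resid**2).sum())
        return sq_sum / self.n_total

    def _backward(
        self, w: np.ndarray, act: np.ndarray, inputs: np.ndarray, dsim: np.ndarray
    ) -> np.ndarray:
        """Reverse-mode gradient of a scalar loss wrt the weight vector,
        given d(loss)/d(sim) for the output rows."""
        n_cond = act.shape[1]
        dact = np.zeros_like(act)
        np.add.at(dact, self.c.output_idx, dsim)
        dw = np.zeros_like(w)
        for node, a_src, a_lab, i_src, i_lab in reversed(self.c.schedule):
            g = dact[node]
            if a_src.size == 0 or not g.any():
                continue
            S = w[a_lab] @ act[a_src]
            if i_src.size:
                terms = 1.0 - w[i_lab, None] * act[i_src]  # (k_i, n_cond)
                I = np.prod(terms, axis=0)
            else:
                I = np.ones(n_cond)
            gI = g * I
            np.add.at(dw, a_lab, (act[a_src] * gI).sum(axis=1))
            np.add.at(dact, a_src, w[a_lab, None] * gI)
            if i_src.size:
                for k in range(i_src.size):
                    others = np.prod(np.delete(terms, k, axis=0), axis=0) if i_src.size > 1 else np.ones(n_cond)
                    dterm = g * S * others
                    dw[i_lab[k]] += float((dterm * (-act[i_src[k]])).sum())
                    dact[i_src[k]] += dterm * (-w[i_lab[k]])
        return dw


# ---------------------------------------------------------------------------
# Projected gradient descent (Barzilai–Borwein + monotone backtracking)
# ---------------------------------------------------------------------------


def _pgd(objective, project, theta0, tol, max_iter, use_avg):
    """Projected gradient descent with Barzilai–Borwein steps and monotone
    Armijo backtracking.  When ``use_avg`` is set, full-gradient steps
    alternate with steps along the common-shift subspace (same move for
    every context of a label), where the uniformity penalty is invariant."""
    theta = project(theta0)
    f, grads = _eval(objective, theta)
    trace = [f]
    steps = [1.0, 1.0]
    directions = (0, 1) if use_avg else (0,)
    converged = False
    for _ in range(max_iter):
        f_cycle_start = f
        moved = False
        for d in directions:
            g = grads[d]
            step = steps[d]
            cand = project(theta - step * g)
            delta = cand - theta
            if not np.any(delta):
                continue
            f_new, grads_new = _eval(objective, cand)
            n_back = 0
            stalled = False
            while f_new > f - 1e-4 / max(step, 1e-12) * float(delta @ delta) and n_back < 40:
                step *= 0.5
                cand = project(theta - step * g)
                delta = cand - theta
                if not np.any(delta):
                    stalled = True
                    break
                f_new, grads_new = _eval(objective, cand)
                n_back += 1
            if stalled or f_new >= f:
                steps[d] = max(step, 1e-8)
                continue
            y = grads_new[d] - g
            sy = float(delta @ y)
            if sy > 1e-18:
                step = float(delta @ delta) / sy
            else:
                step *= 2.0
            steps[d] = float(np.clip(step, 1e-8, 1e4))
            theta, f, grads = cand, f_new, grads_new
            moved = True
        trace.append(f)
        rel_change = abs(f_cycle_start - f) / max(1.0, abs(f))
        if not moved or rel_change < tol:
            converged = True
            break
    return theta, f, trace, converged


def _eval(objective, theta):
    out = objective(theta)
    return out[0], out[1:]


# ---------------------------------------------------------------------------
# Public fit
# ---------------------------------------------------------------------------


def fit(
    network: LogicNetwork,
    datasets: list[MeasurementSet],
    config: FitConfig,
    sharing: list[frozenset] | None = None,
) -> FitResult:
    """Fit a ParameterSet jointly to one MeasurementSet per context.

    Returns the best of ``config.n_starts`` seeded projected-gradient runs
    on ``MSE + lambda_p * pruning + lambda_u * uniformity``.  Deterministic
    for a given (config, data, sharing).  ``sharing`` hard-ties groups of
    (label, context) pairs (see :func:`tie_all_contexts`).
    """
    contexts = [ds.context for ds in datasets]
    if len(set(contexts)) != len(contexts):
        raise ValueError("duplicate contexts in datasets")
    for ds in datasets:
        unknown = [c for c in ds.output_nodes if c not in network.output_nodes]
        if unknown:
            raise ValueError(f"context {ds.context!r} measures non-output nodes: {unknown}")
    compiled = CompiledNetwork(network)
    par = _Parameterization(compiled, contexts, sharing)
    objective = _Objective(
        compiled, datasets, par, config.lambda_pruning, config.lambda_uniformity
    )

    rng = np.random.default_rng(config.seed)
    best = None
    for start in range(config.n_starts):
        theta0 = rng.random(par.n_theta)
        theta, f, trace, conv = _pgd(
            objective,
            par.project,
            theta0,
            config.tol,
            config.max_iter,
            use_avg=config.lambda_uniformity > 0 and len(contexts) >= 2,
        )
        if best is None or f < best[1]:
            best = (theta, f, trace, conv, start)
    theta, total_loss, trace, converged, best_start = best

    params = par.to_parameter_set(theta, sharing)
    fit_mse = objective.mse_only(theta)
    pen_p = pruning_penalty(network, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pen_u = uniformity_penalty(params, contexts)
    return FitResult(
        params=params,
        mse=fit_mse,
        penalty_pruning=pen_p,
        penalty_uniformity=pen_u,
        total_loss=fit_mse
        + config.lambda_pruning * pen_p
        + config.lambda_uniformity * pen_u,
        n_distinct_params=_distinct_count(params, contexts, tol=1e-9),
        converged=converged,
        best_start=best_start,
        loss_trace=trace,
    )


def _distinct_count(params: ParameterSet, contexts: list[str], tol: float) -> int:
    """Labels uniform across contexts (SD <= tol) count once, others once
    per context."""
    C = len(contexts)
    k = 0
    for lab in params.labels:
        w = np.array([params.values[(lab, c)] for c in contexts])
        k += 1 if w.std() <= tol else C
    return k
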