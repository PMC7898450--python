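"""Model selection: BIC over a regularization grid, then topology reduction.

The optimal amount of regularization is chosen by scanning a grid of
(lambda_pruning, lambda_uniformity) values in log2 space, scoring every
fitted model with the Bayesian Information Criterion

    BIC = N * ln(MSE) + k * ln(N)

where ``N`` is the number of measured cells pooled over contexts and ``k``
the number of distinct parameters (a label uniform across contexts counts
once; a context-specific label counts once per context).  The best cell's
model is then *reduced*: edges carrying negligible flux (weight times mean
source activity) are removed, near-uniform parameters are hard-tied across
contexts, and the reduced model is refit without regularization to obtain
unbiased final estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitResult, fit
from .network import EdgeSpec, LogicNetwork, MeasurementSet, StructuralError
from .simulate import CompiledNetwork, ParameterSet

__all__ = [
    "GridSpec",
    "LambdaGridResult",
    "ReducedModel",
    "bic",
    "count_distinct_parameters",
    "scan_lambda_grid",
    "edge_flux",
    "reduce_and_refit",
]

# default grid covers 2^-14 .. 2^0 in steps of 2 on both axes
DEFAULT_LOG2_GRID = tuple(range(-14, 1, 2))


@dataclass(frozen=True)
class GridSpec:
    """log2 lambda values for the two regularization axes.

    ``-inf`` entries mean an exactly unregularized axis (lambda = 0).
    """

    log2_pruning: tuple = DEFAULT_LOG2_GRID
    log2_uniformity: tuple = DEFAULT_LOG2_GRID


@dataclass
class LambdaGridResult:
    """One fit + BIC per (log2 lambda_p, log2 lambda_u) cell."""

    grid: dict[tuple[float, float], tuple[FitResult, float]]
    best: tuple[float, float]
    n_measurements: int
    merge_tol: float

    @property
    def best_fit(self) -> FitResult:
        return self.grid[self.best][0]

    @property
    def best_bic(self) -> float:
        return self.grid[self.best][1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the BIC landscape."""
        rows = [
            {
                "log2_lambda_pruning": lp,
                "log2_lambda_uniformity": lu,
                "mse": res.mse,
                "k_distinct": count_distinct_parameters(res.params, self.merge_tol),
                "bic": b,
                "converged": res.converged,
            }
            for (lp, lu), (res, b) in sorted(self.grid.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class ReducedModel:
    """Final topology after flux pruning and cross-context merging."""

    network: LogicNetwork
    params: ParameterSet
    removed_edges: list[EdgeSpec] = field(default_factory=list)
    merged_groups: list[frozenset] = field(default_factory=list)


def bic(mse: float, n_measurements: int, k_distinct: int) -> float:
    """Gaussian-error BIC up to constants: N*ln(MSE) + k*ln(N)."""
    if n_measurements < 0 or k_distinct < 0:
        raise ValueError("n_measurements and k_distinct must be nonnegative")
    if mse < 0:
        raise ValueError("mse must be nonnegative")
    if mse == 0:
        warnings.warn("MSE is exactly 0; BIC is -inf", stacklevel=2)
        return float("-inf")
    return n_measurements * math.log(mse) + k_distinct * math.log(max(n_measurements, 1))


def count_distinct_parameters(params: ParameterSet, merge_tol: float) -> int:
    """Distinct-parameter count k for the BIC.

    A label whose cross-context standard deviation is <= ``merge_tol``
    counts once (uniform); otherwise it counts once per context.
    """
    if merge_tol < 0:
        raise ValueError("merge_tol must be >= 0")
    contexts = params.contexts
    C = len(contexts)
    k = 0
    for lab in params.labels:
        w = np.array([params.values[(lab, c)] for c in contexts])
        k += 1 if w.std() <= merge_tol else C
    return k


def context_specific_labels(params: ParameterSet, merge_tol: float) -> list[str]:
    """Labels whose cross-context SD exceeds ``merge_tol``."""
    contexts = params.contexts
    out = []
    for lab in params.labels:
        w = np.array([params.values[(lab, c)] for c in contexts])
        if w.std() > merge_tol:
            out.append(lab)
    return out


def scan_lambda_grid(
    network: LogicNetwork,
    datasets: list[MeasurementSet],
    grid_spec: GridSpec,
    config: FitConfig,
    merge_tol: float = 0.01,
) -> LambdaGridResult:
    """Fit every cell of the lambda grid and select the BIC-minimal one.

    Non-convergent cells are flagged and excluded from the arg-min (with a
    warning).  Ties are broken toward larger lambda values (the sparser
    model).
    """
    n_meas = sum(ds.n_measurements for ds in datasets)
    grid: dict[tuple[float, float], tuple[FitResult, float]] = {}
    for lp in grid_spec.log2_pruning:
        for lu in grid_spec.log2_uniformity:
            cell_config = FitConfig(
                lambda_pruning=0.0 if lp == float("-inf") else 2.0**lp,
                lambda_uniformity=0.0 if lu == float("-inf") else 2.0**lu,
                n_starts=config.n_starts,
                seed=config.seed,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            res = fit(network, datasets, cell_config)
            k = count_distinct_parameters(res.params, merge_tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = bic(res.mse, n_meas, k)
            grid[(float(lp), float(lu))] = (res, b)

    usable = {cell: rb for cell, rb in grid.items() if rb[0].converged}
    if not usable:
        warnings.warn("no grid cell converged; selecting among all cells", stacklevel=2)
        usable = grid
    elif len(usable) < len(grid):
        skipped = sorted(set(grid) - set(usable))
        warnings.warn(f"excluding non-convergent grid cells: {skipped}", stacklevel=2)
    # arg-min BIC; ties toward larger lambdas (sparser model)
    best = min(usable, key=lambda cell: (usable[cell][1], -cell[0] - cell[1]))
    return LambdaGridResult(grid=grid, best=best, n_measurements=n_meas, merge_tol=merge_tol)


def edge_flux(
    network: LogicNetwork,
    params: ParameterSet,
    datasets: list[MeasurementSet],
) -> dict[EdgeSpec, float]:
    """Mean signal carried by each edge: weight times mean source activity,
    averaged over every condition of every context."""
    compiled = CompiledNetwork(network)
    flux_sum = {e: 0.0 for e in network.edges}
    n_cond_total = 0
    for ds in datasets:
        w = compiled.weights_vector(params, ds.context)
        act = compiled.forward(w, compiled.input_matrix(ds.conditions))
        n_cond = act.shape[1]
        n_cond_total += n_cond
        for e in network.edges:
            src_act = act[compiled.node_index[e.source]]
            flux_sum[e] += float(w[compiled.label_index[e.param_label]] * src_act.sum())
    return {e: s / n_cond_total for e, s in flux_sum.items()}


def reduce_and_refit(
    network: LogicNetwork,
    datasets: list[MeasurementSet],
    best_fit: FitResult,
    config: FitConfig,
    flux_tol: float = 0.01,
    sd_tol: float = 0.01,
) -> tuple[ReducedModel, FitResult]:
    """Fix the final topology and refit it without regularization.

    Edges whose flux under ``best_fit`` is below ``flux_tol`` are removed;
    labels whose cross-context standard deviation is below ``sd_tol`` are
    hard-tied across contexts; the reduced model is refit with
    lambda = (0, 0) to obtain unbiased final estimates.
    """
    contexts = [ds.context for ds in datasets]
    flux = edge_flux(network, best_fit.params, datasets)
    removed = [e for e, f in flux.items() if f < flux_tol]
    kept = [e for e in network.edges if e not in removed]
    try:
        pruned = LogicNetwork(network.nodes, kept)
    except StructuralError as err:
        raise StructuralError(f"flux reduction disconnected the network: {err}") from err

    kept_labels = {e.param_label for e in kept}
    merged = []
    for lab in best_fit.params.labels:
        if lab not in kept_labels:
            continue
        w = np.array([best_fit.params.values[(lab, c)] for c in contexts])
        if w.std() < sd_tol:
            merged.append(frozenset((lab, c) for c in contexts))

    refit_config = FitConfig(
        lambda_pruning=0.0,
        lambda_uniformity=0.0,
        n_starts=config.n_starts,
        seed=config.seed,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    refit = fit(pruned, datasets, refit_config, sharing=merged)
    reduced = ReducedModel(
        network=pruned, params=refit.params, removed_edges=removed, merged_groups=merged
    )
    return reduced, refit
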