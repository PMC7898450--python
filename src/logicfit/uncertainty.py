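"""Resampling-based parameter uncertainty.

Parameter errors are estimated by repeatedly refitting the final model on
noise-perturbed copies of the measurements: each measured activity is
displaced by Gaussian noise with standard deviation proportional to its
SEM (or to a global noise scale when no SEMs are available), clipped back
to [0, 1], and the final topology is refit.  The per-parameter mean and
standard deviation over the rounds quantify how strongly each weight is
pinned down by the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit
from .network import LogicNetwork, MeasurementSet
from .selection import ReducedModel

__all__ = ["ResampleSummary", "perturb_measurements", "resample_parameters"]


@dataclass
class ResampleSummary:
    """Per-parameter mean and SD over noise-resampled refits."""

    n_resamples: int
    per_param: dict[tuple[str, str], tuple[float, float]]
    seeds: list[int]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples != len(self.seeds):
            raise ValueError("n_resamples must equal the number of seeds")
        for key, (_, sd) in self.per_param.items():
            if sd < 0:
                raise ValueError(f"negative SD for {key}")

    def to_frame(self) -> pd.DataFrame:
        """Label x context table of 'mean (± sd)' pairs, one row per label."""
        labels, contexts = [], []
        for lab, ctx in self.per_param:
            if lab not in labels:
                labels.append(lab)
            if ctx not in contexts:
                contexts.append(ctx)
        data = {}
        for ctx in contexts:
            data[f"{ctx}_mean"] = [self.per_param[(l, ctx)][0] for l in labels]
            data[f"{ctx}_sd"] = [self.per_param[(l, ctx)][1] for l in labels]
        return pd.DataFrame(data, index=pd.Index(labels, name="param_label"))


def perturb_measurements(
    dataset: MeasurementSet, noise_scale: float, seed: int
) -> MeasurementSet:
    """Gaussian-perturbed copy of a dataset, clipped to [0, 1].

    Noise SD per cell is ``noise_scale * sem`` when the dataset carries
    SEMs, else ``noise_scale`` globally.  Reproducible for a given seed.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    values = dataset.values.to_numpy(dtype=float)
    if dataset.sem is not None:
        sd = noise_scale * dataset.sem.to_numpy(dtype=float)
    else:
        sd = np.full_like(values, noise_scale)
    # draw for every cell so the stream is shape-stable, then mask missing
    eps = rng.standard_normal(values.shape) * sd
    perturbed = np.clip(values + eps, 0.0, 1.0)
    perturbed = np.where(np.isfinite(values), perturbed, values)
    new_values = pd.DataFrame(perturbed, index=dataset.values.index.copy(), columns=dataset.values.columns)
    return MeasurementSet(
        context=dataset.context,
        conditions=list(dataset.conditions),
        values=new_values,
        sem=None if dataset.sem is None else dataset.sem.copy(),
    )


def resample_parameters(
    network: LogicNetwork,
    datasets: list[MeasurementSet],
    final_topology: ReducedModel,
    n: int = 20,
    noise_scale: float = 1.0,
    base_seed: int = 0,
    config: FitConfig | None = None,
) -> ResampleSummary:
    """Refit the final topology on ``n`` noise-perturbed dataset copies.

    ``network`` is the original (unreduced) network and is accepted for
    interface symmetry; the refits run on ``final_topology``'s pruned
    network with its merged sharing structure.  Per-round perturbation
    seeds derive from ``base_seed``; the optimizer itself keeps
    ``config.seed``, so at noise_scale 0 every round reproduces the point
    fit exactly.  Non-convergent rounds are dropped (and counted).
    """
    if config is None:
        config = FitConfig()
    seed_rng = np.random.default_rng(base_seed)
    seeds = [int(s) for s in seed_rng.integers(0, 2**31 - 1, size=n)]
    draws: list[dict[tuple[str, str], float]] = []
    n_dropped = 0
    for round_seed in seeds:
        perturbed = [
            perturb_measurements(ds, noise_scale, seed=round_seed + i)
            for i, ds in enumerate(datasets)
        ]
        res = fit(
            final_topology.network,
            perturbed,
            config,
            sharing=final_topology.merged_groups,
        )
        if not res.converged:
            n_dropped += 1
            warnings.warn(
                f"resampling round with seed {round_seed} did not converge; dropped",
                stacklevel=2,
            )
            continue
        draws.append(dict(res.params.values))
    if not draws:
        raise RuntimeError("no resampling round converged")
    keys = list(draws[0])
    per_param = {}
    for key in keys:
        vals = np.array([d[key] for d in draws])
        if np.ptp(vals) == 0.0:
            # bit-identical draws (e.g. noise_scale 0): report them exactly,
            # since the mean of n identical floats can be off by one ulp
            per_param[key] = (float(vals[0]), 0.0)
        else:
            per_param[key] = (float(vals.mean()), float(vals.std()))
    return ResampleSummary(
        n_resamples=n, per_param=per_param, seeds=seeds, n_dropped=n_dropped
    )
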