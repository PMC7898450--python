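# logicfit

Contextualization of probabilistic logic models of signalling networks.

`logicfit` fits a quantitative, probabilistic logic model of a signal
transduction network jointly to perturbation data from several biological
contexts (e.g. cell lines), and asks a sharp question: **which parameters
of the common network actually differ between contexts?** The motivating
application is the kinase network upstream of L-plastin Ser5
phosphorylation in breast-cancer cell lines, where a panel of growth
factors and kinase inhibitors is applied to each line and phospho-levels
of a few readouts are measured by immunoblotting.

## Model

A network is a signed, acyclic, weighted graph. Node activities are
probabilities of the active (phosphorylated) state. For a node `v` with
activating parents `u` (weights `w_uv`) and inhibiting parents `i`
(weights `w_iv`), the steady-state propagation rule is

```
act(v) = [ Σ_u w_uv · act(u) ] · Π_i (1 − w_iv · act(i))
```

Activator weights into a node are *relative contributions* and live on a
simplex (they sum to 1); inhibitor weights are free in [0, 1]. On an
acyclic graph, one pass in topological order is the exact fixed point of
this rule — `steady_state` computes exactly what damped fixed-point
iteration converges to, at a fraction of the cost.

## Pipeline

1. **Joint fitting** (`fit`): multi-start projected gradient descent on
   the pooled mean squared error across all contexts, with two optional
   penalties — a *pruning* penalty (`Σw − max w` per multi-activator
   node) that discourages spreading activation mass over parallel
   in-edges, and a *uniformity* penalty (`Σ |w_c − median_c(w)|` per
   label) that discourages unsupported differences between contexts.
2. **Model selection** (`scan_lambda_grid`): scan a log₂ grid of penalty
   strengths; score every fit with `BIC = N·ln(MSE) + k·ln(N)`, where a
   label uniform across contexts counts once and a context-specific
   label once per context; keep the BIC-minimal cell.
3. **Reduction** (`reduce_and_refit`): remove edges carrying negligible
   flux (weight × mean source activity < 0.01), hard-tie labels whose
   cross-context SD is < 0.01, and refit the reduced model without
   regularization for unbiased final estimates.
4. **Uncertainty** (`resample_parameters`): refit the final topology on
   noise-perturbed copies of the data (Gaussian noise scaled by each
   measurement's SEM, 20 rounds by default) and report per-parameter
   means and SDs.

Everything is deterministic given a seed; reruns are bit-identical.

## Worked example

The packaged `chain_network` fixture is a small, fully identifiable
network (2 stimulators, 2 inhibitor drugs, 1 hidden hub, 3 readouts).
Below, a ground truth in which exactly one parameter — the inhibitor
weight `k_D2_O2` — truly differs between two cell lines is recovered
from noisy simulated data:

```python
import logicfit as lf

net = lf.chain_network()
truth = lf.generate_ground_truth(net, 1, ["lineA", "lineB"], seed=11, noise_scale=0.02)
data = [lf.simulate_dataset(truth, lf.chain_design(), c) for c in ("lineA", "lineB")]
print("true context-specific labels:", [lab for lab, _ in truth.context_diffs])

grid = lf.GridSpec(log2_pruning=(float("-inf"),), log2_uniformity=tuple(range(-14, 1, 1)))
scan = lf.scan_lambda_grid(net, data, grid, lf.FitConfig(n_starts=3, seed=1))
print("selected log2(lambda_u):", scan.best[1], " MSE:", round(scan.best_fit.mse, 5))

reduced, final = lf.reduce_and_refit(net, data, scan.best_fit, lf.FitConfig(n_starts=3, seed=1))
print("removed edges:", len(reduced.removed_edges),
      " merged labels:", len(reduced.merged_groups), "of", len(net.param_labels))

summary = lf.resample_parameters(net, data, reduced, n=20, noise_scale=1.0,
                                 base_seed=1, config=lf.FitConfig(n_starts=3, seed=1))
print(summary.to_frame().round(3).to_string())
```

Output:

```
true context-specific labels: ['k_D2_O2']
selected log2(lambda_u): -14.0  MSE: 0.00024
removed edges: 0  merged labels: 8 of 9
             lineA_mean  lineA_sd  lineB_mean  lineB_sd
param_label
k_S1_M            0.290     0.004       0.290     0.004
k_S2_M            0.710     0.004       0.710     0.004
k_D1_M            0.602     0.006       0.602     0.006
k_M_O1            1.000     0.000       1.000     0.000
k_S1_O2           0.287     0.008       0.287     0.008
k_M_O2            0.713     0.008       0.713     0.008
k_D2_O2           0.465     0.016       0.718     0.012
k_S2_O3           0.295     0.013       0.295     0.013
k_M_O3            0.705     0.013       0.705     0.013
```

The pipeline merges the eight truly uniform parameters across the two
lines and leaves exactly the one genuinely different inhibitor weight
context-specific, with tight resampling SDs.

The larger packaged fixture, `lplastin_prior_network()`, is a 28-node
prior-knowledge network upstream of L-plastin Ser5 phosphorylation
(Ras/MAPK cascade, PI3K/AKT axis, Src/FAK cross-talk, PKA/PKC, five
kinases converging on LPL), with `paper_design(cell_line)` enumerating
the study's perturbation panel: 20 conditions for BT-20, HCC38 and
SKBR3; 12 for MCF7 (no EGF/HGF receptors); 4 readouts (ERK, AKT, Src,
LPL).

## Command line

The `logicfit` entry point wraps the library:

```
logicfit synth     --fixture chain --contexts c1,c2 --out-dir demo   # fixture data
logicfit fit       --network net.tsv --data c1=a.tsv --data c2=b.tsv
logicfit scan      --network net.tsv --data c1=a.tsv --data c2=b.tsv
logicfit reduce    --network net.tsv --data ... --lambda-pruning 0 --lambda-uniformity 1e-3
logicfit resample  --network net.tsv --data ...
logicfit pipeline  --config run.yaml   # scan → select → reduce → refit → resample
```

`pipeline` writes a report bundle (`bic_grid.tsv`, `params.tsv`,
`final_network.tsv`, `fit_vs_measurement.tsv`, `summary.txt`), every
file headed by the package version, a configuration hash and the seed.

Raw immunoblot quantifications can be converted to [0, 1] activities
with `normalize_blot_series` (phospho/total ratio → per-blot mean
normalization → global min–max).

## Reproduction

```
pip install --no-build-isolation -e ".[test]"
pytest                                   # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the end-to-end guarantees: exactness of
the one-pass steady state against damped fixed-point iteration,
numerical-zero MSE on noise-free data for both fixtures, parameter
recovery under noise, correct hard-constraint limits of both penalties,
BIC recovery of the number of context-specific parameters, the study's
design dimensions, and sanity of the resampling SDs.
`scripts/acceptance.py` runs the full pipeline on a synthetic
four-cell-line study over the L-plastin network plus the two chain
experiments and writes the principal quantities as JSON; it is
bit-reproducible for a given `--seed`.

See `docs/methods.md` for the modelling conventions, numerical choices
and limitations.
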