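# Methods

This note records the modelling conventions, numerical choices and known
limitations of `logicfit`. Nothing here claims an empirical result that
the package does not itself compute.

## Model

Networks are signed, weighted DAGs. Node activities are probabilities
of the active state, in [0, 1]. The propagation rule for a non-input
node `v` is

```
act(v) = [ Σ_u w_uv · act(u) ] · Π_i (1 − w_iv · act(i))
```

over activating parents `u` and inhibiting parents `i` — a
non-competitive weighted OR of activators gated by independent
probabilistic inhibition. Conventions:

* **Activator simplex.** Activator weights into a node sum to 1 per
  context: they are relative contributions, and a node with a single
  activating in-edge has that weight pinned at 1. This keeps activities
  in [0, 1] and removes a scale degeneracy.
* **Inhibitor box.** Inhibitor weights are free in [0, 1], independent
  of each other.
* **No activators ⇒ zero.** A node with only inhibiting in-edges has
  zero activation mass and is identically 0.
* **Exact steady state.** On a DAG, one pass in topological order is
  the unique fixed point of the rule, independent of initialization;
  `steady_state` computes it directly, and the test suite verifies
  agreement with damped fixed-point iteration to 1e-9.

Cycles are rejected at parse/validation time (with the offending cycle
named). Feedback is out of scope.

## Data model

Measurements are condition × readout tables per context, values in
[0, 1], `NaN` for missing cells (ignored by the loss), optional SEM
columns. `normalize_blot_series` converts raw immunoblot intensities to
activities: phospho/total ratio per lane, normalization by the mean of
each blot (making the result invariant to per-blot exposure), then a
global min–max to [0, 1]; an all-constant series maps to 0.5.

## Fitting

The loss is the pooled MSE over all non-missing cells of all contexts,
plus two penalties:

* **Pruning** (strength λ_p): for every (node, context) with ≥ 2
  activators, `Σw − max w`. Zero iff each node's activation mass sits
  on a single in-edge — a group partial-norm that sparsifies parallel
  activation paths.
* **Uniformity** (strength λ_u): for every label,
  `Σ_c |w_c − median_c(w)|`. Zero iff the label is identical across
  contexts; its hard limit (λ_u → ∞) is the fully tied "single model",
  which the test suite verifies to 1e-3 per parameter.

Optimization is multi-start projected gradient descent: analytic
reverse-mode gradients through the DAG, Barzilai–Borwein step sizes
with monotone Armijo backtracking, and Euclidean projection onto the
constraints (sort-based simplex projection; Dykstra's alternating
projections when hard cross-context ties make simplex blocks overlap).
Two numerical details matter for the uniformity penalty:

* Inside the optimizer the absolute value is Huber-smoothed with radius
  `μ = 1e-4·λ_u`; a pure sign subgradient blocks MSE descent along the
  uniform manifold. The radius is proportional to λ_u so the smoothed
  term's curvature (λ/μ) stays bounded at any strength; residual
  deviations settle far below the merge tolerance. *Reported* penalty
  values always use the exact formula.
* Full-gradient steps are interleaved with steps along the
  cross-context-averaged gradient (the same shift for every context of
  a label). The uniformity penalty is invariant along such shifts, so
  this subspace is never blocked by the penalty, which removes the
  crawl that plain subgradient descent exhibits near the tied optimum.

Fits are deterministic given (data, config, sharing); the loss trace is
monotone non-increasing; non-convergence is reported, never silent.

## Model selection and reduction

Every cell of a log₂ grid over (λ_p, λ_u) is fitted and scored with
`BIC = N·ln(MSE) + k·ln(N)`: `N` pooled non-missing cells, `k` distinct
parameters, where a label with cross-context SD ≤ 0.01 counts once and
otherwise once per context. Ties break toward larger λ (the sparser
model). Non-convergent cells are excluded from the arg-min with a
warning.

The selected model is then reduced: edges with flux (weight × mean
source activity over all conditions and contexts) below 0.01 are
removed; labels with cross-context SD below 0.01 are hard-tied; the
reduced topology is refit with λ = 0 for unbiased final estimates. A
reduction that would disconnect a measured output raises a structural
error rather than producing a silently broken model.

## Uncertainty

Parameter SDs come from refitting the final topology on 20 (by
default) noise-perturbed copies of the data: each cell is displaced by
Gaussian noise with SD = `noise_scale × SEM` (or a global scale without
SEMs) and clipped to [0, 1]. The optimizer seed is held fixed, so at
`noise_scale = 0` every round reproduces the point fit bit-exactly and
all SDs are exactly zero (identical draws are detected and reported
exactly, since the floating-point mean of n identical values can be one
ulp off).

## Synthetic ground truth

`generate_ground_truth` draws activator splits uniformly on each
node's simplex (resampled until every weight ≥ 0.1, so all prior
pathways carry signal) and inhibitor weights uniform in [0.3, 0.9]
(effective but not saturating). Context differences of magnitude
≥ 0.2 are applied to **inhibitor labels only**, one context each: the
box constraint lets a single label move without dragging sibling
weights along, so the truth has *exactly* the requested number of
context-specific labels — perturbing a simplex label would force its
siblings to move too, making the count ill-defined. The generator
raises if asked for more differences than the network has inhibitor
labels. These generator constants are study conventions, fixed across
all experiments in the test suite and acceptance script.

`simulate_dataset` propagates a design through the truth and adds
clipped Gaussian noise; SEM columns carry the generating SD; the noise
seed derives deterministically from the truth seed and the context
name.

## Experiment design for sparsity recovery

The recovery-of-context-differences experiment (acceptance criterion 5
and `chain_sparsity` in the acceptance script) uses **three contexts**
and a λ_u grid with log₂ step 1. Both choices are statistical, not
tuning: with two contexts a spurious context split costs only `ln N`
in BIC against a ~χ² MSE gain, giving an irreducible false-positive
rate around 20%; a third context doubles the penalty to `2·ln N`. The
finer grid resolves marginal ties where the coarse (step 2) grid has
no cell between "too loose" and "too tight". On noise-free data the
procedure recovers the true sparsity pattern exactly; the measured
rate at noise 0.02 over 25 seeds is 24/25.

## Scope and limitations

* Acyclic networks only; no feedback loops, no dynamics — the model is
  a steady-state snapshot, as appropriate for single-time-point
  perturbation panels.
* The objective is non-convex; multi-start PGD finds the global
  optimum reliably on the packaged fixtures (noise-free MSE ≤ 1e-6)
  but offers no guarantee on arbitrary networks. Increase `n_starts`
  for harder problems.
* BIC with the SD-threshold parameter count is a heuristic; the 0.01
  merge/flux tolerances are conventions, configurable throughout.
* The resampling SDs quantify sensitivity of the fit to
  measurement-scale noise around the observed data, not full posterior
  uncertainty; weakly identified parameters show large SDs but are not
  otherwise flagged.
* The packaged L-plastin network is a faithful rendering of the
  curated pathway content (receptors → Ras/MAPK and PI3K axes, Src/FAK
  cross-talk, five kinases converging on LPL, five drug inhibitions),
  not an edge-for-edge copy of any particular supplementary file;
  `parse_network` accepts such a file directly for exact replication
  work. The PMA→PKA edge is a fixture convention keeping PKA reachable
  under the packaged design.
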