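"""Steady-state propagation of activities through a weighted logic network.

Activities are probabilities of the active (phosphorylated) state.  For a
non-input node ``v`` with activating parents ``u`` (weights ``w_uv``) and
inhibiting parents ``i`` (weights ``w_iv``), the update rule is

    act(v) = [ sum_u w_uv * act(u) ] * prod_i (1 - w_iv * act(i))

a non-competitive weighted OR of activators gated by independent
probabilistic inhibition.  Activator weights live on a per-node simplex
(they are *relative contributions*: they sum to 1), inhibitor weights are
free in [0, 1].  On an acyclic network a single pass in topological order
is the exact fixed point of this rule, independent of initialization, so
``steady_state`` computes exactly what damped fixed-point iteration from a
random start converges to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Condition, LogicNetwork, StructuralError

__all__ = ["ParameterSet", "StateVector", "steady_state", "simulate_design"]

SIMPLEX_ATOL = 1e-6


@dataclass
class ParameterSet:
    """Edge weights per context, with an explicit sharing structure.

    ``values`` maps ``(param_label, context)`` to a weight in [0, 1];
    ``sharing`` is a partition of those pairs into groups constrained to a
    common value (hard ties, used for the single model and for the merged
    groups of the reduced final model).  Pairs not mentioned in ``sharing``
    are free.
    """

    values: dict[tuple[str, str], float]
    sharing: list[frozenset[tuple[str, str]]] = field(default_factory=list)

    @property
    def contexts(self) -> list[str]:
        seen: list[str] = []
        for _, ctx in self.values:
            if ctx not in seen:
                seen.append(ctx)
        return seen

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab, _ in self.values:
            if lab not in seen:
                seen.append(lab)
        return seen

    def get(self, label: str, context: str) -> float:
        return self.values[(label, context)]

    def validate(self, network: LogicNetwork) -> None:
        """Check the box and per-node activator-simplex constraints."""
        for (lab, ctx), w in self.values.items():
            if not (-SIMPLEX_ATOL <= w <= 1 + SIMPLEX_ATOL):
                raise ValueError(f"weight {lab!r}@{ctx!r} = {w} outside [0, 1]")
        for ctx in self.contexts:
            for node in network.node_names:
                acts = network.activators_of(node)
                if not acts:
                    continue
                total = sum(self.values[(e.param_label, ctx)] for e in acts)
                if abs(total - 1.0) > SIMPLEX_ATOL * max(10, len(acts)):
                    raise ValueError(
                        f"activator weights into {node!r} in context {ctx!r} "
                        f"sum to {total:.6f}, expected 1"
                    )
        for group in self.sharing:
            vals = {self.values[p] for p in group}
            if max(vals) - min(vals) > SIMPLEX_ATOL:
                raise ValueError(f"sharing group {sorted(group)} not tied: {vals}")

    def as_frame(self) -> pd.DataFrame:
        """Label × context table of the weights."""
        return pd.DataFrame(
            {ctx: [self.values[(lab, ctx)] for lab in self.labels] for ctx in self.contexts},
            index=self.labels,
        )

    def to_tsv(self) -> str:
        """TSV parameter table: one row per label, one column per context."""
        lines = ["param_label\t" + "\t".join(self.contexts)]
        for lab in self.labels:
            lines.append(
                lab + "\t" + "\t".join(repr(float(self.values[(lab, c)])) for c in self.contexts)
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ParameterSet":
        rows = [l.split("\t") for l in text.splitlines() if l.strip() and not l.startswith("#")]
        header = rows[0]
        if header[0] != "param_label":
            raise ValueError("parameter table must start with a 'param_label' column")
        contexts = header[1:]
        values: dict[tuple[str, str], float] = {}
        for row in rows[1:]:
            lab = row[0]
            for ctx, v in zip(contexts, row[1:]):
                values[(lab, ctx)] = float(v)
        return cls(values=values)


@dataclass(frozen=True)
class StateVector:
    """Steady-state activity of every node, all in [0, 1]."""

    activity: dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.activity[node]


# ---------------------------------------------------------------------------
# Compiled form: index arrays for fast vectorized propagation.  Shared with
# the fitting module, which back-propagates gradients through it.
# ---------------------------------------------------------------------------


class CompiledNetwork:
    """Index-array form of a LogicNetwork for vectorized propagation."""

    def __init__(self, network: LogicNetwork):
        self.network = network
        self.node_names = network.node_names
        self.node_index = {n: i for i, n in enumerate(self.node_names)}
        self.labels = network.param_labels
        self.label_index = {l: i for i, l in enumerate(self.labels)}
        self.input_idx = np.array([self.node_index[n] for n in network.input_nodes], dtype=int)
        self.output_idx = np.array([self.node_index[n] for n in network.output_nodes], dtype=int)
        # per activator label: which node's simplex it belongs to (one only)
        self.activator_labels_by_node: dict[str, list[str]] = {}
        owner: dict[str, str] = {}
        inhibitor_labels: set[str] = set()
        for node in self.node_names:
            labs = [e.param_label for e in network.activators_of(node)]
            if labs:
                self.activator_labels_by_node[node] = labs
            for l in labs:
                if l in inhibitor_labels:
                    raise StructuralError(f"label {l!r} used on both activating and inhibiting edges")
                if l in owner and owner[l] != node:
                    raise StructuralError(
                        f"activator label {l!r} shared across nodes {owner[l]!r} and {node!r}: "
                        "per-node simplex constraints would couple"
                    )
                owner[l] = node
            for e in network.inhibitors_of(node):
                if e.param_label in owner:
                    raise StructuralError(
                        f"label {e.param_label!r} used on both activating and inhibiting edges"
                    )
                inhibitor_labels.add(e.param_label)
        self.inhibitor_labels = sorted(inhibitor_labels, key=self.labels.index)
        # topological update schedule for non-input nodes
        self.schedule: list[tuple[int, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        inputs = set(network.input_nodes)
        for node in network.topological_order():
            if node in inputs:
                continue
            acts = network.activators_of(node)
            inhs = network.inhibitors_of(node)
            self.schedule.append(
                (
                    self.node_index[node],
                    np.array([self.node_index[e.source] for e in acts], dtype=int),
                    np.array([self.label_index[e.param_label] for e in acts], dtype=int),
                    np.array([self.node_index[e.source] for e in inhs], dtype=int),
                    np.array([self.label_index[e.param_label] for e in inhs], dtype=int),
                )
            )

    def weights_vector(self, params: ParameterSet, context: str) -> np.ndarray:
        return np.array([params.values[(l, context)] for l in self.labels], dtype=float)

    def input_matrix(self, conditions: list[Condition]) -> np.ndarray:
        """(n_inputs, n_conditions) matrix of clamped input activities."""
        mat = np.empty((len(self.input_idx), len(conditions)))
        for j, cond in enumerate(conditions):
            for k, name in enumerate(self.network.input_nodes):
                if name not in cond.input_assignment:
                    raise ValueError(
                        f"condition {cond.name!r} does not assign input node {name!r}"
                    )
                mat[k, j] = float(cond.input_assignment[name])
        return mat

    def forward(self, w: np.ndarray, inputs: np.ndarray) -> np.ndarray:
        """Propagate: returns the (n_nodes, n_conditions) activity matrix."""
        n_cond = inputs.shape[1]
        act = np.zeros((len(self.node_names), n_cond))
        act[self.input_idx] = inputs
        for node, a_src, a_lab, i_src, i_lab in self.schedule:
            if a_src.size:
                s = w[a_lab] @ act[a_src]
            else:
                s = np.zeros(n_cond)
            if i_src.size:
                s = s * np.prod(1.0 - w[i_lab, None] * act[i_src], axis=0)
            act[node] = s
        return act


def steady_state(
    network: LogicNetwork, params: ParameterSet, condition: Condition, context: str
) -> StateVector:
    """Exact steady state of the propagation rule for one condition.

    Raises a precondition error for unassigned inputs and a domain error
    for constraint-violating parameters.
    """
    params.validate(network)
    compiled = CompiledNetwork(network)
    act = compiled.forward(
        compiled.weights_vector(params, context), compiled.input_matrix([condition])
    )
    return StateVector({n: float(act[i, 0]) for n, i in compiled.node_index.items()})


def simulate_design(
    network: LogicNetwork,
    params: ParameterSet,
    conditions: list[Condition],
    context: str,
) -> pd.DataFrame:
    """Condition × output-node activity matrix for a whole design."""
    params.validate(network)
    compiled = CompiledNetwork(network)
    act = compiled.forward(
        compiled.weights_vector(params, context), compiled.input_matrix(conditions)
    )
    return pd.DataFrame(
        act[compiled.output_idx].T,
        index=pd.Index([c.name for c in conditions], name="condition"),
        columns=network.output_nodes,
    )
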