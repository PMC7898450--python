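"""Domain types and file I/O for signed signalling logic networks.

A :class:`LogicNetwork` is a signed, acyclic interaction graph whose nodes
play one of three roles: *input* nodes are clamped by the experimental
condition (growth-factor stimulators and kinase-inhibitor drugs), *output*
nodes are experimentally measured (phospho/total immunoblot ratios), and
*hidden* nodes are everything in between.  Edges are either activating
(``->``) or inhibiting (``-|``) and carry a parameter label; edges may share
a label to share a weight.

The module also carries the raw-data preprocessing chain: immunoblot
phospho/total intensity ratios are normalized per blot and min–max scaled
to [0, 1] activities (:func:`normalize_blot_series`).

File dialects are tab-separated UTF-8 with ``#`` comment lines and a header
row; see :func:`parse_network` and :func:`parse_measurements`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "SchemaError",
    "StructuralError",
    "NodeSpec",
    "EdgeSpec",
    "LogicNetwork",
    "Condition",
    "MeasurementSet",
    "BlotSeries",
    "parse_network",
    "write_network",
    "parse_measurements",
    "write_measurements",
    "normalize_blot_series",
]

ROLES = ("input", "hidden", "output")
SIGN_TOKENS = {"->": "activating", "-|": "inhibiting"}
TOKEN_OF_SIGN = {v: k for k, v in SIGN_TOKENS.items()}


class ParseError(ValueError):
    """A document could not be parsed (bad token, non-numeric cell, ...)."""


class SchemaError(ValueError):
    """A document's columns do not match the network it is parsed against."""


class StructuralError(ValueError):
    """The graph violates a structural invariant (cycle, unreachable output, ...)."""


@dataclass(frozen=True)
class NodeSpec:
    """A named network node with a role in {input, hidden, output}."""

    name: str
    role: str = "hidden"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown node role {self.role!r} for node {self.name!r}")


@dataclass(frozen=True)
class EdgeSpec:
    """A signed, labelled interaction from ``source`` to ``target``.

    ``sign`` is ``"activating"`` or ``"inhibiting"``; ``param_label`` names
    the weight parameter (several edges may share one label).
    """

    source: str
    target: str
    sign: str
    param_label: str

    def __post_init__(self) -> None:
        if self.sign not in SIGN_TOKENS.values():
            raise ValueError(f"unknown edge sign {self.sign!r}")
        if self.source == self.target:
            raise StructuralError(f"self-loop on node {self.source!r}")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: an activity assignment for every input node.

    Stimulators and inhibitor drugs are both input nodes; present means
    activity 1, absent means 0 (fractional activities are permitted).
    """

    name: str
    input_assignment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, value in self.input_assignment.items():
            if not (0.0 <= float(value) <= 1.0):
                raise ValueError(
                    f"condition {self.name!r}: input {node!r} activity {value} outside [0, 1]"
                )


class LogicNetwork:
    """A validated signed acyclic interaction graph.

    Parameters
    ----------
    nodes : list of NodeSpec
    edges : list of EdgeSpec

    Raises
    ------
    StructuralError
        On duplicate node names, dangling edge endpoints, duplicate
        (source, target) pairs, cycles, in-edges into input nodes, or an
        output node unreachable from every input node.
    """

    def __init__(self, nodes: list[NodeSpec], edges: list[EdgeSpec]):
        self.nodes = list(nodes)
        self.edges = list(edges)
        self._validate()
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(n.name for n in self.nodes)
        self._graph.add_edges_from((e.source, e.target) for e in self.edges)
        self._topo = list(nx.topological_sort(self._graph))

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise StructuralError(f"duplicate node names: {dupes}")
        name_set = set(names)
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in name_set or e.target not in name_set:
                raise StructuralError(f"edge {e.source}->{e.target} has unknown endpoint")
            if (e.source, e.target) in seen_pairs:
                raise ParseError(f"duplicated edge {e.source} -> {e.target}")
            seen_pairs.add((e.source, e.target))

        g = nx.DiGraph()
        g.add_nodes_from(name_set)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join([c[0] for c in cycle] + [cycle[-1][1]])
            raise StructuralError(f"network contains a cycle: {path}")

        roles = {n.name: n.role for n in self.nodes}
        for e in self.edges:
            if roles[e.target] == "input":
                raise StructuralError(
                    f"input node {e.target!r} has an incoming edge from {e.source!r}"
                )
        inputs = [n for n in names if roles[n] == "input"]
        reachable: set[str] = set(inputs)
        for n in inputs:
            reachable |= nx.descendants(g, n)
        for n in names:
            if roles[n] == "output" and n not in reachable:
                raise StructuralError(f"output node {n!r} unreachable from every input node")

    # -- accessors --------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def input_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "input"]

    @property
    def output_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "output"]

    @property
    def param_labels(self) -> list[str]:
        seen: list[str] = []
        for e in self.edges:
            if e.param_label not in seen:
                seen.append(e.param_label)
        return seen

    def topological_order(self) -> list[str]:
        return list(self._topo)

    def in_edges(self, node: str) -> list[EdgeSpec]:
        return [e for e in self.edges if e.target == node]

    def activators_of(self, node: str) -> list[EdgeSpec]:
        return [e for e in self.in_edges(node) if e.sign == "activating"]

    def inhibitors_of(self, node: str) -> list[EdgeSpec]:
        return [e for e in self.in_edges(node) if e.sign == "inhibiting"]

    def role_of(self, node: str) -> str:
        for n in self.nodes:
            if n.name == node:
                return n.role
        raise KeyError(node)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"LogicNetwork({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"inputs={self.input_nodes}, outputs={self.output_nodes})"
        )


@dataclass
class MeasurementSet:
    """Per-context (cell line) condition × output activity matrix in [0, 1].

    ``values`` is indexed by condition name with output-node columns;
    ``sem`` (optional) holds per-value standard errors of the mean, same
    shape.  Missing measurements are NaN and are masked out of every loss.
    """

    context: str
    conditions: list[Condition]
    values: pd.DataFrame
    sem: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cond_names = [c.name for c in self.conditions]
        if list(self.values.index) != cond_names:
            raise SchemaError("values index must equal the condition names, in order")
        v = self.values.to_numpy(dtype=float)
        finite = np.isfinite(v)
        if np.any((v[finite] < 0) | (v[finite] > 1)):
            raise ValueError(f"context {self.context!r}: activities outside [0, 1]")
        if self.sem is not None:
            if self.sem.shape != self.values.shape or list(self.sem.columns) != list(
                self.values.columns
            ):
                raise SchemaError("sem matrix must be congruent with values")
            s = self.sem.to_numpy(dtype=float)
            if np.any(s[np.isfinite(s)] < 0):
                raise ValueError("negative SEM")

    @property
    def output_nodes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_measurements(self) -> int:
        """Number of non-missing measured cells."""
        return int(np.isfinite(self.values.to_numpy(dtype=float)).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementSet):
            return NotImplemented
        same_sem = (
            (self.sem is None and other.sem is None)
            or (self.sem is not None and other.sem is not None and self.sem.equals(other.sem))
        )
        return (
            self.context == other.context
            and self.conditions == other.conditions
            and self.values.equals(other.values)
            and same_sem
        )


@dataclass
class BlotSeries:
    """Phospho/total intensity pairs for the lanes of one or more blots."""

    phospho_intensity: np.ndarray
    total_intensity: np.ndarray
    blot_id: np.ndarray
    control_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phospho_intensity = np.asarray(self.phospho_intensity, dtype=float)
        self.total_intensity = np.asarray(self.total_intensity, dtype=float)
        self.blot_id = np.asarray(self.blot_id)
        n = self.phospho_intensity.size
        if self.total_intensity.size != n or self.blot_id.size != n:
            raise ValueError("phospho, total and blot_id must have equal length")
        if self.control_flags is None:
            self.control_flags = np.zeros(n, dtype=bool)
        else:
            self.control_flags = np.asarray(self.control_flags, dtype=bool)
            if self.control_flags.size != n:
                raise ValueError("control_flags length mismatch")
        if np.any(self.phospho_intensity <= 0) or np.any(self.total_intensity <= 0):
            raise ValueError("intensities must be strictly positive")


# ---------------------------------------------------------------------------
# Network file I/O
#
# Dialect: TSV, UTF-8, '#' comments, header row
#     source  sign  target  param_label
# with sign tokens '->' (activating) and '-|' (inhibiting), followed by an
# optional '[roles]' section of 'node<TAB>role' lines overriding the
# inferred roles (no in-edges -> input; declared outputs -> output).
# ---------------------------------------------------------------------------


def parse_network(text: str, outputs: list[str] | None = None) -> LogicNetwork:
    """Parse an interaction-list document into a validated LogicNetwork.

    Node roles are inferred — nodes without in-edges become inputs and
    names listed in ``outputs`` (or in the document's ``[roles]`` section)
    become outputs — unless the roles section overrides them.
    """
    edges: list[EdgeSpec] = []
    role_overrides: dict[str, str] = {}
    in_roles = False
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[roles]":
            in_roles = True
            continue
        parts = [p.strip() for p in line.split("\t")]
        if in_roles:
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: roles lines need 'node<TAB>role'")
            node, role = parts
            if role not in ROLES:
                raise ParseError(f"line {lineno}: unknown role {role!r}")
            role_overrides[node] = role
            continue
        if not header_seen:
            header_seen = True
            if [p.lower() for p in parts[:4]] == ["source", "sign", "target", "param_label"]:
                continue  # explicit header row
            # fall through: headerless documents are accepted
        if len(parts) != 4:
            raise ParseError(f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}")
        source, sign_token, target, label = parts
        if sign_token not in SIGN_TOKENS:
            raise ParseError(f"line {lineno}: unknown sign token {sign_token!r}")
        edges.append(EdgeSpec(source, target, SIGN_TOKENS[sign_token], label))

    # the [roles] section, when present, fixes the node order (so writing
    # and re-parsing a network preserves it); edge-only nodes follow in
    # order of first mention
    names: list[str] = list(role_overrides)
    for e in edges:
        for n in (e.source, e.target):
            if n not in names:
                names.append(n)

    targets = {e.target for e in edges}
    outputs = list(outputs or [])
    nodes = []
    for n in names:
        if n in role_overrides:
            role = role_overrides[n]
        elif n in outputs:
            role = "output"
        elif n not in targets:
            role = "input"
        else:
            role = "hidden"
        nodes.append(NodeSpec(n, role))
    return LogicNetwork(nodes, edges)


def write_network(network: LogicNetwork) -> str:
    """Serialize a LogicNetwork to the TSV interaction-list dialect."""
    buf = io.StringIO()
    buf.write("source\tsign\ttarget\tparam_label\n")
    for e in network.edges:
        buf.write(f"{e.source}\t{TOKEN_OF_SIGN[e.sign]}\t{e.target}\t{e.param_label}\n")
    buf.write("[roles]\n")
    for n in network.nodes:
        buf.write(f"{n.name}\t{n.role}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Measurement file I/O
#
# TSV, one row per condition: a 'condition' name column, one column per
# input node (0/1 or fractional), one column per output node (activities in
# [0,1]) and optional '<node>__sem' columns.
# ---------------------------------------------------------------------------


def parse_measurements(text: str, network: LogicNetwork, context: str = "default") -> MeasurementSet:
    """Parse a condition table against a network's input/output schema."""
    df = _read_tsv(text)
    if "condition" not in df.columns:
        raise SchemaError("measurement table needs a 'condition' column")
    missing_inputs = [n for n in network.input_nodes if n not in df.columns]
    if missing_inputs:
        raise SchemaError(f"missing input-node columns: {missing_inputs}")
    known = set(network.input_nodes) | set(network.output_nodes)
    extra = [
        c
        for c in df.columns
        if c != "condition" and not c.endswith("__sem") and c not in known
    ]
    if extra:
        raise SchemaError(f"columns not input or output nodes of the network: {extra}")
    out_cols = [n for n in network.output_nodes if n in df.columns]
    if not out_cols:
        raise SchemaError("no output-node columns present")

    conditions = []
    for _, row in df.iterrows():
        assignment = {}
        for n in network.input_nodes:
            v = _to_float(row[n], row["condition"], n)
            assignment[n] = v
        conditions.append(Condition(str(row["condition"]), assignment))

    values = pd.DataFrame(
        {c: [_to_float(v, i, c, allow_nan=True) for i, v in zip(df["condition"], df[c])] for c in out_cols},
        index=[str(x) for x in df["condition"]],
    )
    values.index.name = "condition"
    sem_cols = [f"{c}__sem" for c in out_cols]
    sem = None
    if any(s in df.columns for s in sem_cols):
        sem = pd.DataFrame(
            {
                c: [
                    _to_float(v, i, f"{c}__sem", allow_nan=True)
                    for i, v in zip(df["condition"], df[f"{c}__sem"])
                ]
                if f"{c}__sem" in df.columns
                else [np.nan] * len(df)
                for c in out_cols
            },
            index=values.index.copy(),
        )
    return MeasurementSet(context=context, conditions=conditions, values=values, sem=sem)


def write_measurements(ms: MeasurementSet, network: LogicNetwork) -> str:
    """Serialize a MeasurementSet to the TSV condition-table dialect.

    Floats are written with ``repr`` so that parse(write(x)) round-trips
    bit-exactly.
    """
    cols = ["condition"] + list(network.input_nodes) + list(ms.output_nodes)
    if ms.sem is not None:
        cols += [f"{c}__sem" for c in ms.output_nodes]
    buf = io.StringIO()
    buf.write("\t".join(cols) + "\n")
    for i, cond in enumerate(ms.conditions):
        row = [cond.name]
        row += [repr(float(cond.input_assignment[n])) for n in network.input_nodes]
        row += [repr(float(ms.values.iloc[i][c])) for c in ms.output_nodes]
        if ms.sem is not None:
            row += [repr(float(ms.sem.iloc[i][c])) for c in ms.output_nodes]
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()


def _read_tsv(text: str) -> pd.DataFrame:
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise ParseError("empty document")
    return pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str)


def _to_float(value, row_key, col: str, allow_nan: bool = False) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if allow_nan:
            return float("nan")
        raise ParseError(f"missing value at row {row_key!r}, column {col!r}")
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"non-numeric cell at row {row_key!r}, column {col!r}: {value!r}")
    if not col.endswith("__sem") and np.isfinite(v) and not (0.0 <= v <= 1.0):
        raise ParseError(f"value out of [0, 1] at row {row_key!r}, column {col!r}: {v}")
    return v


# ---------------------------------------------------------------------------
# Immunoblot preprocessing
# ---------------------------------------------------------------------------


def normalize_blot_series(series: BlotSeries) -> np.ndarray:
    """Turn raw immunoblot intensities into activities in [0, 1].

    Three steps, mirroring the standard quantification chain:

    1. per lane, the phospho/total intensity ratio ``r`` (makes samples
       comparable);
    2. each ``r`` divided by the mean ``r`` of its blot (makes blots
       comparable, absorbing day-to-day technical variability);
    3. min–max scaling of the blot-normalized values over the whole series
       onto [0, 1].

    A constant series (zero range in step 3) maps to 0.5 everywhere — the
    data then carry no contrast and the midpoint is the least-committal
    activity.  The result is invariant under rescaling all intensities of
    any one blot by a positive constant.
    """
    ratios = series.phospho_intensity / series.total_intensity
    normalized = np.empty_like(ratios)
    for blot in np.unique(series.blot_id):
        mask = series.blot_id == blot
        normalized[mask] = ratios[mask] / ratios[mask].mean()
    lo, hi = normalized.min(), normalized.max()
    if hi - lo == 0:
        return np.full_like(normalized, 0.5)
    return (normalized - lo) / (hi - lo)
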