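import numpy as np
import pytest

import logicfit as lf


@pytest.fixture(scope="session")
def chain_net():
    return lf.chain_network()


@pytest.fixture(scope="session")
def chain_design():
    return lf.chain_design()


@pytest.fixture(scope="session")
def lpl_net():
    return lf.lplastin_prior_network()


def random_dag(rng, n_nodes=None, p_edge=0.5, p_inhibit=0.3):
    """A random valid LogicNetwork of <= 8 nodes with >= 1 input and
    >= 1 measured sink, for property and oracle tests."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 9))
    names = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for j in range(1, n_nodes):
        parents = [i for i in range(j) if rng.random() < p_edge]
        if not parents and rng.random() < 0.8:
            parents = [int(rng.integers(j))]
        for i in parents:
            sign = "inhibiting" if rng.random() < p_inhibit else "activating"
            edges.append(lf.EdgeSpec(names[i], names[j], sign, f"k{i}_{j}"))
    targets = {e.target for e in edges}
    sources = {e.source for e in edges}
    nodes = []
    for n in names:
        if n not in targets:
            nodes.append(lf.NodeSpec(n, "input"))
        elif n not in sources:
            nodes.append(lf.NodeSpec(n, "output"))
        else:
            nodes.append(lf.NodeSpec(n, "hidden"))
    net = lf.LogicNetwork(nodes, edges)
    if not net.input_nodes or not net.output_nodes:
        return random_dag(rng, n_nodes, p_edge, p_inhibit)
    # outputs unreachable from inputs would fail validation; the recursive
    # retry above keeps sampling until a valid graph comes out
    return net


def random_params(rng, net, contexts=("ctx",)):
    """Valid random ParameterSet: Dirichlet simplex weights, uniform boxes."""
    values = {}
    base = {}
    for node in net.node_names:
        acts = net.activators_of(node)
        if acts:
            w = rng.dirichlet(np.ones(len(acts)))
            for e, wi in zip(acts, w):
                base[e.param_label] = float(wi)
        for e in net.inhibitors_of(node):
            base[e.param_label] = float(rng.random())
    for lab, v in base.items():
        for c in contexts:
            values[(lab, c)] = v
    return lf.ParameterSet(values=values)


def random_condition(rng, net, name="cond"):
    return lf.Condition(name, {n: float(rng.random()) for n in net.input_nodes})


def naive_fixed_point(net, params, condition, context, rng, damping=0.5, tol=1e-12, max_iter=20000):
    """Independent oracle: damped synchronous fixed-point iteration of the
    propagation rule from a random initial state, dict-based."""
    act = {n: float(rng.random()) for n in net.node_names}
    for n, v in condition.input_assignment.items():
        act[n] = float(v)
    inputs = set(net.input_nodes)
    for _ in range(max_iter):
        new = {}
        for n in net.node_names:
            if n in inputs:
                new[n] = act[n]
                continue
            s = 0.0
            for e in net.activators_of(n):
                s += params.values[(e.param_label, context)] * act[e.source]
            prod = 1.0
            for e in net.inhibitors_of(n):
                prod *= 1.0 - params.values[(e.param_label, context)] * act[e.source]
            new[n] = s * prod
        delta = max(abs(new[n] - act[n]) for n in net.node_names)
        act = {n: (1 - damping) * act[n] + damping * new[n] for n in net.node_names}
        for n, v in condition.input_assignment.items():
            act[n] = float(v)
        if delta < tol:
            break
    return act
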