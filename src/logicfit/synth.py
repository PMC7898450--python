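"""Ground-truthed synthetic networks, designs and datasets.

Two packaged fixtures:

* :func:`lplastin_prior_network` — a literature-style prior-knowledge
  network upstream of L-plastin Ser5 phosphorylation: growth-factor inputs
  (EGF, HGF, IGF, PMA), kinase-inhibitor drug inputs, the
  Ras→Raf→MEK→ERK→RSK cascade, the PI3K→PDK1/mTOR→AKT/SGK/p70S6K axis,
  FAK/Src cross-talk, PKA and PKC, and exactly five activating edges into
  LPL (from RSK, SGK, PKA, PKC and p70S6K).  Measured outputs: ERK, AKT,
  Src, LPL.
* :func:`chain_network` — a small fully identifiable network used for
  parameter-recovery and sparsity-recovery experiments.

:func:`paper_design` enumerates the perturbation design of the study this
pipeline emulates: 20 conditions for BT-20, HCC38 and SKBR3 and 12 for
MCF7 (which lacks EGF and HGF receptors), built as control + each
stimulator alone + each inhibitor alone + every inhibitor×stimulator pair.

:func:`generate_ground_truth` draws simplex-valid weights shared across
contexts and makes a chosen number of parameters context-specific;
:func:`simulate_dataset` propagates a design through the truth and adds
clipped Gaussian noise, emulating SEM-scale immunoblot variability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Condition, LogicNetwork, MeasurementSet, NodeSpec, EdgeSpec
from .simulate import CompiledNetwork, ParameterSet, simulate_design

__all__ = [
    "GroundTruth",
    "DesignSpec",
    "lplastin_prior_network",
    "chain_network",
    "paper_design",
    "chain_design",
    "generate_ground_truth",
    "simulate_dataset",
]

CELL_LINES = ("BT-20", "HCC38", "MCF7", "SKBR3")

# stimulators and modelled inhibitor drugs of the perturbation design
STIMULATORS = ("EGF", "HGF", "IGF", "PMA")
DESIGN_INHIBITORS = ("BID", "AKTi", "FAKi")
# drugs present in the prior network but not part of the modelling design
EXTRA_DRUGS = ("MEKi", "PI3Ki")


@dataclass
class GroundTruth:
    """A network with known parameters, context differences and noise level."""

    network: LogicNetwork
    params: ParameterSet
    context_diffs: list[tuple[str, str]]
    noise_scale: float
    seed: int

    def __post_init__(self) -> None:
        self.params.validate(self.network)
        labels = set(self.network.param_labels)
        for lab, _ctx in self.context_diffs:
            if lab not in labels:
                raise ValueError(f"context diff on unknown label {lab!r}")


@dataclass
class DesignSpec:
    """An experimental design: which inputs are toggled, and how."""

    stimulators: list[str]
    inhibitors: list[str]
    conditions: list[Condition]
    n_outputs: int

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        listed = set(self.stimulators) | set(self.inhibitors)
        for c in self.conditions:
            missing = listed - set(c.input_assignment)
            if missing:
                raise ValueError(f"condition {c.name!r} does not assign {sorted(missing)}")


# ---------------------------------------------------------------------------
# Fixture networks
# ---------------------------------------------------------------------------

_LPL_EDGES = [
    # receptor binding
    ("EGF", "->", "EGFR"),
    ("HGF", "->", "HGFR"),
    ("IGF", "->", "IGFR"),
    # RTKs feed Ras and PI3K
    ("EGFR", "->", "Ras"),
    ("HGFR", "->", "Ras"),
    ("IGFR", "->", "Ras"),
    ("EGFR", "->", "PI3K"),
    ("HGFR", "->", "PI3K"),
    ("IGFR", "->", "PI3K"),
    # Src/FAK cross-talk hub
    ("EGFR", "->", "Src"),
    ("HGFR", "->", "Src"),
    ("Src", "->", "FAK"),
    ("FAK", "->", "Ras"),
    ("FAK", "->", "PI3K"),
    # Ras/MAPK cascade
    ("Ras", "->", "Raf"),
    ("PKC", "->", "Raf"),
    ("Raf", "->", "MEK"),
    ("MEK", "->", "ERK"),
    ("ERK", "->", "RSK"),
    # PI3K axis
    ("PI3K", "->", "PDK1"),
    ("PI3K", "->", "mTOR"),
    ("PDK1", "->", "AKT"),
    ("mTOR", "->", "AKT"),
    ("PDK1", "->", "SGK"),
    ("mTOR", "->", "SGK"),
    ("mTOR", "->", "p70S6K"),
    # phorbol ester arm (PMA->PKA is a fixture convention keeping PKA
    # reachable; the prior wiring of PKA is not constrained by the data)
    ("PMA", "->", "PKC"),
    ("PMA", "->", "PKA"),
    # the five kinases converging on L-plastin Ser5
    ("RSK", "->", "LPL"),
    ("SGK", "->", "LPL"),
    ("PKA", "->", "LPL"),
    ("PKC", "->", "LPL"),
    ("p70S6K", "->", "LPL"),
    # drug inhibitions
    ("BID", "-|", "RSK"),
    ("AKTi", "-|", "AKT"),
    ("FAKi", "-|", "FAK"),
    ("MEKi", "-|", "MEK"),
    ("PI3Ki", "-|", "PI3K"),
    ("PI3Ki", "-|", "mTOR"),
]

_LPL_OUTPUTS = ("ERK", "AKT", "Src", "LPL")


def lplastin_prior_network() -> LogicNetwork:
    """The packaged prior-knowledge network upstream of L-plastin Ser5-P.

    A faithful rendering of the curated pathway content (Ras/MAPK, PI3K/AKT,
    cross-talk, five kinase inputs into LPL), not an edge-for-edge copy of
    any particular supplementary file; :func:`logicfit.parse_network`
    accepts such a file directly for exact replication work.
    """
    inputs = STIMULATORS + DESIGN_INHIBITORS + EXTRA_DRUGS
    names: list[str] = []
    for s, _sign, t in _LPL_EDGES:
        for n in (s, t):
            if n not in names:
                names.append(n)
    nodes = [
        NodeSpec(n, "input" if n in inputs else "output" if n in _LPL_OUTPUTS else "hidden")
        for n in names
    ]
    edges = [
        EdgeSpec(s, t, "activating" if sign == "->" else "inhibiting", f"k_{s}_{t}")
        for s, sign, t in _LPL_EDGES
    ]
    return LogicNetwork(nodes, edges)


def chain_network() -> LogicNetwork:
    """Small identifiable fixture: two stimulators, two inhibitor drugs,
    one hidden hub and three measured outputs.

    Every free parameter (two activator splits at multi-activator nodes
    beyond the hub, the hub split, and the two inhibitor weights) is
    identified by the factorial design of :func:`chain_design`.
    """
    nodes = [
        NodeSpec("S1", "input"),
        NodeSpec("S2", "input"),
        NodeSpec("D1", "input"),
        NodeSpec("D2", "input"),
        NodeSpec("M", "hidden"),
        NodeSpec("O1", "output"),
        NodeSpec("O2", "output"),
        NodeSpec("O3", "output"),
    ]
    edges = [
        EdgeSpec("S1", "M", "activating", "k_S1_M"),
        EdgeSpec("S2", "M", "activating", "k_S2_M"),
        EdgeSpec("D1", "M", "inhibiting", "k_D1_M"),
        EdgeSpec("M", "O1", "activating", "k_M_O1"),
        EdgeSpec("S1", "O2", "activating", "k_S1_O2"),
        EdgeSpec("M", "O2", "activating", "k_M_O2"),
        EdgeSpec("D2", "O2", "inhibiting", "k_D2_O2"),
        EdgeSpec("S2", "O3", "activating", "k_S2_O3"),
        EdgeSpec("M", "O3", "activating", "k_M_O3"),
    ]
    return LogicNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# Experimental designs
# ---------------------------------------------------------------------------


def paper_design(context: str) -> DesignSpec:
    """The perturbation design of the study, per cell line.

    20 conditions for BT-20, HCC38 and SKBR3; 12 for MCF7, which lacks the
    EGF and HGF receptors and therefore the EGF/HGF arms.  Enumeration:
    control, each stimulator alone, each inhibitor alone, then every
    inhibitor × stimulator pair (inhibitor pre-incubated, as in the wet
    protocol).  All drug inputs of the prior network are assigned (0 for
    drugs outside the design).
    """
    if context not in CELL_LINES:
        raise ValueError(f"unknown cell line {context!r}; expected one of {CELL_LINES}")
    stimulators = ["IGF", "PMA"] if context == "MCF7" else list(STIMULATORS)
    inhibitors = list(DESIGN_INHIBITORS)
    all_inputs = list(STIMULATORS) + list(DESIGN_INHIBITORS) + list(EXTRA_DRUGS)

    def cond(name: str, on: list[str]) -> Condition:
        return Condition(name, {n: (1.0 if n in on else 0.0) for n in all_inputs})

    conditions = [cond("control", [])]
    conditions += [cond(s, [s]) for s in stimulators]
    conditions += [cond(i, [i]) for i in inhibitors]
    conditions += [cond(f"{i}+{s}", [i, s]) for i in inhibitors for s in stimulators]
    return DesignSpec(
        stimulators=stimulators,
        inhibitors=inhibitors,
        conditions=conditions,
        n_outputs=len(_LPL_OUTPUTS),
    )


def chain_design() -> DesignSpec:
    """Full 2^4 factorial over the chain fixture's inputs (16 conditions)."""
    inputs = ["S1", "S2", "D1", "D2"]
    conditions = []
    for bits in range(16):
        on = [inputs[i] for i in range(4) if bits >> i & 1]
        name = "+".join(on) if on else "control"
        conditions.append(Condition(name, {n: (1.0 if n in on else 0.0) for n in inputs}))
    return DesignSpec(stimulators=["S1", "S2"], inhibitors=["D1", "D2"], conditions=conditions, n_outputs=3)


# ---------------------------------------------------------------------------
# Ground truth and dataset generation
# ---------------------------------------------------------------------------

MIN_ACTIVATOR_WEIGHT = 0.1
INHIBITOR_RANGE = (0.3, 0.9)
DIFF_MAGNITUDE = (0.2, 0.35)


def generate_ground_truth(
    network: LogicNetwork,
    n_context_diffs: int,
    contexts: list[str],
    seed: int,
    noise_scale: float = 0.05,
) -> GroundTruth:
    """Draw a valid random ParameterSet shared across contexts, then make
    ``n_context_diffs`` parameters context-specific.

    Activator splits are drawn uniformly on each node's simplex, resampled
    until every weight is at least 0.1 (all prior pathways carry signal);
    inhibitor weights are uniform in [0.3, 0.9] (effective but not
    saturating inhibition).  Context differences of at least 0.2 are
    applied to inhibitor-edge parameters, one context each: their box
    constraint lets a single label move without dragging sibling weights
    along, so the truth has *exactly* ``n_context_diffs`` context-specific
    labels.  Raises if the network has fewer inhibitor labels than
    ``n_context_diffs``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    compiled = CompiledNetwork(network)
    inhibitor_labels = list(compiled.inhibitor_labels)
    if n_context_diffs > len(inhibitor_labels):
        raise ValueError(
            f"cannot place {n_context_diffs} independent context differences: "
            f"network has only {len(inhibitor_labels)} inhibitor-edge labels"
        )

    base: dict[str, float] = {}
    for _node, labs in compiled.activator_labels_by_node.items():
        if len(labs) == 1:
            base[labs[0]] = 1.0
            continue
        for _ in range(200):
            w = rng.dirichlet(np.ones(len(labs)))
            if w.min() >= MIN_ACTIVATOR_WEIGHT:
                break
        else:
            raise RuntimeError("could not draw simplex weights above the floor")
        for lab, wi in zip(labs, w):
            base[lab] = float(wi)
    for lab in inhibitor_labels:
        base[lab] = float(rng.uniform(*INHIBITOR_RANGE))

    values = {(lab, ctx): base[lab] for lab in compiled.labels for ctx in contexts}

    diff_labels = list(rng.choice(inhibitor_labels, size=n_context_diffs, replace=False))
    context_diffs: list[tuple[str, str]] = []
    for lab in diff_labels:
        ctx = contexts[int(rng.integers(len(contexts)))]
        old = base[lab]
        for _ in range(100):
            delta = float(rng.uniform(*DIFF_MAGNITUDE)) * (1 if rng.random() < 0.5 else -1)
            new = old + delta
            if 0.02 <= new <= 0.98 and abs(new - old) >= DIFF_MAGNITUDE[0]:
                break
        else:
            raise RuntimeError(f"could not perturb label {lab!r} by >= 0.2 within [0, 1]")
        values[(lab, ctx)] = new
        context_diffs.append((str(lab), ctx))

    params = ParameterSet(values=values)
    return GroundTruth(
        network=network,
        params=params,
        context_diffs=context_diffs,
        noise_scale=noise_scale,
        seed=seed,
    )


def simulate_dataset(
    truth: GroundTruth,
    design: DesignSpec,
    context: str,
    seed: int | None = None,
) -> MeasurementSet:
    """Noise-free propagation of a design through the truth, plus clipped
    Gaussian noise at ``truth.noise_scale``; SEM columns carry the
    generating SD.  The default seed derives deterministically from the
    truth's seed and the context name."""
    clean = simulate_design(truth.network, truth.params, design.conditions, context)
    if seed is None:
        seed = (truth.seed * 100003 + zlib.crc32(context.encode())) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean.to_numpy(), 0.0, 1.0)  # guard float round-off at the bounds
    if truth.noise_scale > 0:
        noisy = np.clip(noisy + rng.standard_normal(noisy.shape) * truth.noise_scale, 0.0, 1.0)
    values = pd.DataFrame(noisy, index=clean.index.copy(), columns=clean.columns)
    sem = pd.DataFrame(
        np.full(values.shape, float(truth.noise_scale)),
        index=values.index.copy(),
        columns=values.columns,
    )
    return MeasurementSet(
        context=context, conditions=list(design.conditions), values=values, sem=sem
    )
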