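"""Random-order asynchronous simulation of Boolean networks.

One time step is a full sweep: a uniformly random permutation of all nodes
is drawn and the nodes are updated sequentially in that order, each update
immediately visible to the updates that follow it within the same sweep.
This captures the stochastic ordering of expression changes in real gene
regulatory networks while still touching every node once per step.

Initial states follow the study protocol: the five input signals are fixed
per experimental case, Apoptosis and the initiator/effector caspases start
OFF (so the simulation can show whether the inputs switch them on), and all
remaining nodes are drawn independently Bernoulli(1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_io import BooleanNetwork, CompiledNetwork

__all__ = [
    "InputCase",
    "Trajectory",
    "INPUT_CASES",
    "CLAMPED_FALSE_NODES",
    "INITIAL_TRUE_NODES",
    "input_case",
    "sweep_update",
    "initial_state",
    "simulate",
]

State = tuple[int, ...]

#: Nodes forced OFF at t=0 in every experiment (apoptosis read-out and the
#: caspase cascade), so that any apoptosis observed is input-driven.
CLAMPED_FALSE_NODES = ("Apoptosis", "CASP3", "CASP6", "CASP7", "CASP8", "CASP9")

#: Nodes forced ON at t=0.  Insulin (INS) is a frozen self-copy node —
#: its rule is the identity — so its initial value persists forever; the
#: modeled beta-cell scenario has insulin present (INS = INSR = 1 in every
#: reported attractor), and randomizing it would merely duplicate every
#: attractor into an artificial INS=0 twin.
INITIAL_TRUE_NODES = ("INS",)

#: The eight input-signal combinations of the study, as
#: (ER stress, oxidative stress, TNFA, FasL, IL6).
INPUT_CASES: dict[int, dict[str, int]] = {
    1: {"ER": 1, "OS": 0, "TNFA": 0, "FasL": 0, "IL6": 0},
    2: {"ER": 0, "OS": 1, "TNFA": 0, "FasL": 0, "IL6": 0},
    3: {"ER": 1, "OS": 1, "TNFA": 0, "FasL": 0, "IL6": 0},
    4: {"ER": 0, "OS": 0, "TNFA": 1, "FasL": 0, "IL6": 0},
    5: {"ER": 0, "OS": 0, "TNFA": 0, "FasL": 1, "IL6": 0},
    6: {"ER": 0, "OS": 0, "TNFA": 0, "FasL": 0, "IL6": 1},
    7: {"ER": 0, "OS": 0, "TNFA": 1, "FasL": 1, "IL6": 1},
    8: {"ER": 1, "OS": 1, "TNFA": 1, "FasL": 1, "IL6": 1},
}


@dataclass(frozen=True)
class InputCase:
    """An input-signal assignment; ``case_id`` 0 denotes a custom case."""

    case_id: int
    signal_values: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.case_id and self.case_id in INPUT_CASES:
            if dict(self.signal_values) != INPUT_CASES[self.case_id]:
                raise ValueError(
                    f"case {self.case_id} signal values do not match the "
                    "study definition"
                )


def input_case(case: "int | InputCase | Mapping[str, int]") -> InputCase:
    """Coerce a case id, mapping, or :class:`InputCase` to an InputCase."""
    if isinstance(case, InputCase):
        return case
    if isinstance(case, int):
        if case not in INPUT_CASES:
            raise ValueError(f"unknown case id {case}; valid ids are 1-8")
        return InputCase(case_id=case, signal_values=dict(INPUT_CASES[case]))
    return InputCase(case_id=0, signal_values={k: int(v) for k, v in dict(case).items()})


@dataclass
class Trajectory:
    """States visited by one seeded run; ``states[0]`` is the initial state."""

    states: list[State]
    seed: int | None
    case_id: int

    def __len__(self) -> int:
        return len(self.states)


def sweep_update(
    network: BooleanNetwork | CompiledNetwork,
    state: Sequence[int],
    permutation: Sequence[int | str],
) -> State:
    """Apply one full asynchronous sweep in the given node order.

    ``permutation`` may contain node indices or node names but must cover
    every node exactly once.  Each node's new value is computed from the
    current working state, so earlier updates in the sweep feed later ones.
    """
    compiled = network.compiled() if isinstance(network, BooleanNetwork) else network
    n = len(compiled.nodes)
    idx_of = {name: i for i, name in enumerate(compiled.nodes)}
    order = [p if isinstance(p, (int, np.integer)) else idx_of[p] for p in permutation]
    if sorted(order) != list(range(n)):
        raise ValueError("permutation must cover every node exactly once")
    if len(state) != n:
        raise ValueError("state length does not match node count")
    work = [1 if v else 0 for v in state]
    for i in order:
        work[i] = compiled.update_node(work, i)
    return tuple(work)


def initial_state(
    case: "int | InputCase | Mapping[str, int]",
    network: BooleanNetwork,
    rng: np.random.Generator,
) -> State:
    """Draw an initial state for one run of the given case.

    Input signals take the case's values; nodes with constant rules take
    their constants; Apoptosis and caspases 3/6/7/8/9 start OFF; the
    frozen insulin node starts ON (insulin is present in the modeled
    scenario); every other node is an independent fair coin flip.  For the
    numbered study cases the signal and clamped nodes are required to
    exist.
    """
    case = input_case(case)
    node_set = set(network.nodes)
    for signal in case.signal_values:
        if signal not in node_set:
            raise KeyError(f"signal node {signal!r} absent from network")
    if case.case_id:
        missing = [n for n in CLAMPED_FALSE_NODES if n not in node_set]
        if missing:
            raise KeyError(f"required node(s) {missing} absent from network")

    bits = rng.integers(0, 2, size=network.n_nodes)
    state = [int(b) for b in bits]
    for i, name in enumerate(network.nodes):
        rule = network.rules[name]
        if rule.constant is not None:
            state[i] = rule.constant
        elif name in case.signal_values:
            state[i] = int(case.signal_values[name])
        elif name in CLAMPED_FALSE_NODES:
            state[i] = 0
        elif name in INITIAL_TRUE_NODES:
            state[i] = 1
    return tuple(state)


def simulate(
    network: BooleanNetwork,
    case: "int | InputCase | Mapping[str, int]",
    steps: int,
    seed: "int | np.random.SeedSequence | None" = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run one random-order asynchronous trajectory of ``steps`` sweeps.

    The same seed yields a bitwise-identical trajectory.  The returned
    trajectory has ``steps + 1`` states (initial state included).
    """
    if steps < 0:
        raise ValueError("steps must be non-negative")
    case = input_case(case)
    if rng is None:
        rng = np.random.default_rng(seed)
    compiled = network.compiled()
    n = len(compiled.nodes)
    state = list(initial_state(case, network, rng))
    states: list[State] = [tuple(state)]
    acts = compiled.activators
    inhs = compiled.inhibitors
    consts = compiled.constants
    has_act = compiled.has_activators
    for _ in range(steps):
        for i in rng.permutation(n).tolist():
            c = consts[i]
            if c is not None:
                state[i] = c
                continue
            if has_act[i]:
                v = 0
                for j in acts[i]:
                    if state[j]:
                        v = 1
                        break
            else:
                v = 1
            if v:
                for j in inhs[i]:
                    if state[j]:
                        v = 0
                        break
            state[i] = v
        states.append(tuple(state))
    seed_val = seed if isinstance(seed, int) else None
    return Trajectory(states=states, seed=seed_val, case_id=case.case_id)
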