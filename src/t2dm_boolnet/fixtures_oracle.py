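"""Small fixture networks and an exact brute-force attractor oracle.

For a network with n nodes (n <= 8) the exact state-transition graph under
random-order asynchronous semantics is enumerable: from each of the 2^n
states, apply one full sweep for every one of the n! node orderings and
record the deduplicated successor set.  The terminal SCCs of this exact
graph are the true attractors of the update scheme, against which the
sampled pipeline can be checked on toy models.

The shipped fixtures cover the behaviours the pipeline must get right:
a toggle switch (two fixed points), a three-gene cascade (two fixed
points), the four-gene positive feedback loop behind the model's paired
ON/OFF attractors (GADD34 -> EIF2S1 -> ATF4 -> CHOP -> GADD34, with the
upstream sensors held FALSE), and a five-node negative-feedback ring with
no fixed point, whose single cyclic attractor exercises fractional
expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import permutations, product

import networkx as nx
import numpy as np

from .model_io import BooleanNetwork, BooleanRule, parse_network
from .sim_engine import sweep_update

__all__ = [
    "ExactSTG",
    "exact_stg",
    "exact_attractors",
    "random_toy_network",
    "load_fixture",
    "FIXTURE_NAMES",
    "toggle_switch",
    "three_gene_cascade",
    "chop_feedback_loop",
    "five_node_oscillator",
]

State = tuple[int, ...]

MAX_ORACLE_NODES = 8

FIXTURE_NAMES = (
    "toggle_switch",
    "three_gene_cascade",
    "chop_loop",
    "five_node_oscillator",
)


@dataclass
class ExactSTG:
    """Exhaustive transition relation under all node permutations."""

    graph: nx.DiGraph
    node_names: tuple[str, ...]

    @property
    def states(self) -> set[State]:
        return set(self.graph.nodes)

    def terminal_sccs(self) -> list[frozenset]:
        cond = nx.condensation(self.graph)
        out = []
        for comp_id in cond.nodes:
            if cond.out_degree(comp_id) == 0:
                out.append(frozenset(cond.nodes[comp_id]["members"]))
        return sorted(out, key=lambda c: min(c))


def exact_stg(network: BooleanNetwork) -> ExactSTG:
    """Enumerate every one-sweep transition of a small network."""
    n = network.n_nodes
    if n > MAX_ORACLE_NODES:
        raise ValueError(
            f"exact oracle limited to {MAX_ORACLE_NODES} nodes (got {n})"
        )
    compiled = network.compiled()
    graph = nx.DiGraph()
    all_perms = list(permutations(range(n)))
    for bits in product((0, 1), repeat=n):
        graph.add_node(bits)
        for perm in all_perms:
            graph.add_edge(bits, sweep_update(compiled, bits, perm))
    return ExactSTG(graph=graph, node_names=network.nodes)


def exact_attractors(network: BooleanNetwork) -> list[frozenset]:
    """Terminal SCCs of the exact graph: the true attractors."""
    return exact_stg(network).terminal_sccs()


def random_toy_network(
    n: int,
    mean_degree: float = 1.5,
    rng: np.random.Generator | None = None,
) -> BooleanNetwork:
    """A seeded random activator/inhibitor network in canonical form.

    Each node receives between 1 and n regulators (binomial around
    ``mean_degree``), sampled without replacement, each an activator or an
    inhibitor with equal probability.  The result always serializes and
    re-parses via the model-io round trip.
    """
    if not 2 <= n <= MAX_ORACLE_NODES:
        raise ValueError(f"n must be in [2, {MAX_ORACLE_NODES}]")
    if rng is None:
        rng = np.random.default_rng()
    names = tuple(f"g{i}" for i in range(1, n + 1))
    p = min(max(mean_degree / n, 0.0), 1.0)
    rules = {}
    for name in names:
        k = int(np.clip(rng.binomial(n, p), 1, n))
        regulators = [names[i] for i in rng.choice(n, size=k, replace=False)]
        roles = rng.integers(0, 2, size=k)
        rules[name] = BooleanRule(
            target=name,
            activators=frozenset(r for r, a in zip(regulators, roles) if a),
            inhibitors=frozenset(r for r, a in zip(regulators, roles) if not a),
        )
    return BooleanNetwork(nodes=names, rules=rules)


def load_fixture(name: str) -> BooleanNetwork:
    """Load one of the shipped fixture networks by file stem."""
    text = (
        resources.files("t2dm_boolnet.data")
        .joinpath(f"fixtures/{name}.rules")
        .read_text(encoding="utf-8")
    )
    return parse_network(text)


def toggle_switch() -> BooleanNetwork:
    """Mutual repression: attractors are the two opposite fixed points."""
    return load_fixture("toggle_switch")


def three_gene_cascade() -> BooleanNetwork:
    """The worked three-gene example: g1 = g3, g2 = g1 or g3, g3 = g2."""
    return load_fixture("three_gene_cascade")


def chop_feedback_loop() -> BooleanNetwork:
    """The GADD34/EIF2S1/ATF4/CHOP positive loop with sensors held FALSE.

    PERK and ATF6 appear only as undefined references (constant FALSE), as
    in the full model's paired-attractor regime; the loop is bistable with
    all-ON and all-OFF attractors.
    """
    return load_fixture("chop_loop")


def five_node_oscillator() -> BooleanNetwork:
    """Negative-feedback ring with two reporter nodes; no fixed point."""
    return load_fixture("five_node_oscillator")
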