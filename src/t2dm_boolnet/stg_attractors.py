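"""Sampled state-transition graphs, SCCs, attractors and expression levels.

The sampled state-transition graph (STG) is the union over all runs of a
case: one vertex per distinct visited state, one edge per observed
consecutive pair, and a visit count per state pooled across runs.
Attractors are the terminal strongly connected components of this graph —
components with no edge leaving them — that are additionally closed under
the sampled dynamics (every member state has an observed successor; this
excludes the spurious "terminal" singleton formed by a trajectory that ends
mid-transient).

Within an attractor the probability of state S_i is its visit count divided
by the total count over the component, and the expression level of gene g
is the probability-weighted fraction of attractor states with g ON:
``Exp(g) = sum of P(S_j) over states S_j where g = 1``.  Levels therefore
lie in [0, 1]; a level of 1 (0) means the gene is ON (OFF) in every
attractor state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .sim_engine import Trajectory

__all__ = [
    "StateGraph",
    "Attractor",
    "build_stg",
    "strongly_connected_components",
    "attractors",
    "expression_levels",
    "attractor_table",
    "write_graphml",
    "write_dot",
]

State = tuple[int, ...]


@dataclass
class StateGraph:
    """Directed graph over observed states with pooled visit counts."""

    graph: nx.DiGraph
    visit_counts: dict[State, int]
    node_names: tuple[str, ...]

    @property
    def vertices(self) -> set[State]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[State, State]]:
        return set(self.graph.edges)


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC with state probabilities and expression levels.

    ``label`` is the lexicographically smallest member bit-string, giving a
    deterministic identity for reports and cross-run matching.
    """

    states: frozenset[State]
    probabilities: Mapping[State, float]
    expression: Mapping[str, float]
    label: str

    @property
    def size(self) -> int:
        return len(self.states)

    def is_fixed_point(self) -> bool:
        return len(self.states) == 1


def _state_str(state: State) -> str:
    return "".join("1" if b else "0" for b in state)


def build_stg(trajectories: Iterable[Trajectory], node_names: Sequence[str]) -> StateGraph:
    """Union the trajectories of one case into a sampled STG."""
    graph = nx.DiGraph()
    counts: dict[State, int] = {}
    n = len(node_names)
    for traj in trajectories:
        for state in traj.states:
            if len(state) != n:
                raise ValueError("trajectory state length does not match node names")
            counts[state] = counts.get(state, 0) + 1
        graph.add_nodes_from(traj.states)
        graph.add_edges_from(zip(traj.states[:-1], traj.states[1:]))
    return StateGraph(graph=graph, visit_counts=counts, node_names=tuple(node_names))


def strongly_connected_components(graph: "StateGraph | nx.DiGraph") -> list[set]:
    """Maximal SCC partition (singletons without self-loops included)."""
    g = graph.graph if isinstance(graph, StateGraph) else graph
    return [set(c) for c in nx.strongly_connected_components(g)]


def _terminal_closed_sccs(g: nx.DiGraph) -> list[set]:
    """Terminal SCCs closed under the sampled dynamics.

    Each finite trajectory is truncated, so its last state may dangle off
    the recurrent region it belongs to without an observed successor.
    Such dead ends (and anything that only led to them) cannot be part of
    a closed recurrent set and are peeled off iteratively; the attractors
    are the terminal SCCs of what remains.
    """
    g = g.copy()
    while True:
        dead = [u for u in g.nodes if g.out_degree(u) == 0]
        if not dead:
            break
        g.remove_nodes_from(dead)
    out = []
    for comp in nx.strongly_connected_components(g):
        comp = set(comp)
        if any(v not in comp for u in comp for v in g.successors(u)):
            continue
        out.append(comp)
    return out


def attractors(stg: StateGraph) -> list[Attractor]:
    """Extract attractors (terminal, dynamics-closed SCCs) from a sampled STG.

    Returned attractors are ordered by their canonical label.
    """
    result = []
    for comp in _terminal_closed_sccs(stg.graph):
        states = sorted(comp)
        counts = np.array([stg.visit_counts[s] for s in states], dtype=np.int64)
        total = int(counts.sum())
        probs = {s: c / total for s, c in zip(states, counts.tolist())}
        # integer accumulation keeps levels exact: a gene ON in every
        # state gets exactly 1.0, never 1 - eps
        mat = np.array(states, dtype=np.int64)
        levels = (counts @ mat) / total
        expr = {name: float(levels[i]) for i, name in enumerate(stg.node_names)}
        label = min(_state_str(s) for s in comp)
        result.append(
            Attractor(
                states=frozenset(comp),
                probabilities=probs,
                expression=expr,
                label=label,
            )
        )
    return sorted(result, key=lambda a: a.label)


def expression_levels(attractor: Attractor) -> dict[str, float]:
    """Per-gene expression levels of an attractor (probability mass on ON)."""
    return dict(attractor.expression)


def attractor_table(attrs: Sequence[Attractor], node_names: Sequence[str]) -> pd.DataFrame:
    """Expression levels as a nodes x attractors table (columns A1, A2, ...)."""
    data = {
        f"A{i + 1}": [attr.expression[n] for n in node_names]
        for i, attr in enumerate(attrs)
    }
    return pd.DataFrame(data, index=list(node_names))


def _annotated_graph(stg: StateGraph, attrs: Sequence[Attractor]) -> nx.DiGraph:
    member = {}
    for i, attr in enumerate(attrs):
        for s in attr.states:
            member[s] = i + 1
    g = nx.DiGraph()
    for s in stg.graph.nodes:
        g.add_node(
            _state_str(s),
            count=stg.visit_counts[s],
            attractor=member.get(s, 0),
        )
    for u, v in stg.graph.edges:
        g.add_edge(_state_str(u), _state_str(v))
    return g


def write_graphml(stg: StateGraph, path, attrs: Sequence[Attractor] = ()) -> None:
    """Export the STG to GraphML with visit-count and attractor attributes."""
    nx.write_graphml(_annotated_graph(stg, attrs), path)


def write_dot(stg: StateGraph, path, attrs: Sequence[Attractor] = ()) -> None:
    """Export the STG to Graphviz DOT (attractor states filled red)."""
    g = _annotated_graph(stg, attrs)
    lines = ["digraph stg {", "  node [shape=box, fontsize=8];"]
    for node, data in g.nodes(data=True):
        color = ' style=filled fillcolor="red"' if data["attractor"] else ""
        lines.append(f'  "{node}" [label="{node}\\n{data["count"]}"{color}];')
    lines.extend(f'  "{u}" -> "{v}";' for u, v in g.edges)
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
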