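"""End-to-end input-signal case experiments and virtual perturbations.

A case experiment runs many seeded random-order asynchronous trajectories
under one input-signal combination, pools them into a sampled
state-transition graph, and reports the attractors with their expression
levels.  Per-run seeds derive deterministically from the experiment seed
and the case id, so cases are independent but jointly reproducible, and an
identical (network, case, runs, steps, seed) tuple always yields an
identical result.

Virtual knockouts clamp a gene's rule to constant 0 (loss of function);
overexpression clamps to constant 1.  Clamped genes are also pinned at
their clamped value in the initial state rather than randomized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model_io import BooleanNetwork, BooleanRule
from .sim_engine import InputCase, Trajectory, input_case, simulate
from .stg_attractors import Attractor, StateGraph, attractor_table, attractors, build_stg
from .validation_metrics import discretize

__all__ = [
    "CaseResult",
    "run_case",
    "run_all_cases",
    "knockout",
    "overexpress",
]


@dataclass
class CaseResult:
    """Attractor-level outcome of one case experiment."""

    case_id: int
    n_runs: int
    n_steps: int
    seed: int
    attractors: list[Attractor]
    state_graph: StateGraph

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    @property
    def apoptosis_on(self) -> int:
        """Number of attractors whose Apoptosis level exceeds 0.50."""
        return sum(
            discretize(a.expression["Apoptosis"])
            for a in self.attractors
            if "Apoptosis" in a.expression
        )

    def to_frame(self):
        net_nodes = self.state_graph.node_names
        return attractor_table(self.attractors, net_nodes)

    def summary(self) -> dict:
        return {
            "case": self.case_id,
            "n_runs": self.n_runs,
            "n_steps": self.n_steps,
            "seed": self.seed,
            "n_attractors": self.n_attractors,
            "apoptosis_on_count": self.apoptosis_on,
            "attractor_sizes": [a.size for a in self.attractors],
        }

    def write_summary(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)


def _case_seed_sequence(seed: int, case_id: int) -> np.random.SeedSequence:
    # Mixing the case id into the entropy gives each case its own stream
    # while keeping the whole experiment reproducible from one integer.
    return np.random.SeedSequence(entropy=[int(seed), int(case_id) & 0x7FFFFFFF])


def run_case(
    network: BooleanNetwork,
    case: "int | InputCase | Mapping[str, int]",
    n_runs: int,
    n_steps: int,
    seed: int,
) -> CaseResult:
    """Simulate one case and extract its attractors.

    Runs ``n_runs`` trajectories of ``n_steps`` sweeps each with per-run
    seeds spawned from ``(seed, case_id)``, pools them into the union STG,
    and returns the terminal-SCC attractors with expression levels.
    """
    if n_runs < 1 or n_steps < 1:
        raise ValueError("n_runs and n_steps must be >= 1")
    case = input_case(case)
    ss = _case_seed_sequence(seed, case.case_id)
    trajectories: list[Trajectory] = []
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        trajectories.append(simulate(network, case, n_steps, rng=rng))
    stg = build_stg(trajectories, network.nodes)
    return CaseResult(
        case_id=case.case_id,
        n_runs=n_runs,
        n_steps=n_steps,
        seed=seed,
        attractors=attractors(stg),
        state_graph=stg,
    )


def run_all_cases(
    network: BooleanNetwork,
    n_runs: int,
    n_steps: int,
    seed: int,
    cases: Sequence[int] = tuple(range(1, 9)),
) -> list[CaseResult]:
    """Run every study case with independent per-case seed streams."""
    return [run_case(network, c, n_runs, n_steps, seed) for c in cases]


def _clamp(network: BooleanNetwork, genes: Iterable[str], value: int) -> BooleanNetwork:
    genes = list(genes)
    for g in genes:
        if g not in network.rules:
            raise KeyError(f"unknown gene {g!r}")
        if g == "Apoptosis":
            raise ValueError("the Apoptosis read-out node cannot be perturbed")
    net = network
    for g in genes:
        net = net.with_rule(
            BooleanRule(
                target=g,
                activators=frozenset(),
                inhibitors=frozenset(),
                raw_expression=str(value),
                constant=value,
            )
        )
    return net


def knockout(network: BooleanNetwork, genes: Iterable[str]) -> BooleanNetwork:
    """Clamp each listed gene to constant 0 (virtual loss of function)."""
    return _clamp(network, genes, 0)


def overexpress(network: BooleanNetwork, genes: Iterable[str]) -> BooleanNetwork:
    """Clamp each listed gene to constant 1 (virtual overexpression)."""
    return _clamp(network, genes, 1)
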