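"""Literature validation metrics and random-network comparison.

Attractor expression levels in [0, 1] are discretized with a strict 0.50
threshold (a gene is called expressed only when its level exceeds 0.50).
Discretized calls are compared against a user-supplied truth table of
literature expectations, yielding the four confusion counts and
precision, recall (sensitivity), specificity and F1:

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

Ratios with a zero denominator are reported as NaN with an explicit
warning, never silently as 0.

The random-network comparison resamples each non-input node's regulators
uniformly (preserving its in-degree, with activator/inhibitor roles drawn
by fair coin) and reruns the identical simulation protocol, to show that
the curated model's handful of attractors is far below the attractor count
of degree-matched random Boolean networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_io import BooleanNetwork, BooleanRule

__all__ = [
    "MetricsReport",
    "discretize",
    "confusion_and_metrics",
    "f1_score",
    "pooled_metrics",
    "macro_average_metrics",
    "read_truth_table",
    "random_network_like",
    "compare_attractor_counts",
]


def discretize(level: float) -> int:
    """1 if the expression level strictly exceeds 0.50, else 0."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"expression level {level!r} outside [0, 1]")
    return 1 if level > 0.50 else 0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four derived validation metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    specificity: float
    f1: float

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def confusion_and_metrics(
    predicted: Mapping[str, int], truth: Mapping[str, int]
) -> MetricsReport:
    """Score discretized predictions against a literature truth table.

    Evaluation is restricted to the genes of ``truth``; each of them must
    have a prediction.
    """
    if not truth:
        raise ValueError("truth table is empty")
    tp = tn = fp = fn = 0
    for gene, expected in truth.items():
        if gene not in predicted:
            raise KeyError(f"no prediction for truth-table gene {gene!r}")
        pred = 1 if predicted[gene] else 0
        exp = 1 if expected else 0
        if pred and exp:
            tp += 1
        elif pred and not exp:
            fp += 1
        elif not pred and exp:
            fn += 1
        else:
            tn += 1
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    return MetricsReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1_score(precision, recall),
    )


def pooled_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Combine per-case reports by summing confusion counts, then derive
    the metrics from the pooled counts (micro averaging)."""
    if not reports:
        raise ValueError("no reports to pool")
    tp = sum(r.tp for r in reports)
    tn = sum(r.tn for r in reports)
    fp = sum(r.fp for r in reports)
    fn = sum(r.fn for r in reports)
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        precision=precision, recall=recall, specificity=specificity,
        f1=f1_score(precision, recall),
    )


def macro_average_metrics(reports: Sequence[MetricsReport]) -> dict[str, float]:
    """Average each metric over per-case reports (macro averaging).

    NaN entries (undefined ratios) propagate rather than being silently
    dropped, so an undefined per-case metric is visible in the average.
    """
    if not reports:
        raise ValueError("no reports to average")
    n = len(reports)
    return {
        "precision": sum(r.precision for r in reports) / n,
        "recall": sum(r.recall for r in reports) / n,
        "specificity": sum(r.specificity for r in reports) / n,
        "f1": sum(r.f1 for r in reports) / n,
    }


def read_truth_table(path) -> dict[str, int]:
    """Read a ``gene,expected,source_citation`` CSV into a truth mapping."""
    df = pd.read_csv(path, comment="#")
    if "gene" not in df.columns or "expected" not in df.columns:
        raise ValueError("truth table needs 'gene' and 'expected' columns")
    return {str(g): int(e) for g, e in zip(df["gene"], df["expected"])}


def random_network_like(
    template: BooleanNetwork, rng: np.random.Generator
) -> BooleanNetwork:
    """Degree-preserving random rewiring of a template network.

    Each non-input node keeps its in-degree but its regulators are
    resampled uniformly without replacement from the non-input nodes, and
    each sampled regulator is an activator or an inhibitor with equal
    probability.  Input nodes keep their original rules, so the rewired
    network runs under the same experimental protocol as the template.
    """
    pool = [n for n in template.nodes if n not in template.input_nodes]
    rules = dict(template.rules)
    for name in template.nodes:
        if name in template.input_nodes:
            continue
        rule = template.rules[name]
        if rule.constant is not None:
            continue
        k = min(len(rule.activators) + len(rule.inhibitors), len(pool))
        regulators = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        roles = rng.integers(0, 2, size=k)
        activators = frozenset(r for r, a in zip(regulators, roles) if a)
        inhibitors = frozenset(r for r, a in zip(regulators, roles) if not a)
        rules[name] = BooleanRule(
            target=name,
            activators=activators,
            inhibitors=inhibitors,
            raw_expression="",
        )
    return BooleanNetwork(
        nodes=template.nodes,
        rules=rules,
        input_nodes=template.input_nodes,
        undefined_refs=frozenset(),
    )


def compare_attractor_counts(
    template: BooleanNetwork,
    n_random: int,
    case,
    n_runs: int,
    n_steps: int,
    seed: int,
) -> tuple[int, list[int]]:
    """Attractor counts of the template and of rewired random networks.

    Every network (template and randoms) is simulated under the identical
    protocol.  Returns ``(template_count, [random counts...])``.
    """
    from .case_experiments import run_case

    if n_random < 0:
        raise ValueError("n_random must be >= 0")
    template_count = run_case(template, case, n_runs, n_steps, seed).n_attractors
    counts = []
    ss = np.random.SeedSequence(entropy=[int(seed), 0x52414E44])
    for child in ss.spawn(n_random):
        rng = np.random.default_rng(child)
        net = random_network_like(template, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        counts.append(run_case(net, case, n_runs, n_steps, sub_seed).n_attractors)
    return template_count, counts
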