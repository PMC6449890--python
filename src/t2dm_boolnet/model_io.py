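"""Parsing, validation and serialization of Boolean network models.

A network is a set of named nodes, each carrying one Boolean update rule.
Rules follow the activator/inhibitor canonical form used throughout the
model: a node switches ON when at least one of its activating regulators is
ON (a rule with no activators places no such requirement) and every one of
its inhibiting regulators is OFF.  Rule files are plain text in a
BoolNet-flavored dialect, one ``name = expression`` assignment per line with
``#`` comments.  Two quirks of the printed source model are accepted: two
parenthesized terms may be adjacent with no operator between them (read as
AND), and mixed ``and``/``or`` expressions are normalized to the canonical
(OR over activators) AND (NOT each inhibitor) form.

The bundled 72-node type-2-diabetes model (insulin resistance integrated
with beta-cell apoptosis, five input signals) ships as package data and is
loaded with :func:`load_t2dm_model`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "BooleanRule",
    "BooleanNetwork",
    "RuleParseError",
    "canonicalize_name",
    "parse_network",
    "evaluate_rule",
    "write_network",
    "load_t2dm_model",
    "T2DM_INPUT_SIGNALS",
    "T2DM_CONSTANT_FALSE",
]

#: The five environmental input signals of the bundled T2DM model.
T2DM_INPUT_SIGNALS = ("ER", "OS", "TNFA", "FasL", "IL6")

#: Referenced in rules of the bundled model but given no update function;
#: they evaluate as constant FALSE.
T2DM_CONSTANT_FALSE = frozenset({"P53", "GADD45", "CASP12"})


class RuleParseError(ValueError):
    """Raised when a rule file cannot be parsed into a valid network."""


def _load_name_map() -> dict[str, str]:
    text = (
        resources.files("t2dm_boolnet.data")
        .joinpath("canonical_names.yaml")
        .read_text(encoding="utf-8")
    )
    data = yaml.safe_load(text)
    return {str(k): str(v) for k, v in data.items()}


_NAME_MAP = _load_name_map()
# Longest spelling first so e.g. "Cytochrome c" wins over bare "Cytochrome";
# boundaries stop a spelling from matching inside a longer identifier.
_NAME_PATTERN = re.compile(
    "(?<![A-Za-z0-9_])("
    + "|".join(re.escape(k) for k in sorted(_NAME_MAP, key=len, reverse=True))
    + ")(?![A-Za-z0-9_])"
)


def canonicalize_name(name: str) -> str:
    """Map a printed node spelling to its canonical ASCII identifier."""
    out = _NAME_PATTERN.sub(lambda m: _NAME_MAP[m.group(1)], name)
    return " ".join(out.split())


@dataclass(frozen=True)
class BooleanRule:
    """One update function in activator/inhibitor canonical form.

    ``value = (OR over activators) AND (AND over NOT inhibitor)``, where an
    empty activator set contributes TRUE (a pure-inhibition rule) and an
    empty inhibitor set contributes TRUE.  ``constant`` overrides the form
    entirely (used for knockouts/overexpression and for explicit ``0``/``1``
    rules).  ``raw_expression`` preserves the text as printed in the source
    file for provenance.
    """

    target: str
    activators: frozenset[str]
    inhibitors: frozenset[str]
    raw_expression: str = ""
    constant: int | None = None

    def __post_init__(self) -> None:
        overlap = self.activators & self.inhibitors
        if overlap:
            raise RuleParseError(
                f"{self.target}: {sorted(overlap)} appear as both activator "
                "and inhibitor"
            )

    def referenced(self) -> frozenset[str]:
        return self.activators | self.inhibitors


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered collection of nodes with one rule each.

    ``input_nodes`` are the designated external signals; ``undefined_refs``
    are names referenced by some rule but carrying no rule themselves, which
    evaluate as constant FALSE.
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, BooleanRule]
    input_nodes: frozenset[str] = frozenset()
    undefined_refs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.nodes) != set(self.rules):
            raise RuleParseError("nodes and rules must cover the same names")
        if len(set(self.nodes)) != len(self.nodes):
            raise RuleParseError("duplicate node names")
        if not self.input_nodes <= set(self.nodes):
            raise RuleParseError("input_nodes must be a subset of nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        return self.nodes.index(name)

    def with_rule(self, rule: BooleanRule) -> "BooleanNetwork":
        if rule.target not in self.rules:
            raise KeyError(rule.target)
        rules = dict(self.rules)
        rules[rule.target] = rule
        return replace(self, rules=rules)

    def compiled(self) -> "CompiledNetwork":
        return CompiledNetwork.from_network(self)


@dataclass(frozen=True)
class CompiledNetwork:
    """Index-based form of a network for fast repeated evaluation.

    Regulators that are undefined references are dropped at compile time:
    a constant-FALSE activator can never fire and a constant-FALSE inhibitor
    never vetoes.
    """

    nodes: tuple[str, ...]
    activators: tuple[tuple[int, ...], ...]
    inhibitors: tuple[tuple[int, ...], ...]
    constants: tuple[int | None, ...]
    has_activators: tuple[bool, ...]

    @classmethod
    def from_network(cls, network: BooleanNetwork) -> "CompiledNetwork":
        idx = {name: i for i, name in enumerate(network.nodes)}
        acts, inhs, consts, has_act = [], [], [], []
        for name in network.nodes:
            rule = network.rules[name]
            acts.append(tuple(idx[a] for a in sorted(rule.activators) if a in idx))
            inhs.append(tuple(idx[h] for h in sorted(rule.inhibitors) if h in idx))
            consts.append(rule.constant)
            # An activator set that is nonempty but entirely undefined can
            # never fire, so the node is effectively constant FALSE.
            if rule.constant is not None:
                has_act.append(False)
            elif rule.activators and not acts[-1]:
                consts[-1] = 0
                has_act.append(False)
            else:
                has_act.append(bool(acts[-1]))
        return cls(
            nodes=network.nodes,
            activators=tuple(acts),
            inhibitors=tuple(inhs),
            constants=tuple(consts),
            has_activators=tuple(has_act),
        )

    def update_node(self, state: list[int], i: int) -> int:
        c = self.constants[i]
        if c is not None:
            return c
        if self.has_activators[i]:
            v = 0
            for j in self.activators[i]:
                if state[j]:
                    v = 1
                    break
        else:
            v = 1
        if v:
            for j in self.inhibitors[i]:
                if state[j]:
                    v = 0
                    break
        return v


_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z0-9_./-]+")
_CONST_TRUE = {"1", "true"}
_CONST_FALSE = {"0", "false"}


def _tokenize(expression: str) -> list[str]:
    canonical = _NAME_PATTERN.sub(lambda m: _NAME_MAP[m.group(1)], expression)
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(canonical):
        if canonical[pos : m.start()].strip():
            raise RuleParseError(
                f"unparseable token {canonical[pos:m.start()].strip()!r} "
                f"in {expression!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    if canonical[pos:].strip():
        raise RuleParseError(
            f"unparseable token {canonical[pos:].strip()!r} in {expression!r}"
        )
    return tokens


def _parse_rule(target: str, expression: str) -> BooleanRule:
    """Normalize one printed expression to canonical form.

    Every plain name occurrence becomes an activator and every negated name
    an inhibitor; ``and``/``or`` structure and operator omissions are
    flattened away, per the model's stated construction convention.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise RuleParseError(f"{target}: empty expression")
    lowered = [t.lower() for t in tokens]
    if len(tokens) == 1 and lowered[0] in _CONST_TRUE | _CONST_FALSE:
        return BooleanRule(
            target=target,
            activators=frozenset(),
            inhibitors=frozenset(),
            raw_expression=expression.strip(),
            constant=1 if lowered[0] in _CONST_TRUE else 0,
        )

    activators: set[str] = set()
    inhibitors: set[str] = set()
    depth = 0
    i = 0
    while i < len(tokens):
        tok, low = tokens[i], lowered[i]
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise RuleParseError(f"{target}: unbalanced ')' in {expression!r}")
        elif low in ("and", "or"):
            pass
        elif low == "not":
            j = i + 1
            if j < len(tokens) and tokens[j] == "(":
                depth += 1
                j += 1
            if j >= len(tokens) or not _is_name(tokens[j]):
                raise RuleParseError(
                    f"{target}: 'not' must be followed by a node name "
                    f"in {expression!r}"
                )
            inhibitors.add(tokens[j])
            i = j
        elif _is_name(tok):
            activators.add(tok)
        else:
            raise RuleParseError(f"{target}: unparseable token {tok!r}")
        i += 1
    if depth != 0:
        raise RuleParseError(f"{target}: unbalanced '(' in {expression!r}")
    if not activators and not inhibitors:
        raise RuleParseError(f"{target}: expression references no nodes")
    return BooleanRule(
        target=target,
        activators=frozenset(activators),
        inhibitors=frozenset(inhibitors),
        raw_expression=expression.strip(),
    )


def _is_name(token: str) -> bool:
    return token not in ("(", ")") and token.lower() not in ("and", "or", "not")


def parse_network(
    rule_text: str,
    input_nodes: Iterable[str] | None = None,
) -> BooleanNetwork:
    """Parse a rule file into a canonicalized :class:`BooleanNetwork`.

    Parameters
    ----------
    rule_text
        One ``name = expression`` assignment per line; ``#`` starts a
        comment.  A comment line ``# inputs: a, b, c`` declares the input
        signals.
    input_nodes
        Explicit input signal names (canonicalized); overrides any
        ``# inputs:`` directive.  If neither is given, nodes whose rule is a
        pure self-copy are taken as inputs.

    Names referenced by some rule but never assigned are collected into
    ``undefined_refs`` (they evaluate as constant FALSE), not treated as
    errors.
    """
    declared_inputs: list[str] | None = None
    order: list[str] = []
    rules: dict[str, BooleanRule] = {}
    for lineno, raw_line in enumerate(rule_text.splitlines(), start=1):
        line = raw_line
        if "#" in line:
            comment = line[line.index("#") + 1 :].strip()
            m = re.match(r"inputs\s*:\s*(.*)", comment, flags=re.IGNORECASE)
            if m:
                declared_inputs = [
                    canonicalize_name(p.strip())
                    for p in m.group(1).split(",")
                    if p.strip()
                ]
            line = line[: line.index("#")]
        if not line.strip():
            continue
        if "=" not in line:
            raise RuleParseError(f"line {lineno}: expected 'name = expression'")
        lhs, rhs = line.split("=", 1)
        target = canonicalize_name(lhs.strip())
        if not target:
            raise RuleParseError(f"line {lineno}: empty node name")
        if target in rules:
            raise RuleParseError(f"line {lineno}: duplicate rule for {target!r}")
        rules[target] = _parse_rule(target, rhs)
        order.append(target)

    referenced = set().union(*(r.referenced() for r in rules.values())) if rules else set()
    undefined = frozenset(referenced - set(order))

    if input_nodes is not None:
        inputs = frozenset(canonicalize_name(n) for n in input_nodes)
    elif declared_inputs is not None:
        inputs = frozenset(declared_inputs)
    else:
        inputs = frozenset(
            n
            for n, r in rules.items()
            if r.constant is None
            and r.activators == frozenset({n})
            and not r.inhibitors
        )
    missing = inputs - set(order)
    if missing:
        raise RuleParseError(f"declared input(s) {sorted(missing)} have no rule")

    return BooleanNetwork(
        nodes=tuple(order),
        rules=rules,
        input_nodes=inputs,
        undefined_refs=undefined,
    )


def evaluate_rule(
    rule: BooleanRule,
    state: Mapping[str, int],
    constants_false: Iterable[str] = (),
) -> int:
    """Evaluate one rule against a named state.

    ``constants_false`` members evaluate as 0; any other referenced node
    missing from ``state`` raises ``KeyError``.
    """
    if rule.constant is not None:
        return rule.constant
    false_set = set(constants_false)

    def value(name: str) -> int:
        if name in false_set:
            return 0
        if name not in state:
            raise KeyError(
                f"{rule.target}: referenced node {name!r} missing from state"
            )
        return 1 if state[name] else 0

    if rule.activators:
        active = any(value(a) for a in rule.activators)
    else:
        active = True
    if not active:
        return 0
    return 0 if any(value(h) for h in rule.inhibitors) else 1


def write_network(network: BooleanNetwork) -> str:
    """Serialize a network to rule-file text.

    The output is in canonical form (not the raw printed expressions) and
    round-trips: ``parse_network(write_network(n))`` is semantically
    identical to ``n``.
    """
    lines = []
    if network.nodes:
        ordered = [n for n in network.nodes if n in network.input_nodes]
        lines.append(("# inputs: " + ", ".join(ordered)).rstrip())
    for name in network.nodes:
        rule = network.rules[name]
        if rule.constant is not None:
            expr = str(rule.constant)
        else:
            parts = []
            if rule.activators:
                ors = " or ".join(sorted(rule.activators))
                if len(rule.activators) > 1 and rule.inhibitors:
                    ors = f"({ors})"
                parts.append(ors)
            parts.extend(f"(not {h})" for h in sorted(rule.inhibitors))
            expr = " and ".join(parts) if parts else "1"
        lines.append(f"{name} = {expr}")
    return "\n".join(lines) + ("\n" if lines else "")


def load_t2dm_model() -> BooleanNetwork:
    """Load the bundled 72-node T2DM model.

    Returns a network with 72 nodes, the five input signals
    (ER stress, oxidative stress, TNFA, FasL, IL6) and the three
    constant-FALSE undefined references (P53, GADD45, CASP12).
    """
    text = (
        resources.files("t2dm_boolnet.data")
        .joinpath("t2dm.rules")
        .read_text(encoding="utf-8")
    )
    return parse_network(text, input_nodes=T2DM_INPUT_SIGNALS)
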