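"""Boolean signaling networks: rule parsing, serialization, and synchronous updates.

A network is a set of named nodes, each carrying a binary state in {0, 1} and a
Boolean update rule over the states of its regulators. Rules use the BoolNet-style
``target, factors`` file dialect with ``!`` (NOT), ``&`` (AND), ``|`` (OR),
parentheses, and the constants ``0``/``1``. Input nodes (ligands, drug exposure
switches) are written as self-rules ``X, X`` so they hold their state under the
synchronous update unless explicitly clamped.

Clamps fix a node to a constant value, overriding its rule at every step; they
model knockouts / pharmacological inhibition (clamp to 0) and constitutive
activation or ligand presence (clamp to 1).
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BnetParseError",
    "LogicNetwork",
    "parse_expression",
    "parse_bnet",
    "write_bnet",
    "expression_to_text",
    "expression_variables",
    "evaluate_rule",
    "synchronous_step",
    "check_clamps",
    "rules_equivalent",
]

# AST node shapes: ("const", 0|1) | ("var", name) | ("not", a) | ("and", a, b) | ("or", a, b)
Ast = tuple

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])|(?P<op>[!&|()])|(?P<bad>\S))"
)


class BnetParseError(ValueError):
    """Malformed rule file or rule expression."""


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        pos = m.end()
        if m.lastgroup == "bad":
            raise BnetParseError(f"unexpected character {m.group('bad')!r} in expression {text!r}")
        if m.lastgroup is None:  # trailing whitespace
            break
        tokens.append((m.lastgroup, m.group(m.lastgroup)))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect_op(self, op: str):
        kind, val = self.take()
        if kind != "op" or val != op:
            raise BnetParseError(f"expected {op!r} in expression {self.text!r}")

    # grammar: expr := term ('|' term)* ; term := factor ('&' factor)* ;
    #          factor := '!' factor | '(' expr ')' | name | 0 | 1
    def expr(self) -> Ast:
        node = self.term()
        while self.peek() == ("op", "|"):
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self) -> Ast:
        node = self.factor()
        while self.peek() == ("op", "&"):
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self) -> Ast:
        kind, val = self.take()
        if kind == "op" and val == "!":
            return ("not", self.factor())
        if kind == "op" and val == "(":
            node = self.expr()
            self.expect_op(")")
            return node
        if kind == "name":
            return ("var", val)
        if kind == "const":
            return ("const", int(val))
        raise BnetParseError(f"unexpected end or token in expression {self.text!r}")


def parse_expression(text: str) -> Ast:
    """Parse a single Boolean rule expression into an AST."""
    tokens = _tokenize(text)
    if not tokens:
        raise BnetParseError(f"empty expression {text!r}")
    parser = _Parser(tokens, text)
    node = parser.expr()
    if parser.pos != len(tokens):
        raise BnetParseError(f"trailing tokens in expression {text!r}")
    return node


def expression_variables(ast: Ast) -> list[str]:
    """Distinct variable names in first-appearance order."""
    out: list[str] = []
    seen: set[str] = set()

    def walk(node: Ast):
        if node[0] == "var":
            if node[1] not in seen:
                seen.add(node[1])
                out.append(node[1])
        elif node[0] == "not":
            walk(node[1])
        elif node[0] in ("and", "or"):
            walk(node[1])
            walk(node[2])

    walk(ast)
    return out


def _eval(ast: Ast, env: Mapping[str, object]):
    op = ast[0]
    if op == "const":
        return bool(ast[1])
    if op == "var":
        try:
            return env[ast[1]]
        except KeyError:
            raise KeyError(f"rule references {ast[1]!r}, which is missing from the state") from None
    if op == "not":
        return np.logical_not(_eval(ast[1], env))
    if op == "and":
        return np.logical_and(_eval(ast[1], env), _eval(ast[2], env))
    if op == "or":
        return np.logical_or(_eval(ast[1], env), _eval(ast[2], env))
    raise ValueError(f"unknown AST node {op!r}")


def evaluate_rule(rule: str | Ast, state: Mapping[str, object]) -> int:
    """Evaluate a Boolean rule at a state; returns 0/1 (or an array for array-valued states)."""
    ast = parse_expression(rule) if isinstance(rule, str) else rule
    result = _eval(ast, state)
    if np.isscalar(result) or isinstance(result, (bool, np.bool_)):
        return int(bool(result))
    return np.asarray(result).astype(np.uint8)


_PREC = {"or": 0, "and": 1, "not": 2, "var": 3, "const": 3}


def expression_to_text(ast: Ast) -> str:
    """Serialize an AST with minimal parentheses; reparses to an equivalent rule."""

    def render(node: Ast, parent_prec: int) -> str:
        op = node[0]
        if op == "const":
            return str(node[1])
        if op == "var":
            return node[1]
        if op == "not":
            return "!" + render(node[1], _PREC["not"])
        sep = " & " if op == "and" else " | "
        text = sep.join(render(child, _PREC[op]) for child in node[1:])
        return f"({text})" if _PREC[op] < parent_prec else text

    return render(ast, 0)


@dataclasses.dataclass
class LogicNetwork:
    """A Boolean network: ordered node names plus one update rule per node.

    Input nodes are exactly those whose rule is the identity self-rule
    (``rules[x] == ("var", x)``); they hold state and are intended to be set by
    initial conditions or clamps.
    """

    nodes: list[str]
    rules: dict[str, Ast]
    initial_state: dict[str, int] | None = None

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise BnetParseError("duplicate node names")
        missing = [n for n in self.nodes if n not in self.rules]
        if missing:
            raise BnetParseError(f"nodes without rules: {missing}")
        declared = set(self.nodes)
        for node, ast in self.rules.items():
            for var in expression_variables(ast):
                if var not in declared:
                    raise BnetParseError(
                        f"rule for {node!r} references undeclared regulator {var!r}"
                    )

    def is_input(self, node: str) -> bool:
        return self.rules[node] == ("var", node)

    @property
    def inputs(self) -> list[str]:
        return [n for n in self.nodes if self.is_input(n)]

    def regulators(self, node: str) -> list[str]:
        return expression_variables(self.rules[node])

    @property
    def n_edges(self) -> int:
        """Interaction count: distinct regulators per rule, excluding input self-rules."""
        return sum(len(self.regulators(n)) for n in self.nodes if not self.is_input(n))

    def copy(self) -> "LogicNetwork":
        return LogicNetwork(
            list(self.nodes),
            dict(self.rules),
            dict(self.initial_state) if self.initial_state else None,
        )


def parse_bnet(text: str) -> LogicNetwork:
    """Parse a BoolNet-style rule file into a :class:`LogicNetwork`.

    One rule per line, ``Node, expression``. An optional ``targets, factors``
    header, ``#`` comments, and blank lines are accepted. Node order follows
    first appearance of the rule lines.
    """
    nodes: list[str] = []
    rules: dict[str, Ast] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 or not nodes:
            squashed = line.replace(" ", "").lower()
            if squashed in ("targets,factors", "targets,functions"):
                continue
        if "," not in line:
            raise BnetParseError(f"line {lineno}: expected 'Node, expression', got {raw!r}")
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not _NAME_RE.fullmatch(target):
            raise BnetParseError(f"line {lineno}: invalid node name {target!r}")
        if target in rules:
            raise BnetParseError(f"line {lineno}: duplicate rule for node {target!r}")
        try:
            ast = parse_expression(expr_text)
        except BnetParseError as err:
            raise BnetParseError(f"line {lineno}: {err}") from None
        nodes.append(target)
        rules[target] = ast
    if not nodes:
        raise BnetParseError("empty rule file")
    declared = set(nodes)
    for node in nodes:
        for var in expression_variables(rules[node]):
            if var not in declared:
                raise BnetParseError(
                    f"rule for {node!r} references undeclared regulator {var!r}"
                )
    return LogicNetwork(nodes, rules)


def write_bnet(network: LogicNetwork, header: bool = True) -> str:
    """Serialize a network to the rule-file dialect; inverse of :func:`parse_bnet`."""
    lines = ["targets, factors"] if header else []
    for node in network.nodes:
        lines.append(f"{node}, {expression_to_text(network.rules[node])}")
    return "\n".join(lines) + "\n"


def check_clamps(network: LogicNetwork, clamps: Mapping[str, int] | None) -> dict[str, int]:
    """Validate a clamp assignment against the network; returns a normalized dict."""
    if clamps is None:
        return {}
    out = {}
    for node, value in clamps.items():
        if node not in network.rules:
            raise KeyError(f"clamped node {node!r} is not in the network")
        if value not in (0, 1):
            raise ValueError(f"clamp value for {node!r} must be 0 or 1, got {value!r}")
        out[node] = int(value)
    return out


def synchronous_step(
    network: LogicNetwork,
    state: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """One synchronous update: every rule is evaluated on the prior state.

    Clamped nodes take their clamp value; input nodes hold state via their
    self-rule unless clamped.
    """
    clamps = check_clamps(network, clamps)
    missing = [n for n in network.nodes if n not in state]
    if missing:
        raise KeyError(f"state is missing nodes: {missing}")
    nxt = {}
    for node in network.nodes:
        if node in clamps:
            nxt[node] = clamps[node]
        else:
            nxt[node] = evaluate_rule(network.rules[node], state)
    return nxt


def rules_equivalent(a: Ast, b: Ast, max_vars: int = 16) -> bool:
    """Exhaustive truth-table equality of two rule expressions."""
    variables = sorted(set(expression_variables(a)) | set(expression_variables(b)))
    if len(variables) > max_vars:
        raise ValueError(f"too many variables ({len(variables)}) for exhaustive comparison")
    for corner in range(1 << len(variables)):
        env = {v: bool((corner >> i) & 1) for i, v in enumerate(variables)}
        if evaluate_rule(a, env) != evaluate_rule(b, env):
            return False
    return True


def truth_table(ast: Ast, regulators: Sequence[str]) -> np.ndarray:
    """Rule output over all ``2**m`` regulator corners; corner ``c`` sets
    regulator ``j`` to bit ``j`` of ``c``."""
    m = len(regulators)
    table = np.zeros(1 << m, dtype=np.uint8)
    for corner in range(1 << m):
        env = {r: bool((corner >> j) & 1) for j, r in enumerate(regulators)}
        table[corner] = evaluate_rule(ast, env)
    return table


def networks_equivalent(a: LogicNetwork, b: LogicNetwork) -> bool:
    """Same node set and identical truth tables for every node."""
    if set(a.nodes) != set(b.nodes):
        return False
    return all(rules_equivalent(a.rules[n], b.rules[n]) for n in a.nodes)


def random_states(
    network: LogicNetwork,
    n: int,
    rng: np.random.Generator,
    clamps: Mapping[str, int] | None = None,
) -> list[dict[str, int]]:
    """Uniform random complete states; clamped nodes fixed to their clamp value."""
    clamps = check_clamps(network, clamps)
    free = [node for node in network.nodes if node not in clamps]
    bits = rng.integers(0, 2, size=(n, len(free)))
    states = []
    for row in bits:
        st = {node: int(v) for node, v in zip(free, row)}
        st.update(clamps)
        states.append(st)
    return states
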