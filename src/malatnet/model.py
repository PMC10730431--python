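"""Core formalism: multivalued logical models.

A logical model is a set of named nodes, each carrying a small integer
level in ``0..max_level`` (``max_level = 1`` for Boolean nodes), together
with one logical rule per non-input node.  Rules are monotone formulas
over threshold literals ``Name:k`` (true iff the level of ``Name`` is at
least ``k``), combined with ``&``, ``|``, ``!`` and parentheses.
Multilevel targets use guarded case expressions
``{2 if <expr>; 1 if <expr>; else 0}`` evaluated first-match with
descending levels.

The signed regulatory graph is *derived* from the rules: for every
regulator of every target, the semantic monotone effect (exhaustive over
the contexts of the remaining regulators) determines the edge sign and
acting threshold.  A regulator whose effect is non-monotone, or whose
literals contradict the derived sign syntactically, is reported by
:func:`validate_model`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NodeSpec",
    "SignedEdge",
    "RuleExpr",
    "LogicalModel",
    "Perturbation",
    "ValidationReport",
    "ModelSyntaxError",
    "parse_model",
    "serialize_model",
    "validate_model",
    "apply_perturbation",
]


class ModelSyntaxError(ValueError):
    """Raised on malformed rule files; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lit:
    """Threshold literal: true iff level(name) >= thr."""

    name: str
    thr: int = 1

    def eval(self, env: Mapping[str, int]) -> bool:
        return env[self.name] >= self.thr

    def variables(self) -> set[str]:
        return {self.name}

    def polarities(self, neg: bool = False) -> set[tuple[str, int]]:
        return {(self.name, -1 if neg else 1)}

    def unparse(self) -> str:
        return self.name if self.thr == 1 else f"{self.name}:{self.thr}"


@dataclass(frozen=True)
class Const:
    """Boolean constant; ``0`` and ``1`` in rule files."""

    value: bool

    def eval(self, env: Mapping[str, int]) -> bool:
        return self.value

    def variables(self) -> set[str]:
        return set()

    def polarities(self, neg: bool = False) -> set[tuple[str, int]]:
        return set()

    def unparse(self) -> str:
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Not:
    arg: "Expr"

    def eval(self, env: Mapping[str, int]) -> bool:
        return not self.arg.eval(env)

    def variables(self) -> set[str]:
        return self.arg.variables()

    def polarities(self, neg: bool = False) -> set[tuple[str, int]]:
        return self.arg.polarities(not neg)

    def unparse(self) -> str:
        inner = self.arg.unparse()
        if isinstance(self.arg, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And:
    args: tuple["Expr", ...]

    def eval(self, env: Mapping[str, int]) -> bool:
        return all(a.eval(env) for a in self.args)

    def variables(self) -> set[str]:
        return set().union(*(a.variables() for a in self.args))

    def polarities(self, neg: bool = False) -> set[tuple[str, int]]:
        return set().union(*(a.polarities(neg) for a in self.args))

    def unparse(self) -> str:
        parts = [
            f"({a.unparse()})" if isinstance(a, Or) else a.unparse()
            for a in self.args
        ]
        return " & ".join(parts)


@dataclass(frozen=True)
class Or:
    args: tuple["Expr", ...]

    def eval(self, env: Mapping[str, int]) -> bool:
        return any(a.eval(env) for a in self.args)

    def variables(self) -> set[str]:
        return set().union(*(a.variables() for a in self.args))

    def polarities(self, neg: bool = False) -> set[tuple[str, int]]:
        return set().union(*(a.polarities(neg) for a in self.args))

    def unparse(self) -> str:
        return " | ".join(a.unparse() for a in self.args)


Expr = Lit | Const | Not | And | Or


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    name: str
    max_level: int = 1
    is_input: bool = False
    is_output: bool = False

    def __post_init__(self):
        if self.max_level < 1:
            raise ValueError(f"{self.name}: max_level must be >= 1")


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition
    threshold: int = 1
    citation: str = ""

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


@dataclass(frozen=True)
class RuleExpr:
    """One rule per non-input node.

    ``cases`` is a tuple of (level, guard) pairs in strictly descending
    level order; evaluation returns the level of the first true guard,
    or 0.  A plain Boolean rule is the single case ``(1, expr)``.
    """

    target: str
    cases: tuple[tuple[int, Expr], ...]

    def eval(self, env: Mapping[str, int]) -> int:
        for level, guard in self.cases:
            if guard.eval(env):
                return level
        return 0

    def variables(self) -> set[str]:
        out: set[str] = set()
        for _, guard in self.cases:
            out |= guard.variables()
        return out

    def polarities(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for _, guard in self.cases:
            out |= guard.polarities()
        return out

    def unparse(self) -> str:
        if len(self.cases) == 1 and self.cases[0][0] == 1:
            return self.cases[0][1].unparse()
        parts = [f"{lvl} if {g.unparse()}" for lvl, g in self.cases]
        return "{" + "; ".join(parts) + "; else 0}"


@dataclass(frozen=True)
class Perturbation:
    """Clamp assignment: node -> level.

    Gain of function (E1) clamps a node at its maximal level, knock-out
    (KO) at zero; intermediate levels are allowed for multivalued nodes.
    """

    assignments: tuple[tuple[str, int], ...] = ()

    @classmethod
    def from_spec(cls, model: "LogicalModel", spec: Mapping[str, int | str]) -> "Perturbation":
        pairs = []
        for name, mode in spec.items():
            node = model.node(name)
            if mode in ("E1", "e1"):
                level = node.max_level
            elif mode in ("KO", "ko"):
                level = 0
            else:
                level = int(mode)
            if not 0 <= level <= node.max_level:
                raise ValueError(f"{name}: clamp level {level} out of range")
            pairs.append((name, level))
        return cls(tuple(sorted(pairs)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.assignments)

    def label(self, model: "LogicalModel | None" = None) -> str:
        if not self.assignments:
            return "wild-type"
        parts = []
        for name, level in self.assignments:
            if level == 0:
                mode = "KO"
            elif model is not None and level == model.node(name).max_level:
                mode = "E1"
            else:
                mode = f"={level}"
            parts.append(f"{name} {mode}")
        return ", ".join(parts)


@dataclass
class ValidationReport:
    n_components: int = 0
    n_edges: int = 0
    sign_consistency_errors: list[str] = field(default_factory=list)
    unreachable_nodes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.sign_consistency_errors


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class LogicalModel:
    """A multivalued logical model with derived signed regulatory graph."""

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        rules: Mapping[str, RuleExpr],
        clamps: Mapping[str, int] | None = None,
        citations: Mapping[tuple[str, str], str] | None = None,
    ):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        self._index = {n.name: i for i, n in enumerate(self.nodes)}
        self.rules: dict[str, RuleExpr] = dict(rules)
        self.clamps: dict[str, int] = dict(clamps or {})
        self._citations = dict(citations or {})
        self._check_structure()
        self.edges: tuple[SignedEdge, ...] = self._infer_edges()
        self._regulators = {
            n.name: tuple(sorted(self.rules[n.name].variables(), key=self._index.__getitem__))
            for n in self.nodes
            if not n.is_input
        }
        self._targets_of: dict[str, list[str]] = {n.name: [] for n in self.nodes}
        for e in self.edges:
            self._targets_of[e.source].append(e.target)

    # -- basic accessors ----------------------------------------------------

    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def max_levels(self) -> tuple[int, ...]:
        return tuple(n.max_level for n in self.nodes)

    def regulators(self, target: str) -> tuple[str, ...]:
        return self._regulators.get(target, ())

    def targets(self, source: str) -> tuple[str, ...]:
        return tuple(self._targets_of[source])

    def edge(self, source: str, target: str) -> SignedEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source} -> {target}")

    @property
    def n_states(self) -> int:
        total = 1
        for n in self.nodes:
            total *= n.max_level + 1
        return total

    # -- state packing (mixed radix, node order of the model file) ----------

    def pack(self, state: Sequence[int]) -> int:
        idx = 0
        for level, node in zip(state, self.nodes):
            idx = idx * (node.max_level + 1) + level
        return idx

    def unpack(self, idx: int) -> tuple[int, ...]:
        out = []
        for node in reversed(self.nodes):
            out.append(idx % (node.max_level + 1))
            idx //= node.max_level + 1
        return tuple(reversed(out))

    def state_dict(self, state: Sequence[int]) -> dict[str, int]:
        return {n.name: v for n, v in zip(self.nodes, state)}

    # -- rule evaluation -----------------------------------------------------

    def target_image(self, target: str, env: Mapping[str, int]) -> int:
        """Image of one node given regulator levels (clamps applied)."""
        if target in self.clamps:
            return self.clamps[target]
        node = self.node(target)
        if node.is_input:
            return env[target]
        return self.rules[target].eval(env)

    # -- structure -----------------------------------------------------------

    def _check_structure(self):
        for n in self.nodes:
            if n.is_input and n.name in self.rules:
                raise ValueError(f"input node {n.name} must not carry a rule")
            if not n.is_input and n.name not in self.rules:
                raise ValueError(f"missing rule for node {n.name}")
        for name, rule in self.rules.items():
            if name not in self._index:
                raise ValueError(f"rule for undeclared node {name}")
            for var in rule.variables():
                if var not in self._index:
                    raise ValueError(f"rule for {name} references undeclared node {var}")
                for lit_name, thr in _literal_thresholds(rule):
                    if thr > self.node(lit_name).max_level:
                        raise ValueError(
                            f"rule for {name}: literal {lit_name}:{thr} exceeds max level"
                        )
            for lvl, _ in rule.cases:
                if not 1 <= lvl <= self.node(name).max_level:
                    raise ValueError(f"rule for {name}: case level {lvl} out of range")
        for name, level in self.clamps.items():
            node = self.node(name)
            if not 0 <= level <= node.max_level:
                raise ValueError(f"clamp {name}={level} out of range")
        for n in self.nodes:
            if n.is_output:
                for name, rule in self.rules.items():
                    if n.name in rule.variables():
                        raise ValueError(
                            f"output node {n.name} regulates {name}; outputs must be terminal"
                        )

    def regulator_effect(self, source: str, target: str) -> tuple[int, int]:
        """Semantic monotone effect of ``source`` on ``target``'s rule.

        Returns ``(sign, threshold)`` with sign in {+1, -1, 0} (0 means the
        regulator never changes the image: vacuous).  Raises ValueError on a
        non-monotone regulator.  Exhaustive over contexts of the remaining
        regulators, so only usable for modest in-degrees.
        """
        rule = self.rules[target]
        others = sorted(rule.variables() - {source}, key=self._index.__getitem__)
        src_max = self.node(source).max_level
        ranges = [range(self.node(o).max_level + 1) for o in others]
        pos = neg = False
        threshold = 0
        for ctx in product(*ranges):
            env = dict(zip(others, ctx))
            prev = None
            for k in range(src_max + 1):
                env[source] = k
                val = rule.eval(env)
                if prev is not None:
                    if val > prev:
                        pos = True
                        threshold = k if threshold == 0 else min(threshold, k)
                    elif val < prev:
                        neg = True
                        threshold = k if threshold == 0 else min(threshold, k)
                prev = val
        if pos and neg:
            raise ValueError(f"non-monotone regulator {source} -> {target}")
        if not pos and not neg:
            return 0, 0
        return (1 if pos else -1), threshold

    def _infer_edges(self) -> tuple[SignedEdge, ...]:
        edges = []
        for n in self.nodes:
            if n.is_input:
                continue
            rule = self.rules[n.name]
            for src in sorted(rule.variables(), key=self._index.__getitem__):
                try:
                    sign, thr = self.regulator_effect(src, n.name)
                except ValueError:
                    # kept out of the graph; reported by validate_model
                    continue
                if sign == 0:
                    continue
                edges.append(
                    SignedEdge(
                        src,
                        n.name,
                        sign,
                        thr,
                        self._citations.get((src, n.name), ""),
                    )
                )
        return tuple(edges)

    def with_citations(self, citations: Mapping[tuple[str, str], str]) -> "LogicalModel":
        merged = dict(self._citations)
        merged.update(citations)
        return LogicalModel(self.nodes, self.rules, self.clamps, merged)

    # -- exports -------------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(
                n.name,
                max_level=n.max_level,
                is_input=int(n.is_input),
                is_output=int(n.is_output),
            )
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                sign=e.sign,
                threshold=e.threshold,
                citation=e.citation,
            )
        return g

    def edge_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "sign": "+" if e.sign > 0 else "-",
                    "threshold": e.threshold,
                    "citation": e.citation,
                }
                for e in self.edges
            ]
        )

    def __repr__(self):
        return (
            f"LogicalModel({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"{len(self.clamps)} clamps)"
        )


def _literal_thresholds(rule: RuleExpr) -> Iterable[tuple[str, int]]:
    def walk(e: Expr):
        if isinstance(e, Lit):
            yield (e.name, e.thr)
        elif isinstance(e, Not):
            yield from walk(e.arg)
        elif isinstance(e, (And, Or)):
            for a in e.args:
                yield from walk(a)

    for _, guard in rule.cases:
        yield from walk(guard)


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_NAME = r"[A-Za-z][A-Za-z0-9_\-]*"
_TOKEN = re.compile(
    rf"\s*(?:(?P<name>{_NAME})(?::(?P<thr>\d+))?|(?P<op>[&|!(){{}};])|(?P<int>\d+))"
)


class _ExprParser:
    def __init__(self, text: str, line: int):
        self.tokens = self._tokenize(text, line)
        self.pos = 0
        self.line = line

    @staticmethod
    def _tokenize(text: str, line: int):
        tokens = []
        i = 0
        while i < len(text):
            if text[i].isspace():
                i += 1
                continue
            m = _TOKEN.match(text, i)
            if not m:
                raise ModelSyntaxError(f"bad token near {text[i:i+10]!r}", line)
            if m.group("name"):
                thr = int(m.group("thr")) if m.group("thr") else 1
                tokens.append(("lit", (m.group("name"), thr)))
            elif m.group("op"):
                tokens.append(("op", m.group("op")))
            else:
                tokens.append(("int", int(m.group("int"))))
            i = m.end()
        return tokens

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self, kind=None, value=None):
        tok = self.peek()
        if kind and tok[0] != kind or value is not None and tok[1] != value:
            raise ModelSyntaxError(f"unexpected token {tok[1]!r}", self.line)
        self.pos += 1
        return tok

    def parse_expr(self) -> Expr:
        expr = self._or()
        if self.pos != len(self.tokens):
            raise ModelSyntaxError("trailing tokens in expression", self.line)
        return expr

    def _or(self) -> Expr:
        args = [self._and()]
        while self.peek() == ("op", "|"):
            self.take()
            args.append(self._and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def _and(self) -> Expr:
        args = [self._unary()]
        while self.peek() == ("op", "&"):
            self.take()
            args.append(self._unary())
        return args[0] if len(args) == 1 else And(tuple(args))

    def _unary(self) -> Expr:
        kind, val = self.peek()
        if kind == "op" and val == "!":
            self.take()
            return Not(self._unary())
        if kind == "op" and val == "(":
            self.take()
            expr = self._or()
            self.take("op", ")")
            return expr
        if kind == "lit":
            self.take()
            name, thr = val
            if name == "if" or name == "else":
                raise ModelSyntaxError(f"keyword {name!r} in expression", self.line)
            return Lit(name, thr)
        if kind == "int":
            self.take()
            if val not in (0, 1):
                raise ModelSyntaxError(f"constant must be 0 or 1, got {val}", self.line)
            return Const(bool(val))
        raise ModelSyntaxError(f"unexpected token {val!r}", self.line)


def _parse_rule_body(target: str, body: str, line: int) -> RuleExpr:
    body = body.strip()
    if body.startswith("{"):
        if not body.endswith("}"):
            raise ModelSyntaxError("unterminated guarded expression", line)
        inner = body[1:-1]
        parts = [p.strip() for p in inner.split(";") if p.strip()]
        if not parts or not re.fullmatch(r"else\s+0", parts[-1]):
            raise ModelSyntaxError("guarded expression must end with 'else 0'", line)
        cases = []
        for part in parts[:-1]:
            m = re.match(r"(\d+)\s+if\s+(.*)", part, re.S)
            if not m:
                raise ModelSyntaxError(f"bad guarded case {part!r}", line)
            cases.append((int(m.group(1)), _ExprParser(m.group(2), line).parse_expr()))
        levels = [lvl for lvl, _ in cases]
        if levels != sorted(levels, reverse=True) or len(set(levels)) != len(levels):
            raise ModelSyntaxError("case levels must be strictly descending", line)
        return RuleExpr(target, tuple(cases))
    return RuleExpr(target, ((1, _ExprParser(body, line).parse_expr()),))


_DECL = re.compile(
    rf"(?P<name>{_NAME})\s*,\s*(?P<max>\d+)\s*(?:,\s*(?P<flag>input|output)\s*)?"
    r"(?::(?P<body>.*))?$",
    re.S,
)


def parse_model(text: str) -> LogicalModel:
    """Parse a rule file into a :class:`LogicalModel`.

    One declaration per line: ``Name, max_level[, input|output] : expression``.
    Input nodes omit the expression.  ``#`` starts a comment.  Logical lines
    may be continued by ending a physical line with a backslash.
    """
    nodes: list[NodeSpec] = []
    rules: dict[str, RuleExpr] = {}
    # join continued lines, tracking original line numbers
    logical: list[tuple[int, str]] = []
    pending = ""
    pending_line = 0
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        stripped = raw.split("#", 1)[0].rstrip("\n")
        if pending:
            stripped = pending + " " + stripped.strip()
        else:
            pending_line = lineno
        if stripped.rstrip().endswith("\\"):
            pending = stripped.rstrip()[:-1].rstrip()
            continue
        pending = ""
        if stripped.strip():
            logical.append((pending_line, stripped.strip()))
    if pending:
        raise ModelSyntaxError("dangling line continuation", pending_line)

    for lineno, line in logical:
        m = _DECL.match(line)
        if not m:
            raise ModelSyntaxError(f"cannot parse declaration {line!r}", lineno)
        name, max_level = m.group("name"), int(m.group("max"))
        flag, body = m.group("flag"), m.group("body")
        if any(n.name == name for n in nodes):
            raise ModelSyntaxError(f"duplicate node {name}", lineno)
        is_input = flag == "input"
        is_output = flag == "output"
        if is_input and body is not None and body.strip():
            raise ModelSyntaxError(f"input node {name} must not carry a rule", lineno)
        if not is_input and (body is None or not body.strip()):
            raise ModelSyntaxError(f"missing rule for node {name}", lineno)
        try:
            nodes.append(NodeSpec(name, max_level, is_input, is_output))
        except ValueError as exc:
            raise ModelSyntaxError(str(exc), lineno) from exc
        if not is_input:
            rules[name] = _parse_rule_body(name, body, lineno)

    declared = {n.name for n in nodes}
    for name, rule in rules.items():
        for var in rule.variables():
            if var not in declared:
                raise ModelSyntaxError(f"rule for {name} references undeclared node {var}")
    try:
        return LogicalModel(nodes, rules)
    except ValueError as exc:
        raise ModelSyntaxError(str(exc)) from exc


def serialize_model(model: LogicalModel) -> str:
    """Canonical rule-file form; ``parse_model`` of the output is the identity."""
    lines = []
    for n in model.nodes:
        flag = ", input" if n.is_input else (", output" if n.is_output else "")
        if n.is_input:
            lines.append(f"{n.name}, {n.max_level}{flag}")
        else:
            lines.append(f"{n.name}, {n.max_level}{flag} : {model.rules[n.name].unparse()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Validation & perturbation
# ---------------------------------------------------------------------------


def validate_model(
    model: LogicalModel,
    declared_edges: Iterable[tuple[str, str, int]] | None = None,
) -> ValidationReport:
    """Structural report: component/edge counts and sign-consistency findings.

    ``n_components`` counts non-input nodes (the convention that the input
    is reported separately).  Sign consistency holds when every regulator's
    semantic monotone effect exists, is non-vacuous, matches the syntactic
    polarity of its literals, and — when ``declared_edges`` (triples
    ``(source, target, sign)``) are given — matches the declared sign.
    """
    report = ValidationReport(
        n_components=sum(1 for n in model.nodes if not n.is_input),
        n_edges=len(model.edges),
    )
    inferred: dict[tuple[str, str], int] = {}
    for n in model.nodes:
        if n.is_input:
            continue
        rule = model.rules[n.name]
        pol: dict[str, set[int]] = {}
        for var, p in rule.polarities():
            pol.setdefault(var, set()).add(p)
        for src in sorted(rule.variables(), key=model.index):
            try:
                sign, _thr = model.regulator_effect(src, n.name)
            except ValueError:
                report.sign_consistency_errors.append(
                    f"{src} -> {n.name}: non-monotone effect"
                )
                continue
            if sign == 0:
                report.sign_consistency_errors.append(
                    f"{src} -> {n.name}: vacuous regulator (never alters the image)"
                )
                continue
            inferred[(src, n.name)] = sign
            if -sign in pol.get(src, set()) and sign not in pol[src]:
                word = "activator" if sign > 0 else "inhibitor"
                report.sign_consistency_errors.append(
                    f"{src} -> {n.name}: {word} appears only with opposite polarity"
                )
    if declared_edges is not None:
        for src, tgt, sign in declared_edges:
            got = inferred.get((src, tgt))
            if got is None:
                report.sign_consistency_errors.append(
                    f"{src} -> {tgt}: declared edge absent from the rules"
                )
            elif got != sign:
                report.sign_consistency_errors.append(
                    f"{src} -> {tgt}: declared sign {sign:+d} but rules imply {got:+d}"
                )
    # reachability from the inputs over the regulatory graph
    inputs = [n.name for n in model.nodes if n.is_input]
    if inputs:
        seen = set(inputs)
        frontier = list(inputs)
        while frontier:
            cur = frontier.pop()
            for tgt in model.targets(cur):
                if tgt not in seen:
                    seen.add(tgt)
                    frontier.append(tgt)
        report.unreachable_nodes = [n.name for n in model.nodes if n.name not in seen]
    return report


def apply_perturbation(model: LogicalModel, p: Perturbation) -> LogicalModel:
    """Return a copy of the model with the perturbation's clamps applied.

    Clamped nodes keep their rules (the regulatory graph is unchanged) but
    their image is pinned to the clamp level, so they never move in any
    trajectory.
    """
    clamps = dict(model.clamps)
    for name, level in p.assignments:
        node = model.node(name)  # raises KeyError on unknown node
        if not 0 <= level <= node.max_level:
            raise ValueError(f"{name}: clamp level {level} out of range")
        clamps[name] = level
    return LogicalModel(model.nodes, model.rules, clamps, model._citations)
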