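"""Signed feedback circuits and their functionality contexts.

An elementary circuit of the regulatory graph is *positive* when it
carries an even number of inhibitions and *negative* otherwise; positive
circuits are the structural prerequisite for multistability, negative
circuits for sustained oscillations.  A circuit is *functional* when
there is at least one context — an assignment of levels to the other
regulators of its targets — in which every edge of the circuit actively
moves its target's rule image in the edge's sign direction at the edge's
acting threshold.  Only functional circuits actually shape the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .model import LogicalModel, SignedEdge

__all__ = [
    "Circuit",
    "CircuitContext",
    "CircuitCensus",
    "enumerate_circuits",
    "circuit_sign",
    "functionality_context",
    "functional_circuit_census",
]


@dataclass(frozen=True)
class Circuit:
    """An elementary cycle, canonicalized to its lexicographically minimal
    rotation so that rotations compare equal."""

    nodes: tuple[str, ...]
    edges: tuple[SignedEdge, ...]

    @classmethod
    def from_nodes(cls, model: LogicalModel, nodes: Sequence[str]) -> "Circuit":
        nodes = _canonical_rotation(tuple(nodes))
        edges = tuple(
            model.edge(nodes[i], nodes[(i + 1) % len(nodes)]) for i in range(len(nodes))
        )
        return cls(nodes, edges)

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def sign(self) -> str:
        return circuit_sign(self)

    def __str__(self):
        return "/".join(self.nodes) + f" ({self.sign})"


@dataclass(frozen=True)
class CircuitContext:
    circuit: Circuit
    variables: tuple[str, ...]
    witness: tuple[tuple[str, int], ...] | None
    n_witnesses: int | None = None  # None when the joint space was not enumerated

    @property
    def is_functional(self) -> bool:
        return self.witness is not None


def _canonical_rotation(nodes: tuple[str, ...]) -> tuple[str, ...]:
    rotations = [nodes[i:] + nodes[:i] for i in range(len(nodes))]
    return min(rotations)


def enumerate_circuits(model: LogicalModel, max_len: int | None = None) -> list[Circuit]:
    """All elementary cycles of the signed regulatory graph, canonicalized,
    in deterministic (length, nodes) order."""
    import networkx as nx

    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be >= 1")
    g = nx.DiGraph()
    g.add_nodes_from(model.names)
    g.add_edges_from((e.source, e.target) for e in model.edges)
    seen = set()
    out = []
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        c = Circuit.from_nodes(model, cyc)
        if c.nodes not in seen:
            seen.add(c.nodes)
            out.append(c)
    out.sort(key=lambda c: (c.length, c.nodes))
    return out


def circuit_sign(c: Circuit) -> str:
    """'positive' iff the number of inhibitions along the cycle is even."""
    neg = sum(1 for e in c.edges if e.sign < 0)
    return "positive" if neg % 2 == 0 else "negative"


def _edge_witnesses(model: LogicalModel, edge: SignedEdge):
    """Assignments of the target's other regulators under which raising the
    source across its acting threshold moves the target's image in the
    edge's sign direction.  Clamped regulators are pinned at their clamp."""
    rule = model.rules[edge.target]
    others = tuple(sorted(rule.variables() - {edge.source}, key=model.index))
    domains = [
        (model.clamps[o],) if o in model.clamps else tuple(range(model.node(o).max_level + 1))
        for o in others
    ]
    witnesses = []
    for combo in product(*domains):
        local = dict(zip(others, combo))
        local[edge.source] = edge.threshold - 1
        lo = rule.eval(local)
        local[edge.source] = edge.threshold
        hi = rule.eval(local)
        if (hi - lo) * edge.sign > 0:
            witnesses.append(combo)
    return others, witnesses


_COUNT_SPACE_BOUND = 2**14


def functionality_context(
    model: LogicalModel, c: Circuit, count_witnesses: bool | None = None
) -> CircuitContext:
    """Simultaneous satisfiability of every circuit edge's local
    functionality condition.

    The joint context ranges over the union of the targets' other
    regulators (which may include circuit nodes that act as external
    regulators of another circuit target); clamped nodes are fixed at
    their clamp, and a clamped circuit node makes the circuit
    non-functional outright, since its image can never move.

    Satisfiability is decided by joining the per-edge witness sets with
    backtracking.  The exact number of joint witnesses is enumerated when
    the joint space is small (or ``count_witnesses=True`` forces it);
    otherwise ``n_witnesses`` is left ``None``.
    """
    for name in c.nodes:
        if name in model.clamps:
            return CircuitContext(c, (), None, 0)
        if model.node(name).is_input:
            return CircuitContext(c, (), None, 0)  # inputs carry no rule to drive

    conditions = []
    variables: set[str] = set()
    for edge in c.edges:
        others, wits = _edge_witnesses(model, edge)
        if not wits:
            return CircuitContext(c, others, None, 0)
        conditions.append((others, wits))
        variables.update(others)
    var_order = tuple(sorted(variables, key=model.index))

    conditions.sort(key=lambda cond: len(cond[1]))

    def rec(i: int, env: dict):
        if i == len(conditions):
            return env
        vars_i, wits = conditions[i]
        for w in wits:
            if all(env.get(v, lvl) == lvl for v, lvl in zip(vars_i, w)):
                child = dict(env)
                child.update(zip(vars_i, w))
                found = rec(i + 1, child)
                if found is not None:
                    return found
        return None

    sat = rec(0, {})
    if sat is None:
        return CircuitContext(c, var_order, None, 0)
    witness = tuple((v, sat[v]) for v in var_order)

    n_witnesses: int | None = None
    space = 1
    for v in var_order:
        space *= 1 if v in model.clamps else model.node(v).max_level + 1
    if count_witnesses or (count_witnesses is None and space <= _COUNT_SPACE_BOUND):
        domains = [
            (model.clamps[v],) if v in model.clamps else tuple(range(model.node(v).max_level + 1))
            for v in var_order
        ]
        wit_sets = [(vs, set(ws)) for vs, ws in conditions]
        n_witnesses = 0
        for combo in product(*domains):
            env = dict(zip(var_order, combo))
            if all(tuple(env[v] for v in vs) in ws for vs, ws in wit_sets):
                n_witnesses += 1
    return CircuitContext(c, var_order, witness, n_witnesses)


@dataclass
class CircuitCensus:
    total_circuits: int
    total_functional: int
    functional_by_sign: dict[str, int]
    functional_by_length: dict[int, int]
    functional_short: list[Circuit]  # functional circuits with <= 4 components
    contexts: list[CircuitContext]

    @property
    def n_functional_short(self) -> int:
        return len(self.functional_short)

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "circuit": "/".join(ctx.circuit.nodes),
                    "length": ctx.circuit.length,
                    "sign": ctx.circuit.sign,
                    "functional": ctx.is_functional,
                    "n_contexts": ctx.n_witnesses,
                }
                for ctx in self.contexts
            ]
        )


def functional_circuit_census(
    model: LogicalModel, max_len: int | None = None
) -> CircuitCensus:
    """Enumerate circuits, test functionality, and tabulate the counts."""
    circuits = enumerate_circuits(model, max_len)
    contexts = [functionality_context(model, c) for c in circuits]
    functional = [ctx for ctx in contexts if ctx.is_functional]
    by_sign: dict[str, int] = {"positive": 0, "negative": 0}
    by_length: dict[int, int] = {}
    for ctx in functional:
        by_sign[ctx.circuit.sign] += 1
        by_length[ctx.circuit.length] = by_length.get(ctx.circuit.length, 0) + 1
    return CircuitCensus(
        total_circuits=len(circuits),
        total_functional=len(functional),
        functional_by_sign=by_sign,
        functional_by_length=dict(sorted(by_length.items())),
        functional_short=[ctx.circuit for ctx in functional if ctx.circuit.length <= 4],
        contexts=contexts,
    )
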