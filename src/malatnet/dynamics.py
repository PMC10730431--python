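"""Asynchronous multivalued dynamics.

States are tuples of levels in the model's node order.  The update scheme
is unitary asynchronous: a transition changes exactly one node by exactly
one level toward the value its rule prescribes, so every state has one
successor per node whose rule image differs from its current level.

Stable states (fixed points of the synchronous image, equivalently states
with no asynchronous successor) are enumerated exactly by a pruned
backtracking sweep that never builds the state space.  Attractors in
general are terminal strongly connected components of the asynchronous
state-transition graph (STG); for models above a configurable size bound
the full STG is not built and cyclic attractors are instead sought on the
reachable STG from a set of initial states, while the stable-state sweep
remains exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .model import LogicalModel, Lit, Const, Not, And, Or, RuleExpr

__all__ = [
    "State",
    "STG",
    "Attractor",
    "image",
    "async_successors",
    "stable_states",
    "reachable_stg",
    "attractors",
    "bounded_attractors",
    "default_initial_states",
    "StateSpaceTooLarge",
]

State = tuple  # tuple[int, ...], one level per node


class StateSpaceTooLarge(RuntimeError):
    """The requested exhaustive analysis exceeds the configured bound."""


# ---------------------------------------------------------------------------
# Compiled evaluators
# ---------------------------------------------------------------------------


def _expr_source(expr, index) -> str:
    if isinstance(expr, Lit):
        return f"(s[{index[expr.name]}]>={expr.thr})"
    if isinstance(expr, Const):
        return "True" if expr.value else "False"
    if isinstance(expr, Not):
        return f"(not {_expr_source(expr.arg, index)})"
    if isinstance(expr, And):
        return "(" + " and ".join(_expr_source(a, index) for a in expr.args) + ")"
    if isinstance(expr, Or):
        return "(" + " or ".join(_expr_source(a, index) for a in expr.args) + ")"
    raise TypeError(type(expr))


def _rule_source(rule: RuleExpr, index) -> str:
    src = "0"
    for level, guard in reversed(rule.cases):
        src = f"({level} if {_expr_source(guard, index)} else {src})"
    return src


def node_evaluators(model: LogicalModel) -> list[Callable[[Sequence[int]], int]]:
    """One callable per node mapping a full state to that node's image."""
    cached = getattr(model, "_node_evals", None)
    if cached is not None:
        return cached
    index = {name: i for i, name in enumerate(model.names)}
    fns = []
    for i, node in enumerate(model.nodes):
        if node.name in model.clamps:
            level = model.clamps[node.name]
            fns.append(eval(f"lambda s: {level}"))
        elif node.is_input:
            fns.append(eval(f"lambda s: s[{i}]"))
        else:
            fns.append(eval("lambda s: " + _rule_source(model.rules[node.name], index)))
    model._node_evals = fns
    return fns


def image_function(model: LogicalModel) -> Callable[[State], State]:
    """Compiled synchronous image ``s -> f(s)``."""
    cached = getattr(model, "_image_fn", None)
    if cached is not None:
        return cached
    index = {name: i for i, name in enumerate(model.names)}
    parts = []
    for i, node in enumerate(model.nodes):
        if node.name in model.clamps:
            parts.append(str(model.clamps[node.name]))
        elif node.is_input:
            parts.append(f"s[{i}]")
        else:
            parts.append(_rule_source(model.rules[node.name], index))
    fn = eval("lambda s: (" + ",".join(parts) + ("," if len(parts) == 1 else "") + ")")
    model._image_fn = fn
    return fn


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def image(model: LogicalModel, s: State) -> State:
    """Synchronous image: component-wise rule evaluation.

    Input and clamped nodes are copied through / pinned.
    """
    _check_state(model, s)
    return image_function(model)(s)


def async_successors(model: LogicalModel, s: State) -> set[State]:
    """Unitary asynchronous successors (empty iff ``s`` is stable)."""
    img = image_function(model)(s)
    out = set()
    for i, (cur, tgt) in enumerate(zip(s, img)):
        if tgt != cur:
            step = 1 if tgt > cur else -1
            out.add(s[:i] + (cur + step,) + s[i + 1 :])
    return out


def _check_state(model: LogicalModel, s: State) -> None:
    if len(s) != len(model.nodes):
        raise ValueError("state length does not match the model")
    for level, node in zip(s, model.nodes):
        if not 0 <= level <= node.max_level:
            raise ValueError(f"{node.name}: level {level} out of range")


# ---------------------------------------------------------------------------
# Stable states: pruned backtracking sweep
# ---------------------------------------------------------------------------


def stable_states(model: LogicalModel, max_solutions: int | None = None) -> set[State]:
    """All fixed points ``{s : f(s) = s}``, exactly, without enumerating
    the state space.

    Nodes are assigned in an order that completes each node's stability
    check (its own level plus all its regulators assigned) as early as
    possible, and every completed check prunes the branch immediately.
    Unclamped inputs are free variables, so the sweep covers every input
    combination.
    """
    n = len(model.nodes)
    names = model.names
    idx = {name: i for i, name in enumerate(names)}
    evals = node_evaluators(model)

    # dependencies: node i's check needs {i} | regulators(i)
    needs: list[set[int]] = []
    for node in model.nodes:
        if node.name in model.clamps or node.is_input:
            needs.append({idx[node.name]})
        else:
            needs.append({idx[v] for v in model.regulators(node.name)} | {idx[node.name]})

    # greedy order: repeatedly take the node completing the most checks soonest
    order: list[int] = []
    assigned: set[int] = set()
    remaining = set(range(n))
    while remaining:
        best = min(
            remaining,
            key=lambda j: (
                min(
                    (len(needs[k] - assigned) for k in range(n) if j in needs[k]),
                    default=n,
                ),
                j,
            ),
        )
        order.append(best)
        assigned.add(best)
        remaining.discard(best)

    pos_of = {node: depth for depth, node in enumerate(order)}
    checks_at: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        checks_at[max(pos_of[j] for j in needs[k])].append(k)

    domains = []
    for j in order:
        node = model.nodes[j]
        if node.name in model.clamps:
            domains.append((model.clamps[node.name],))
        else:
            domains.append(tuple(range(node.max_level + 1)))

    out: set[State] = set()
    state = [0] * n

    def rec(depth: int):
        if depth == n:
            out.add(tuple(state))
            return
        j = order[depth]
        for level in domains[depth]:
            state[j] = level
            ok = True
            for k in checks_at[depth]:
                node = model.nodes[k]
                if node.is_input and node.name not in model.clamps:
                    continue
                if evals[k](state) != state[k]:
                    ok = False
                    break
            if ok:
                rec(depth + 1)
                if max_solutions is not None and len(out) >= max_solutions:
                    return
        state[j] = 0

    rec(0)
    return out


# ---------------------------------------------------------------------------
# STGs and attractors
# ---------------------------------------------------------------------------


@dataclass
class STG:
    """An explicit (possibly partial) asynchronous state-transition graph."""

    states: set[State] = field(default_factory=set)
    transitions: set[tuple[State, State]] = field(default_factory=set)
    truncated: bool = False
    initial: tuple[State, ...] = ()

    def successors(self, s: State) -> set[State]:
        return {t for (a, t) in self.transitions if a == s}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.transitions)
        g.graph["truncated"] = self.truncated
        return g


@dataclass(frozen=True)
class Attractor:
    kind: str  # "stable" | "cyclic"
    states: frozenset
    phenotype: str | None = None

    def __post_init__(self):
        if self.kind == "stable" and len(self.states) != 1:
            raise ValueError("a stable attractor holds exactly one state")
        if self.kind == "cyclic" and len(self.states) < 2:
            raise ValueError("a cyclic attractor holds at least two states")

    @property
    def state(self) -> State:
        """The single state of a stable attractor."""
        (s,) = self.states
        return s

    def with_phenotype(self, label: str) -> "Attractor":
        return Attractor(self.kind, self.states, label)


def reachable_stg(
    model: LogicalModel,
    initial: Iterable[State],
    max_states: int = 2**20,
) -> STG:
    """Breadth-first closure of ``initial`` under asynchronous successors.

    Exploration stops (with ``truncated=True``) once ``max_states`` states
    have been expanded.
    """
    init = tuple(dict.fromkeys(tuple(s) for s in initial))
    for s in init:
        _check_state(model, s)
    stg = STG(initial=init)
    frontier = list(init)
    stg.states.update(init)
    while frontier:
        nxt = []
        for s in frontier:
            for t in async_successors(model, s):
                stg.transitions.add((s, t))
                if t not in stg.states:
                    if len(stg.states) >= max_states:
                        stg.truncated = True
                        continue
                    stg.states.add(t)
                    nxt.append(t)
        frontier = nxt
    return stg


def _terminal_sccs(states: Iterable[State], succ) -> list[frozenset]:
    """Terminal SCCs of an implicit graph, iterative Tarjan.

    Only SCCs whose every member's successors stay inside the SCC are
    returned; for a partial graph the successor map must still be the
    *true* successor function, so any terminal SCC found is genuine.
    """
    indexes: dict[State, int] = {}
    low: dict[State, int] = {}
    on_stack: set[State] = set()
    stack: list[State] = []
    counter = 0
    out: list[frozenset] = []

    for root in states:
        if root in indexes:
            continue
        work = [(root, iter(succ(root)))]
        indexes[root] = low[root] = counter
        counter += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in indexes:
                    indexes[w] = low[w] = counter
                    counter += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(succ(w))))
                    advanced = True
                    break
                if w in on_stack:
                    low[v] = min(low[v], indexes[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[v])
            if low[v] == indexes[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == v:
                        break
                comp_set = frozenset(comp)
                if all(set(succ(w)) <= comp_set for w in comp_set):
                    out.append(comp_set)
    return out


def bounded_attractors(
    model: LogicalModel,
    initial: Iterable[State] | None = None,
    max_states: int = 100_000,
) -> tuple[set[Attractor], bool]:
    """Attractors found by bounded breadth-first exploration from ``initial``
    (default: the all-zero state per input combination).

    Returns ``(attractors, complete)``.  Any terminal SCC returned is a
    genuine attractor (its members' full successor sets stay inside it);
    when ``complete`` is False the exploration hit ``max_states`` and
    attractors outside the explored region may be missed.
    """
    imgf = image_function(model)
    pack = model.pack
    if initial is None:
        initial = default_initial_states(model)
    frontier = [tuple(s) for s in dict.fromkeys(tuple(s) for s in initial)]
    for s in frontier:
        _check_state(model, s)
    seen: set[int] = {pack(s) for s in frontier}
    succ_map: dict[int, tuple[int, ...]] = {}
    truncated = False
    while frontier:
        nxt = []
        for s in frontier:
            img = imgf(s)
            succs = []
            for i, (cur, tgt) in enumerate(zip(s, img)):
                if tgt != cur:
                    q = s[:i] + (cur + (1 if tgt > cur else -1),) + s[i + 1 :]
                    pq = pack(q)
                    succs.append(pq)
                    if pq not in seen:
                        if len(seen) >= max_states:
                            truncated = True
                            continue
                        seen.add(pq)
                        nxt.append(q)
            succ_map[pack(s)] = tuple(succs)
        frontier = nxt

    expanded = set(succ_map)
    out: set[Attractor] = set()
    for comp in _terminal_sccs(
        expanded, lambda p: [q for q in succ_map[p] if q in expanded]
    ):
        # genuine only if no member has a successor outside the component
        if any(q not in comp for p in comp for q in succ_map[p]):
            continue
        states = frozenset(model.unpack(p) for p in comp)
        out.add(Attractor("stable" if len(states) == 1 else "cyclic", states))
    return out, not truncated


def attractors(
    model: LogicalModel,
    max_full: int = 2**22,
    initial: Iterable[State] | None = None,
    max_states: int = 2**17,
) -> set[Attractor]:
    """Stable states plus terminal cyclic SCCs of the asynchronous STG.

    Below ``max_full`` total states the full STG is analyzed implicitly and
    the result is exact.  Above it, the stable-state sweep stays exact and
    cyclic attractors are sought by bounded exploration from ``initial``
    (default: the all-zero state for every combination of input levels);
    a terminal SCC found there is a true attractor even if exploration was
    truncated, but cyclic attractors outside the explored region may be
    missed.
    """
    out: set[Attractor] = set()
    if model.n_states <= max_full:
        succ = lambda s: async_successors(model, s)  # noqa: E731
        all_states = (model.unpack(i) for i in range(model.n_states))
        for comp in _terminal_sccs(all_states, succ):
            out.add(Attractor("stable" if len(comp) == 1 else "cyclic", comp))
        return out

    for s in stable_states(model):
        out.add(Attractor("stable", frozenset([s])))
    found, _complete = bounded_attractors(model, initial, max_states)
    out |= found
    return out


def default_initial_states(model: LogicalModel) -> list[State]:
    """All-zero states, one per combination of unclamped input levels."""
    from itertools import product as _product

    base = [model.clamps.get(n.name, 0) for n in model.nodes]
    free_inputs = [
        i
        for i, n in enumerate(model.nodes)
        if n.is_input and n.name not in model.clamps
    ]
    if not free_inputs:
        return [tuple(base)]
    out = []
    for combo in _product(*(range(model.nodes[i].max_level + 1) for i in free_inputs)):
        s = list(base)
        for i, v in zip(free_inputs, combo):
            s[i] = v
        out.append(tuple(s))
    return out
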