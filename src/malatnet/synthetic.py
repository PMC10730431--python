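"""Random multivalued logical models and brute-force oracles.

The generator emulates the structural class the engine assumes: sparse
signed regulatory graphs with monotone rules of the form
``(OR of activators) AND NOT (OR of inhibitors)``, optionally with a few
multivalued nodes.  Sign consistency holds by construction, which makes
the generated models valid fixtures for every analysis stage.

The oracles re-derive attractors and functional circuits by explicit
enumeration of the full state space, independently of the pruned sweep,
the implicit-graph SCC search, and the context-restricted functionality
test used by the engine, so exact agreement on batteries of random models
is a meaningful check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import product

from .circuits import Circuit, enumerate_circuits
from .dynamics import Attractor, StateSpaceTooLarge, async_successors, _terminal_sccs
from .model import And, Const, Lit, LogicalModel, NodeSpec, Not, Or, RuleExpr

__all__ = [
    "RandomModelConfig",
    "random_model",
    "brute_force_attractors",
    "brute_force_functional_circuits",
]


@dataclass(frozen=True)
class RandomModelConfig:
    n_nodes: int = 6
    max_inputs: int = 2  # maximal in-degree
    fraction_multivalued: float = 0.0
    fraction_negative: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.max_inputs <= self.n_nodes:
            raise ValueError("max_inputs must be in 0..n_nodes")
        for frac in (self.fraction_multivalued, self.fraction_negative):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def random_model(cfg: RandomModelConfig) -> LogicalModel:
    """Deterministic-for-seed random model.

    Every node receives at most ``max_inputs`` regulators drawn without
    replacement, each regulator acting as activator or inhibitor with
    probability ``fraction_negative`` of the latter, and a monotone rule
    ``any(activators) and not any(inhibitors)`` (scaled to the target's
    top level for multivalued targets, with an intermediate case when the
    activators hold but an inhibitor is present).  A node drawn with no
    regulators becomes a constant-zero rule.
    """
    rng = random.Random(cfg.seed)
    names = [f"n{i}" for i in range(cfg.n_nodes)]
    nodes = []
    for name in names:
        max_level = 2 if rng.random() < cfg.fraction_multivalued else 1
        nodes.append(NodeSpec(name, max_level=max_level))

    rules: dict[str, RuleExpr] = {}
    for i, name in enumerate(names):
        k = rng.randint(0, cfg.max_inputs)
        regs = rng.sample(names, k) if k else []
        activators, inhibitors = [], []
        for reg in regs:
            thr = rng.randint(1, nodes[names.index(reg)].max_level)
            (inhibitors if rng.random() < cfg.fraction_negative else activators).append(
                Lit(reg, thr)
            )
        if not activators and not inhibitors:
            rules[name] = RuleExpr(name, ((1, Const(False)),))
            continue
        act: object
        if activators:
            act = activators[0] if len(activators) == 1 else Or(tuple(activators))
        else:
            act = None
        parts = []
        if act is not None:
            parts.append(act)
        parts.extend(Not(lit) for lit in inhibitors)
        expr = parts[0] if len(parts) == 1 else And(tuple(parts))
        if nodes[i].max_level == 2 and act is not None and inhibitors:
            inhib_any = (
                inhibitors[0] if len(inhibitors) == 1 else Or(tuple(inhibitors))
            )
            rules[name] = RuleExpr(
                name,
                (
                    (2, expr),
                    (1, And((act, inhib_any))),
                ),
            )
        else:
            top = nodes[i].max_level
            rules[name] = RuleExpr(name, ((top, expr),))
    return LogicalModel(nodes, rules)


def brute_force_attractors(model: LogicalModel, max_states: int = 2**20) -> set[Attractor]:
    """Attractors as terminal SCCs of the explicitly enumerated STG."""
    if model.n_states > max_states:
        raise StateSpaceTooLarge(
            f"{model.n_states} states exceed the brute-force bound {max_states}"
        )
    succ = lambda s: async_successors(model, s)  # noqa: E731
    all_states = (model.unpack(i) for i in range(model.n_states))
    out: set[Attractor] = set()
    for comp in _terminal_sccs(all_states, succ):
        out.add(Attractor("stable" if len(comp) == 1 else "cyclic", comp))
    return out


def brute_force_functional_circuits(
    model: LogicalModel, max_states: int = 2**16
) -> set[Circuit]:
    """Functional circuits by scanning every full state.

    For each elementary cycle, a state witnesses functionality when every
    edge's source, flipped across its acting threshold with everything
    else held at the state's levels, moves its target's image in the
    edge's sign direction.  Clamped or input-containing circuits cannot
    be driven and are never functional.
    """
    if model.n_states > max_states:
        raise StateSpaceTooLarge(
            f"{model.n_states} states exceed the brute-force bound {max_states}"
        )
    circuits = enumerate_circuits(model)
    out: set[Circuit] = set()
    names = model.names
    for c in circuits:
        if any(model.node(n).is_input or n in model.clamps for n in c.nodes):
            continue
        found = False
        for idx in range(model.n_states):
            s = model.unpack(idx)
            env = dict(zip(names, s))
            ok = True
            for e in c.edges:
                rule = model.rules[e.target]
                local = dict(env)
                local[e.source] = e.threshold - 1
                lo = rule.eval(local)
                local[e.source] = e.threshold
                hi = rule.eval(local)
                if (hi - lo) * e.sign <= 0:
                    ok = False
                    break
            if ok:
                found = True
                break
        if found:
            out.add(c)
    return out
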