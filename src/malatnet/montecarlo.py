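"""Monte-Carlo phenotype quantification by random asynchronous trajectories.

Each run starts from a configured initial condition (default: the
wild-type proliferation stable state with the DNA-damage input switched
ON, i.e. a cycling cell hit by drug-induced genotoxic stress), picks one
enabled unitary transition uniformly at random per step, and stops on
absorption into a stable state or a known cyclic attractor (or censoring
at ``max_steps``).  Tallied absorption phenotypes estimate the probability
of each cell-fate endpoint; a bistability scenario (senescence and
apoptosis coexist) is called resistance-reducing when the apoptotic
probability strictly exceeds the 70 % threshold.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .dynamics import Attractor, State, image_function, stable_states
from .model import LogicalModel, Perturbation, apply_perturbation
from .perturbation import classify_attractor

__all__ = [
    "TrajectoryResult",
    "PhenotypeDistribution",
    "sample_trajectory",
    "phenotype_probabilities",
    "classify_bistability",
    "damaged_proliferation_state",
]

CENSORED = "censored"


@dataclass(frozen=True)
class TrajectoryResult:
    initial: State
    final: State
    steps: int
    absorbed: bool
    attractor: Attractor | None  # None when censored


@dataclass(frozen=True)
class PhenotypeDistribution:
    counts: Mapping[str, int]
    n_runs: int
    seed: int
    max_steps: int

    @property
    def probabilities(self) -> dict[str, float]:
        return {k: v / self.n_runs for k, v in sorted(self.counts.items())}

    @property
    def censored_fraction(self) -> float:
        return self.counts.get(CENSORED, 0) / self.n_runs

    def probability(self, label: str) -> float:
        return self.counts.get(label, 0) / self.n_runs

    def as_dict(self) -> dict:
        return {
            "probabilities": self.probabilities,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "max_steps": self.max_steps,
            "censored_fraction": self.censored_fraction,
        }


def sample_trajectory(
    model: LogicalModel,
    s0: State,
    rng: random.Random | int,
    max_steps: int = 10_000,
    cyclic_attractors: Iterable[Attractor] = (),
) -> TrajectoryResult:
    """One random asynchronous walk until absorption or censoring.

    Absorption is detected on stable states (no enabled transition) and on
    membership in any supplied cyclic attractor (a terminal set can never
    be left, so the first hit decides).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    imgf = image_function(model)
    cyclic_index: dict[State, Attractor] = {}
    for a in cyclic_attractors:
        for s in a.states:
            cyclic_index[s] = a
    s = tuple(s0)
    for step in range(max_steps + 1):
        if s in cyclic_index:
            return TrajectoryResult(tuple(s0), s, step, True, cyclic_index[s])
        img = imgf(s)
        moves = [
            (i, 1 if tgt > cur else -1)
            for i, (cur, tgt) in enumerate(zip(s, img))
            if tgt != cur
        ]
        if not moves:
            return TrajectoryResult(
                tuple(s0), s, step, True, Attractor("stable", frozenset([s]))
            )
        if step == max_steps:
            break
        i, delta = moves[rng.randrange(len(moves))] if len(moves) > 1 else moves[0]
        s = s[:i] + (s[i] + delta,) + s[i + 1 :]
    return TrajectoryResult(tuple(s0), s, max_steps, False, None)


def damaged_proliferation_state(model: LogicalModel) -> State:
    """The wild-type proliferation stable state with every input set to 1.

    This is the default Monte-Carlo initial condition: a proliferating
    cell receiving drug-induced DNA damage.
    """
    inputs = [i for i, n in enumerate(model.nodes) if n.is_input]
    base = {name: 0 for name in model.names if model.node(name).is_input}
    unperturbed = LogicalModel(model.nodes, model.rules, base)
    candidates = sorted(stable_states(unperturbed))
    if not candidates:
        raise ValueError("model has no stable state with inputs OFF")
    s = list(candidates[0])
    for i in inputs:
        s[i] = 1
    return tuple(s)


def phenotype_probabilities(
    model: LogicalModel,
    markers: Mapping[str, Mapping[str, int]],
    perturbation: Perturbation | Mapping[str, int | str] | None = None,
    n_runs: int = 10_000,
    seed: int = 0,
    max_steps: int = 10_000,
    initial: State | str = "damaged-proliferation",
    cyclic_attractors: Iterable[Attractor] = (),
) -> PhenotypeDistribution:
    """Estimate phenotype probabilities from ``n_runs`` random trajectories.

    ``initial`` is either an explicit state, the default
    ``"damaged-proliferation"`` condition, or ``"uniform"`` for independent
    uniform random initial states (inputs pinned ON).  The perturbation is
    applied on top, with the DNA-damage input clamped ON.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec: dict[str, int | str] = {n.name: 1 for n in model.nodes if n.is_input}
    if isinstance(perturbation, Perturbation):
        spec.update(perturbation.as_dict())
    elif perturbation:
        spec.update(perturbation)
    pm = apply_perturbation(model, Perturbation.from_spec(model, spec))

    rng = random.Random(seed)
    uniform = initial == "uniform"
    if uniform:
        start = None
    elif initial == "damaged-proliferation":
        start = damaged_proliferation_state(model)
        start = tuple(
            pm.clamps.get(n.name, v) for n, v in zip(pm.nodes, start)
        )
    else:
        start = tuple(
            pm.clamps.get(n.name, v) for n, v in zip(pm.nodes, initial)
        )

    counts: dict[str, int] = {}
    for _ in range(n_runs):
        if uniform:
            s0 = tuple(
                pm.clamps.get(n.name, rng.randrange(n.max_level + 1))
                for n in pm.nodes
            )
        else:
            s0 = start
        res = sample_trajectory(pm, s0, rng, max_steps, cyclic_attractors)
        if not res.absorbed:
            label = CENSORED
        else:
            label = classify_attractor(markers, res.attractor, pm, strict=False).label
        counts[label] = counts.get(label, 0) + 1
    if counts.get(CENSORED, 0) == n_runs:
        raise RuntimeError(
            "every trajectory was censored; increase max_steps or supply "
            "the model's cyclic attractors"
        )
    return PhenotypeDistribution(counts, n_runs, seed, max_steps)


def classify_bistability(
    d: PhenotypeDistribution, threshold: float = 0.70
) -> str:
    """The published decision rule for senescence/apoptosis bistability:
    the scenario lowers drug resistance iff P(Apoptosis) strictly exceeds
    the threshold (default 70 %)."""
    return (
        "reduces_resistance"
        if d.probability("Apoptosis") > threshold
        else "supports_resistance"
    )
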