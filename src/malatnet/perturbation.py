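"""Phenotype calls, mutant validation, and circuit-perturbation grids.

A stable state is assigned the unique phenotype label whose marker levels
it matches exactly; cyclic attractors are labeled Oscillation.  Mutants are
gain-of-function (E1 = clamp at maximal level) or loss-of-function
(KO = clamp at 0) perturbations evaluated with the DNA-damage input ON
unless a scenario states otherwise.  Attractors of perturbed models are the
exact stable states from the pruned sweep plus any terminal cyclic
component found by bounded exploration from the quiescent initial states.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from .dynamics import Attractor, attractors, stable_states
from .model import LogicalModel, Perturbation, apply_perturbation

__all__ = [
    "ClassificationError",
    "PhenotypeCall",
    "PerturbationOutcome",
    "ValidationRow",
    "classify_attractor",
    "perturbation_attractors",
    "perturbation_outcome",
    "run_validation_suite",
    "circuit_perturbation_grid",
]

OSCILLATION = "Oscillation"
UNCLASSIFIED = "Unclassified"


class ClassificationError(ValueError):
    """A stable state matches zero or several marker patterns, which
    signals an inconsistency between the marker map and the model."""


@dataclass(frozen=True)
class PhenotypeCall:
    label: str
    attractor: Attractor


@dataclass(frozen=True)
class PerturbationOutcome:
    perturbation: Perturbation
    label: str  # human-readable perturbation label
    phenotypes: frozenset[str]
    calls: tuple[PhenotypeCall, ...]
    cyclic_search_complete: bool = True

    @property
    def bistable(self) -> bool:
        """Senescence and Apoptosis coexist: the case resolved
        by Monte-Carlo absorption probabilities."""
        return {"Senescence", "Apoptosis"} <= self.phenotypes


def classify_attractor(
    markers: Mapping[str, Mapping[str, int]],
    a: Attractor,
    model: LogicalModel,
    strict: bool = True,
) -> PhenotypeCall:
    """Match a stable state against the marker patterns (cyclic ->
    Oscillation).

    Exactly one pattern must match; zero or several matches raise
    :class:`ClassificationError` (a marker-map/model inconsistency for the
    model's own endpoints).  With ``strict=False`` an unmatched state is
    labeled ``Unclassified`` instead — clamp combinations in perturbation
    grids can force marker configurations outside the four endpoints.
    """
    if a.kind == "cyclic":
        return PhenotypeCall(OSCILLATION, a)
    levels = model.state_dict(a.state)
    matches = [
        label
        for label, req in markers.items()
        if all(levels[node] == lvl for node, lvl in req.items())
    ]
    if len(matches) != 1:
        if not strict and not matches:
            return PhenotypeCall(UNCLASSIFIED, a)
        raise ClassificationError(
            f"stable state matches {len(matches)} marker patterns "
            f"({', '.join(matches) or 'none'}): "
            + ", ".join(f"{k}={v}" for k, v in levels.items() if v)
        )
    return PhenotypeCall(matches[0], a)


def perturbation_attractors(
    model: LogicalModel,
    p: Perturbation,
    max_full: int = 2**22,
    max_states: int = 100_000,
) -> tuple[set[Attractor], bool]:
    """Attractors of the perturbed model.

    Returns ``(attractors, cyclic_search_complete)``: stable states are
    exact; the cyclic search is complete when the reachable exploration
    from the quiescent initial states terminated within ``max_states``.
    """
    pm = apply_perturbation(model, p)
    if pm.n_states <= max_full:
        return attractors(pm, max_full=max_full), True
    from .dynamics import bounded_attractors

    out = {Attractor("stable", frozenset([s])) for s in stable_states(pm)}
    found, complete = bounded_attractors(pm, max_states=max_states)
    return out | found, complete


def perturbation_outcome(
    model: LogicalModel,
    markers: Mapping[str, Mapping[str, int]],
    spec: Mapping[str, int | str],
    damage_on: bool = True,
    max_states: int = 20_000,
) -> PerturbationOutcome:
    """Clamp the requested nodes (plus DNA_damage=1 by default), compute
    attractors, and phenotype them."""
    full_spec: dict[str, int | str] = {}
    inputs = [n.name for n in model.nodes if n.is_input]
    if damage_on:
        for name in inputs:
            full_spec[name] = 1
    full_spec.update(spec)
    p = Perturbation.from_spec(model, full_spec)
    ats, complete = perturbation_attractors(model, p, max_states=max_states)
    calls = tuple(
        sorted(
            (classify_attractor(markers, a, model, strict=False) for a in ats),
            key=lambda c: c.label,
        )
    )
    label = Perturbation.from_spec(model, dict(spec)).label(model) if spec else "wild-type"
    return PerturbationOutcome(
        p, label, frozenset(c.label for c in calls), calls, complete
    )


# ---------------------------------------------------------------------------
# Published-scenario validation suite
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationRow:
    scenario: str
    perturbation: Mapping[str, str]
    expected: str
    observed: str
    passed: bool


def _has(out: PerturbationOutcome, label: str) -> bool:
    return label in out.phenotypes


def _marker_in_all(
    model: LogicalModel, out: PerturbationOutcome, node: str, level: int
) -> bool:
    stable = [c.attractor for c in out.calls if c.attractor.kind == "stable"]
    return bool(stable) and all(
        model.state_dict(a.state)[node] == level for a in stable
    )


def run_validation_suite(
    model: LogicalModel, markers: Mapping[str, Mapping[str, int]]
) -> list[ValidationRow]:
    """The published gain/loss-of-function scenarios, each with its
    expected qualitative outcome, evaluated on the damage-ON attractors."""
    scenarios = [
        ("wild-type: resistant, senescent and apoptotic endpoints coexist",
         {}, lambda o: {"DrugResistance", "Senescence", "Apoptosis"} <= o.phenotypes),
        ("MALAT1 E1: accelerates drug resistance",
         {"MALAT1": "E1"}, lambda o: _has(o, "DrugResistance")),
        ("MALAT1 KO: miR-145 up in every endpoint",
         {"MALAT1": "KO"}, lambda o: _marker_in_all(model, o, "miR-145", 1)),
        ("MALAT1 KO: KLF4 silenced in every endpoint",
         {"MALAT1": "KO"}, lambda o: _marker_in_all(model, o, "KLF4", 0)),
        ("MALAT1 KO: apoptosis restored, resistance lost",
         {"MALAT1": "KO"},
         lambda o: _has(o, "Apoptosis") and not _has(o, "DrugResistance")),
        ("miR-145 KO: drug resistance",
         {"miR-145": "KO"}, lambda o: _has(o, "DrugResistance")),
        ("miR-145 E1: prevents drug resistance",
         {"miR-145": "E1"}, lambda o: not _has(o, "DrugResistance")),
        ("miR-145 E1: senescence restored",
         {"miR-145": "E1"}, lambda o: _has(o, "Senescence")),
        ("BMI1 E1: drug resistance with Sp1 active",
         {"BMI1": "E1"},
         lambda o: _has(o, "DrugResistance")
         and any(
             model.state_dict(c.attractor.state)["Sp1"] == 1
             for c in o.calls
             if c.label == "DrugResistance"
         )),
        ("BMI1 KO: miR-145 up, Sp1 silenced, sensitivity restored",
         {"BMI1": "KO"},
         lambda o: _marker_in_all(model, o, "miR-145", 1)
         and _marker_in_all(model, o, "Sp1", 0)
         and not _has(o, "DrugResistance")),
        ("Myc E1: sustains the resistant program",
         {"Myc": "E1"}, lambda o: _has(o, "DrugResistance")),
        ("Bcl2 KO: BAX/caspase-3 apoptosis available",
         {"Bcl2": "KO"},
         lambda o: any(
             c.label == "Apoptosis"
             and model.state_dict(c.attractor.state)["BAX"] == 1
             and model.state_dict(c.attractor.state)["Caspase3"] == 1
             for c in o.calls
         )),
    ]
    rows = []
    for name, spec, check in scenarios:
        out = perturbation_outcome(model, markers, spec)
        ok = check(out)
        rows.append(
            ValidationRow(
                scenario=name,
                perturbation=dict(spec),
                expected="see scenario",
                observed="/".join(sorted(out.phenotypes)) or "(none)",
                passed=bool(ok),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Circuit-perturbation grids
# ---------------------------------------------------------------------------


def circuit_perturbation_grid(
    model: LogicalModel,
    markers: Mapping[str, Mapping[str, int]],
    circuit_nodes: Sequence[str],
    modes: Iterable[str] = ("E1", "KO"),
    include_combinations: bool = True,
    full_grid: bool = False,
    max_states: int = 20_000,
) -> list[PerturbationOutcome]:
    """Clamp combinations over one circuit's members, DNA_damage ON.

    By default this evaluates every single-node clamp and every pair, plus
    the all-KO case; ``full_grid`` switches to the complete mode assignment
    grid over the circuit (every node in {free} ∪ modes).
    """
    for n in circuit_nodes:
        model.node(n)  # raises on unknown node
    specs: list[dict[str, str]] = []
    if full_grid:
        for assign in product(("", *modes), repeat=len(circuit_nodes)):
            spec = {n: m for n, m in zip(circuit_nodes, assign) if m}
            if spec:
                specs.append(spec)
    else:
        for n in circuit_nodes:
            for m in modes:
                specs.append({n: m})
        if include_combinations:
            for i, a in enumerate(circuit_nodes):
                for b in circuit_nodes[i + 1 :]:
                    for ma in modes:
                        for mb in modes:
                            specs.append({a: ma, b: mb})
            specs.append({n: "KO" for n in circuit_nodes})
    seen: set[tuple] = set()
    out = []
    for spec in specs:
        key = tuple(sorted(spec.items()))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            perturbation_outcome(model, markers, spec, max_states=max_states)
        )
    return out


def grid_table(outcomes: Sequence[PerturbationOutcome]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "perturbation": o.label,
                "phenotypes": "+".join(sorted(o.phenotypes)),
                "bistable": o.bistable,
                "cyclic_search_complete": o.cyclic_search_complete,
            }
            for o in outcomes
        ]
    )
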