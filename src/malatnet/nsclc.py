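"""The shipped NSCLC drug-resistance model.

The network couples the MALAT1 / miR-145 / BMI1 axis to the DNA-damage
response (ATM, p53, Mdm2, Wip1, p38 MAPK) and the G1/S machinery
(Myc, E2F1, RB1, cyclin-CDK complexes), with four phenotype reporters
(Proliferation, DrugResistance, Senescence, Apoptosis).  A single Boolean
input, DNA_damage, stands for drug-induced genotoxic stress; 27 signaling
components and 85 direct interconnections sit downstream of it.  p53 is
ternary: level 1 is the arrester regime (p53-A, drives p21/senescence),
level 2 the killer regime (p53-K, drives BAX/apoptosis).

Every literature-documented interaction ships with its provenance in
``interactions.csv``; the remaining wiring completes the G1/S and
apoptosis modules and the reporter read-outs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import yaml

from .model import LogicalModel, parse_model

__all__ = [
    "InteractionRecord",
    "build_nsclc_model",
    "documented_interactions",
    "load_marker_map",
    "RULES_RESOURCE",
]

RULES_RESOURCE = "nsclc_malat1_mir145.rules"


@dataclass(frozen=True)
class InteractionRecord:
    source: str
    target: str
    sign: int  # +1 / -1
    citation: str  # reference tag, e.g. "[2]"
    note: str

    @property
    def as_triple(self) -> tuple[str, str, int]:
        return (self.source, self.target, self.sign)


def _read_text(name: str) -> str:
    return resources.files("malatnet.data").joinpath(name).read_text(encoding="utf-8")


def documented_interactions() -> tuple[InteractionRecord, ...]:
    """The literature-documented interactions, one record per direct edge."""
    out = []
    for row in csv.DictReader(_read_text("interactions.csv").splitlines()):
        out.append(
            InteractionRecord(
                source=row["source"],
                target=row["target"],
                sign=1 if row["sign"].strip() == "+" else -1,
                citation=row["citation"].strip(),
                note=row["note"].strip(),
            )
        )
    return tuple(out)


def build_nsclc_model() -> LogicalModel:
    """Parse the shipped rule file and attach per-edge provenance."""
    model = parse_model(_read_text(RULES_RESOURCE))
    citations = {
        (rec.source, rec.target): f"{rec.citation} {rec.note}"
        for rec in documented_interactions()
    }
    return model.with_citations(citations)


def load_marker_map() -> dict[str, dict[str, int]]:
    """Phenotype label -> required marker levels, from markers.yaml."""
    return yaml.safe_load(_read_text("markers.yaml"))
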