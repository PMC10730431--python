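"""Report generation: JSON/CSV/GraphML artifacts with full provenance.

Every JSON report embeds the run configuration, the package version, and
the seed, and is serialized with sorted keys so that re-running an
identical configuration reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__ as _version
from .circuits import CircuitCensus
from .dynamics import Attractor
from .model import LogicalModel, serialize_model

__all__ = [
    "RunConfig",
    "attractor_report",
    "census_report",
    "write_json",
    "export_graphml",
    "export_edge_list",
    "export_stg",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; embedded in every report."""

    model_path: str = "(builtin NSCLC model)"
    command: str = ""
    perturbation: dict[str, str] = field(default_factory=dict)
    n_runs: int = 10_000
    seed: int = 0
    max_steps: int = 10_000
    bistability_threshold: float = 0.70
    max_full_states: int = 2**22
    max_explored_states: int = 20_000
    output_dir: str = "."

    def provenance(self) -> dict:
        return {"config": asdict(self), "package_version": _version}


def attractor_report(model: LogicalModel, ats: Sequence[Attractor]) -> list[dict]:
    out = []
    for a in sorted(ats, key=lambda a: (a.kind, sorted(a.states))):
        out.append(
            {
                "kind": a.kind,
                "phenotype": a.phenotype,
                "states": [model.state_dict(s) for s in sorted(a.states)],
            }
        )
    return out


def census_report(census: CircuitCensus) -> dict:
    return {
        "total_circuits": census.total_circuits,
        "total_functional": census.total_functional,
        "functional_by_sign": census.functional_by_sign,
        "functional_by_length": {str(k): v for k, v in census.functional_by_length.items()},
        "functional_with_at_most_4_components": census.n_functional_short,
        "functional_short_circuits": ["/".join(c.nodes) for c in census.functional_short],
    }


def write_json(path: str | Path, payload: Mapping[str, Any]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    return path


def export_graphml(model: LogicalModel, path: str | Path) -> Path:
    import networkx as nx

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(model.to_networkx(), path)
    return path


def export_edge_list(model: LogicalModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    model.edge_table().to_csv(path, index=False)
    return path


def export_stg(stg, path: str | Path, model: LogicalModel) -> Path:
    """Edge-list CSV of an explicit STG; truncation noted in a header row."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "source": model.pack(a),
            "target": model.pack(b),
            "source_state": "".join(map(str, a)),
            "target_state": "".join(map(str, b)),
        }
        for a, b in sorted(stg.transitions)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "source_state", "target_state"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# truncated={stg.truncated} states={len(stg.states)}\n")
        df.to_csv(fh, index=False)
    return path


def export_model(model: LogicalModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(serialize_model(model), encoding="utf-8")
    return path
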