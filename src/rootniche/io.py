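"""Readers and writers for the package's tabular interchange formats.

All tables are plain CSV with documented headers: parameter tables
(``name,value``), 5-day FPKM tables (``species,cell_type,fpkm``),
fold-change tables (``species,time_h,fold_change``), tidy time courses
(``species,cell_type,time_h,fpkm``), trajectory exports
(``time,agent,species,value`` plus an ``agent,time`` event list) and
Cytoscape-style node/edge tables.  Run manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingParameterError
from .fitting import TimeCourse
from .model import ParameterSet, required_parameter_names
from .network import GeneNetwork
from .simulate import Trajectory

__all__ = [
    "read_parameter_table",
    "write_parameter_table",
    "read_fpkm_table",
    "read_foldchange_table",
    "read_timecourse",
    "write_timecourse",
    "write_trajectory",
    "read_network_tables",
    "write_impact_table",
    "run_manifest",
]


def read_parameter_table(path, variant: str | None = None) -> ParameterSet:
    """Read a ``name,value`` CSV into a validated :class:`ParameterSet`.

    With ``variant`` given, the table is checked against that variant's
    registry: unknown names are rejected (naming the offender) and missing
    required names raise :class:`MissingParameterError`.
    """
    frame = pd.read_csv(path)
    if not {"name", "value"}.issubset(frame.columns):
        raise ConfigurationError(f"{path}: parameter table needs 'name,value' header")
    try:
        values = {
            str(row.name): float(row.value)
            for row in frame.itertuples(index=False)
        }
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: non-numeric parameter value ({exc})") from exc
    params = ParameterSet(values)
    if variant is not None:
        registry = set(required_parameter_names("repressorx"))
        unknown = sorted(set(values) - registry)
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown parameter name(s): {', '.join(unknown)}"
            )
        params.require(required_parameter_names(variant))
    return params


def write_parameter_table(params: ParameterSet, path) -> None:
    frame = pd.DataFrame(
        sorted(params.to_dict().items()), columns=["name", "value"]
    )
    frame.to_csv(path, index=False)


def read_fpkm_table(path) -> dict[tuple[str, str], float]:
    """5-day FPKM CSV ``species,cell_type,fpkm`` -> mapping."""
    frame = pd.read_csv(path)
    if not {"species", "cell_type", "fpkm"}.issubset(frame.columns):
        raise ConfigurationError(f"{path}: needs 'species,cell_type,fpkm' header")
    return {
        (str(r.species), str(r.cell_type)): float(r.fpkm)
        for r in frame.itertuples(index=False)
    }


def read_foldchange_table(path) -> dict[tuple[str, float], float]:
    """Fold-change CSV ``species,time_h,fold_change`` -> mapping."""
    frame = pd.read_csv(path)
    if not {"species", "time_h", "fold_change"}.issubset(frame.columns):
        raise ConfigurationError(f"{path}: needs 'species,time_h,fold_change' header")
    return {
        (str(r.species), float(r.time_h)): float(r.fold_change)
        for r in frame.itertuples(index=False)
    }


def read_timecourse(path, provenance: str = "measured") -> TimeCourse:
    frame = pd.read_csv(path)
    return TimeCourse(frame, provenance=provenance)


def write_timecourse(tc: TimeCourse, path) -> None:
    tc.frame.to_csv(path, index=False)


def write_trajectory(traj: Trajectory, out_dir, seed=None) -> dict:
    """Export a trajectory: tidy states CSV, events CSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = traj.model.state_labels
    rows = []
    for i, t in enumerate(traj.times):
        for j, label in enumerate(labels):
            species, agent = label.rsplit("_", 1)
            rows.append(
                {
                    "time": t,
                    "agent": agent.upper(),
                    "species": species,
                    "value": traj.states[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(out / "trajectory.csv", index=False)
    pd.DataFrame(
        [{"agent": e.agent.value, "time": e.time} for e in traj.events]
    ).to_csv(out / "events.csv", index=False)
    manifest = run_manifest(
        variant=traj.variant,
        seed=seed,
        solver=traj.solver_report,
        parameters=traj.model.params.to_dict(),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_network_tables(node_path, edge_path) -> GeneNetwork:
    return GeneNetwork.from_cytoscape_tables(
        pd.read_csv(node_path), pd.read_csv(edge_path)
    )


def write_impact_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def run_manifest(**entries) -> dict:
    """Manifest with a deterministic content hash of its own entries."""

    def _clean(v):
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in sorted(v.items())}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    payload = _clean(entries)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["config_hash"] = digest
    return payload
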