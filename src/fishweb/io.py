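"""Output bundles: serialized webs, tables, config echo and a manifest.

A run bundle is a directory whose every summary number can be
recomputed from the bundle contents alone; the manifest records a
SHA-256 hash per emitted file so identical seeds give identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lifehistory import Community, leslie_matrix
from .dynamics import StateTrajectory
from .experiment import EnsembleResult

__all__ = [
    "staged_to_json",
    "trajectory_to_frame",
    "write_run_bundle",
    "write_ensemble_bundle",
]


def staged_to_json(community: Community) -> str:
    """Staged-web JSON: niche triples per node plus the node -> (species,
    stage) map and per-stage masses; the Leslie matrix is echoed for
    audit."""
    record = {
        "nodes": [
            {
                "id": i,
                "species": int(community.species[i]),
                "stage": int(community.stage[i]),
                "guild": str(community.guild[i]),
                "n": float(community.n[i]),
                "r": float(community.r[i]),
                "c": float(community.c[i]),
                "mass": float(community.M[i]),
                "x": float(community.x[i]),
            }
            for i in range(community.size)
        ],
        "links": [[int(i), int(j)] for i, j in zip(*np.nonzero(community.A))],
        "fish_species": list(map(int, community.fish_species)),
        "leslie_matrix": leslie_matrix().tolist(),
    }
    return json.dumps(record, indent=1)


def trajectory_to_frame(
    traj: StateTrajectory, run_id: str, daily: bool = False
) -> pd.DataFrame:
    """Long-format trajectory table (run_id, node_id, species_id, stage,
    year, day, biomass); annual year-end rows, or daily rows when the
    run recorded them."""
    rows = []
    n_nodes = traj.year_end.shape[1]
    if daily and traj.daily is not None:
        samples_per_year = traj.daily.shape[0] // traj.years
        for k in range(traj.daily.shape[0]):
            year, day = divmod(k, samples_per_year)
            for node in range(n_nodes):
                rows.append((run_id, node, int(traj.node_species[node]),
                             int(traj.node_stage[node]), year, day,
                             traj.daily[k, node]))
    else:
        for year in range(traj.years):
            for node in range(n_nodes):
                rows.append((run_id, node, int(traj.node_species[node]),
                             int(traj.node_stage[node]), year, -1,
                             traj.year_end[year, node]))
    return pd.DataFrame(
        rows,
        columns=["run_id", "node_id", "species_id", "stage", "year", "day",
                 "biomass"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_run_bundle(
    out_dir: str | Path,
    files: dict[str, str | pd.DataFrame],
    failed_runs: list | None = None,
) -> dict:
    """Write named files (text or DataFrame -> CSV) plus manifest.json
    listing every emitted file with its SHA-256 hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, content in files.items():
        path = out / name
        if isinstance(content, pd.DataFrame):
            content.to_csv(path, index=False)
        else:
            path.write_text(content)
        entries[name] = _sha256(path)
    manifest = {"files": entries, "failed_runs": failed_runs or []}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_ensemble_bundle(result: EnsembleResult, out_dir: str | Path) -> dict:
    """Persist an ensemble: per-run and per-species tables, survivor
    frequencies, regressions, headline metrics, config echo and seed
    record."""
    cfg = dataclasses.asdict(result.config)
    files: dict[str, str | pd.DataFrame] = {
        "runs.csv": result.runs,
        "species.csv": result.species,
        "survivor_frequencies.csv": result.survivor_freq.reset_index(),
        "headline.json": json.dumps(result.headline, indent=1),
        "config.yaml": yaml.safe_dump(cfg, sort_keys=False),
        "seed.json": json.dumps({"seed": result.config.seed}),
    }
    if result.regressions is not None:
        files["regressions.csv"] = result.regressions
    failed = (
        result.runs.loc[~result.runs["completed"], ["web_id", "model_type"]]
        .to_dict("records")
        if len(result.runs)
        else []
    )
    return write_run_bundle(out_dir, files, failed_runs=failed)
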