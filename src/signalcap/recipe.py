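"""End-to-end experiment recipes: simulate → normalize → analyze.

A recipe is a named sequence of stages forming a DAG: each stage may consume
the outputs of earlier stages (``uses``) and may write a file (``out``).
Stage kinds cover the pipeline surface: trajectory simulation, fold-change
normalization, bootstrap summaries, peak statistics, pathway contribution,
decoder-based MI/capacity, snapshot simulation, EMD matrices and threshold
reports.  Reruns with the same recipe (and seed) reproduce all numeric
outputs; a manifest records the package version, config hash, per-stage
seeds and filter drop counts.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, NumericalError, SignalCapError
from .info import FeatureSpec, build_response_matrix, bootstrap_diagnostics
from .io import config_hash, load_config, write_json, write_snapshot_csv, write_trajectory_csv
from .shift import emd_matrix, embed_emd, threshold_report
from .simulate import SimConfig, simulate_snapshot, simulate_trajectories, simulate_ktr_trajectories
from .trajectories import (
    NormalizationSpec,
    normalize_fold_change,
    pathway_contribution,
    peak_fold_change,
    summarize_mean_ci,
)
from .types import SnapshotSample, TrajectorySet

logger = logging.getLogger(__name__)

RECIPE_KEYS = {"name", "seed", "stages"}
STAGE_KEYS = {"name", "kind", "params", "uses", "out"}


def bundled_recipe_path(name: str) -> Path:
    """Path of a recipe shipped with the package (e.g. three_dose_capacity)."""
    root = importlib.resources.files("signalcap") / "recipes" / f"{name}.yaml"
    if not root.is_file():
        raise ConfigurationError(f"no bundled recipe named {name!r}")
    return Path(str(root))


def validate_recipe(recipe: dict) -> None:
    unknown = set(recipe) - RECIPE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown recipe keys: {sorted(unknown)}")
    stages = recipe.get("stages")
    if not stages:
        raise ConfigurationError("recipe has no stages")
    seen: set[str] = set()
    for stage in stages:
        unknown = set(stage) - STAGE_KEYS
        if unknown:
            raise ConfigurationError(
                f"stage {stage.get('name')!r}: unknown keys {sorted(unknown)}"
            )
        name = stage.get("name")
        if not name or name in seen:
            raise ConfigurationError(f"missing or duplicate stage name {name!r}")
        for dep in stage.get("uses", []):
            if dep not in seen:
                raise ConfigurationError(
                    f"stage {name!r} uses {dep!r}, which is not an earlier "
                    "stage — stages must form a DAG in execution order"
                )
        seen.add(name)


def _stage_seed(recipe_seed: int, index: int, params: dict) -> int:
    if "seed" in params:
        return int(params["seed"])
    return int(recipe_seed) + 1000 * (index + 1)


def _write_output(result, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, TrajectorySet):
        write_trajectory_csv(result, path)
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path)
    elif isinstance(result, list) and result and isinstance(result[0], SnapshotSample):
        write_snapshot_csv(result, path)
    elif isinstance(result, dict):
        write_json(result, path)
    else:
        raise ConfigurationError(f"cannot serialize stage result of type {type(result)}")


def run_recipe(recipe: dict, outdir) -> dict:
    """Execute a validated recipe; returns the run manifest."""
    validate_recipe(recipe)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recipe_seed = int(recipe.get("seed", 0))
    results: dict[str, object] = {}
    manifest = {
        "recipe": recipe.get("name", "unnamed"),
        "version": __version__,
        "config_hash": config_hash(recipe),
        "seed": recipe_seed,
        "stages": [],
        "outputs": [],
    }
    for index, stage in enumerate(recipe["stages"]):
        name = stage["name"]
        kind = stage["kind"]
        params = dict(stage.get("params", {}))
        uses = [results[d] for d in stage.get("uses", [])]
        seed = _stage_seed(recipe_seed, index, params)
        params.pop("seed", None)
        try:
            result = _run_stage(kind, params, uses, seed)
        except SignalCapError as err:
            raise type(err)(f"stage {name!r} ({kind}) failed: {err}") from err
        except Exception as err:
            raise NumericalError(f"stage {name!r} ({kind}) failed: {err}") from err
        results[name] = result
        entry = {"name": name, "kind": kind, "seed": seed}
        if isinstance(result, TrajectorySet):
            entry["n_cells"] = result.n_cells
        manifest["stages"].append(entry)
        if stage.get("out"):
            out_path = outdir / stage["out"]
            _write_output(result, out_path)
            manifest["outputs"].append(str(out_path))
    write_json(manifest, outdir / "manifest.json")
    return manifest


def _concat_trajectories(sets: list[TrajectorySet]) -> TrajectorySet:
    grid = sets[0].time_s
    for ts in sets[1:]:
        if not np.array_equal(ts.time_s, grid):
            raise ConfigurationError("cannot concatenate: mismatched time grids")
    values = np.vstack([ts.values for ts in sets])
    meta = pd.concat([ts.meta for ts in sets], ignore_index=True)
    meta["cell_id"] = [f"cell_{i:06d}" for i in range(len(meta))]
    return TrajectorySet(grid, values, meta)


def _info_stage(kind: str, params: dict, traj: TrajectorySet, seed: int) -> dict:
    feature = FeatureSpec(
        mode=params.get("mode", "trajectory"),
        time=params.get("time"),
        times=params.get("times"),
    )
    label_by = tuple(params.get("label_by", ("stimulus", "dose")))
    Z, S = build_response_matrix(traj, feature, label_by=label_by)
    est = bootstrap_diagnostics(
        Z,
        S,
        estimator=kind,
        n_boot=int(params.get("n_boot", 40)),
        frac=float(params.get("frac", 0.8)),
        seed=seed,
        regularization=params.get("regularization"),
        cv=int(params.get("cv", 5)),
    )
    return {"estimator": kind, **est.to_dict()}


def _run_stage(kind: str, params: dict, uses: list, seed: int):
    if kind == "simulate":
        return simulate_trajectories(SimConfig(**params, seed=seed))
    if kind == "simulate_ktr":
        from .simulate import ktr_config

        return simulate_ktr_trajectories(ktr_config(**params, seed=seed))
    if kind == "read":
        from .io import read_trajectory_csv

        return read_trajectory_csv(params["path"])
    if kind == "concat":
        return _concat_trajectories(uses)
    if kind == "normalize":
        return normalize_fold_change(uses[0], NormalizationSpec(**params))
    if kind == "summarize":
        series = summarize_mean_ci(uses[0], seed=seed, **params)
        return series.to_frame()
    if kind == "peaks":
        stats = peak_fold_change(uses[0])
        return {
            "mean_trace_peak": stats["mean_trace_peak"],
            "peak_time_min": stats["peak_time_min"],
            "n_cells": uses[0].n_cells,
        }
    if kind == "contribution":
        window = tuple(params.get("window", (40.0, 60.0)))
        pct = pathway_contribution(
            uses[0], uses[1], phase_window=window,
            per_cell=bool(params.get("per_cell", False)),
        )
        return {"contribution_percent": pct, "window_min": list(window)}
    if kind in ("mi", "capacity"):
        return _info_stage(kind, params, uses[0], seed)
    if kind == "snapshot":
        conditions = params["conditions"]
        n_cells = int(params.get("n_cells", 500))
        return [
            simulate_snapshot(spec, n_cells, seed + i)
            for i, spec in enumerate(conditions)
        ]
    if kind == "emd":
        return emd_matrix(
            uses[0],
            params["reference"],
            markers=params.get("markers"),
            cofactor=float(params.get("cofactor", 5.0)),
            signed=bool(params.get("signed", False)),
        )
    if kind == "embed":
        return embed_emd(
            uses[0],
            backend=params.get("backend", "mds"),
            seed=seed,
        )
    if kind == "threshold":
        report = threshold_report(
            uses[0],
            params["marker"],
            params["reference"],
            q=float(params.get("q", 95.0)),
            cofactor=float(params.get("cofactor", 5.0)),
        )
        return report.to_dict()
    raise ConfigurationError(f"unknown stage kind {kind!r}")


def run_recipe_file(path, outdir) -> dict:
    return run_recipe(load_config(path), outdir)
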