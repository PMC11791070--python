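"""File formats: long-format trajectory CSV, snapshot tables, YAML configs.

The canonical interchange format is delimited text.  Trajectories travel as
long-format CSV with columns ``cell_id, genotype, stimulus, dose, time_s,
value``; snapshots as one row per cell with condition columns plus marker
columns.  FCS ingestion is an optional adapter that requires the
``fcsparser`` package.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .types import META_COLUMNS, SnapshotSample, TrajectorySet

#: columns that identify a snapshot condition rather than a marker
CONDITION_COLUMNS = ("condition", "genotype", "stimulus", "dose", "time", "inhibitor")


def write_trajectory_csv(traj: TrajectorySet, path) -> None:
    traj.to_long_frame().to_csv(path, index=False)


def read_trajectory_csv(path) -> TrajectorySet:
    """Read and validate a long-format trajectory CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    required = set(META_COLUMNS) | {"time_s", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return TrajectorySet.from_long_frame(frame)


def write_snapshot_csv(snapshots: list[SnapshotSample], path) -> None:
    """One row per cell; condition labels in a `condition` column."""
    frames = []
    for snap in snapshots:
        frame = snap.marker_values.copy()
        frame.insert(0, "condition", snap.label())
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_snapshot_table(path, format: str = "csv") -> list[SnapshotSample]:
    """Read per-condition snapshot samples from CSV (canonical) or FCS.

    CSV: a ``condition`` column (or any of the standard condition columns)
    groups cells; every remaining column is a marker.  FCS requires the
    optional ``fcsparser`` dependency and yields a single sample per file.
    """
    path = Path(path)
    if format == "fcs":
        try:
            import fcsparser  # type: ignore
        except ImportError as err:
            raise ConfigurationError(
                "FCS ingestion requires the optional 'fcsparser' package"
            ) from err
        _, frame = fcsparser.parse(str(path))
        return [SnapshotSample({"file": path.name}, frame)]
    if format != "csv":
        raise ConfigurationError(f"unknown snapshot format {format!r}")
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise SchemaError(f"{path}: empty snapshot table")
    group_cols = [c for c in CONDITION_COLUMNS if c in frame.columns]
    if not group_cols:
        raise SchemaError(
            f"{path}: no condition column found (expected one of "
            f"{CONDITION_COLUMNS})"
        )
    marker_cols = [c for c in frame.columns if c not in group_cols]
    if not marker_cols:
        raise SchemaError(f"{path}: no marker columns")
    samples = []
    for key, group in frame.groupby(group_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        condition = dict(zip(group_cols, map(str, key)))
        samples.append(SnapshotSample(condition, group[marker_cols].reset_index(drop=True)))
    return samples


def apply_marker_mapping(
    snapshots: list[SnapshotSample], mapping: dict[str, str]
) -> list[SnapshotSample]:
    """Rename instrument channel names to marker names (e.g. FCS panels)."""
    out = []
    for snap in snapshots:
        unknown = set(mapping) - set(snap.marker_values.columns)
        if unknown:
            raise ConfigurationError(f"unknown marker mapping keys: {sorted(unknown)}")
        out.append(
            SnapshotSample(snap.condition, snap.marker_values.rename(columns=mapping))
        )
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path, allowed_keys: set[str] | None = None) -> dict:
    """Load a YAML/JSON config; strict mode rejects unknown keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(config) - allowed_keys
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config keys {sorted(unknown)} "
                f"(allowed: {sorted(allowed_keys)})"
            )
    return config


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, recorded in run manifests."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
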