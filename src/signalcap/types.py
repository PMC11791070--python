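"""Core in-memory containers shared by the simulation and analysis layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: metadata columns every TrajectorySet carries, in canonical order
META_COLUMNS = ("cell_id", "genotype", "stimulus", "dose")


@dataclass
class TrajectorySet:
    """Labeled single-cell time series on a shared time grid.

    Parameters
    ----------
    time_s:
        Strictly increasing sample times in seconds, shared by every cell.
    values:
        Array of shape ``(n_cells, n_time)``; NaN marks missing samples.
    meta:
        One row per cell with at least the :data:`META_COLUMNS` columns.
    """

    time_s: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.ndim != 1 or np.any(np.diff(self.time_s) <= 0):
            raise SchemaError("time grid must be 1-D and strictly increasing")
        if self.values.ndim != 2 or self.values.shape[1] != self.time_s.size:
            raise SchemaError(
                f"values shape {self.values.shape} incompatible with "
                f"{self.time_s.size}-point time grid"
            )
        if len(self.meta) != self.values.shape[0]:
            raise SchemaError("meta must have one row per cell")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"meta missing columns: {missing}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.time_s.size

    @property
    def time_min(self) -> np.ndarray:
        """Time grid in minutes."""
        return self.time_s / 60.0

    def select(self, index: np.ndarray) -> "TrajectorySet":
        """Subset of cells (boolean mask or integer index array)."""
        index = np.asarray(index)
        return TrajectorySet(
            self.time_s, self.values[index], self.meta.iloc[np.atleast_1d(index)]
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (cell, time point)."""
        n_c, n_t = self.values.shape
        rep = self.meta.loc[self.meta.index.repeat(n_t)].reset_index(drop=True)
        rep["time_s"] = np.tile(self.time_s, n_c)
        rep["value"] = self.values.ravel()
        return rep

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "TrajectorySet":
        """Inverse of :meth:`to_long_frame`; rejects ragged time grids."""
        required = set(META_COLUMNS) | {"time_s", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        if not np.issubdtype(np.asarray(frame["time_s"]).dtype, np.number):
            raise SchemaError("non-numeric time_s column")
        grids = frame.groupby("cell_id", sort=False)["time_s"].apply(tuple)
        if grids.empty:
            raise SchemaError("empty trajectory table")
        reference = grids.iloc[0]
        offenders = grids.index[grids != reference].tolist()
        if offenders:
            raise SchemaError(
                f"cells on mismatched time grids: {offenders}"
            )
        time_s = np.asarray(reference, dtype=float)
        cells = frame.groupby("cell_id", sort=False)
        values = np.vstack([g["value"].to_numpy(dtype=float) for _, g in cells])
        meta = cells.first().reset_index()[list(META_COLUMNS)]
        return cls(time_s, values, meta)


@dataclass
class SnapshotSample:
    """Cytometry-style snapshot: one row per cell, one column per marker.

    ``condition`` identifies stimulus, dose, genotype, time point and
    inhibitor status; ``marker_values`` holds nonnegative raw intensities.
    """

    condition: dict
    marker_values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.marker_values.columns)
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate marker names")
        vals = self.marker_values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise SchemaError("marker intensities must be nonnegative")

    @property
    def markers(self) -> list[str]:
        return list(self.marker_values.columns)

    @property
    def n_cells(self) -> int:
        return len(self.marker_values)

    def label(self) -> str:
        """Stable condition identifier used in EMD matrices and reports."""
        return "|".join(f"{k}={self.condition[k]}" for k in sorted(self.condition))


@dataclass
class SummarySeries:
    """Population mean trace with bootstrap confidence band."""

    time_s: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_cells: int
    n_boot: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "mean": self.mean,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )
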