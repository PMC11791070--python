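"""Pixel- and track-level quantification of translocation-reporter images.

Implements the KTR measurement convention: mean nuclear intensity in a
5×5-pixel square around the tracked centroid; cytoplasmic intensity as the
mean of the brightest 50% of pixels in a 2-px ring around the nuclear mask
(robust against background pixels in thin, elongated cells); and the
cytoplasmic fraction

    CN_R = KTR_cyto / (KTR_nuc + KTR_cyto)

bounded by 0 (fully nuclear reporter, low AKT activity) and 1 (complete
nuclear exclusion, high AKT activity).  Quality filters remove short tracks,
small (debris) objects, saturated cells and trajectories containing missing
values.  Segmentation and tracking themselves are inputs, not implemented.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MeasurementError

#: default quality-filter settings for 12-bit image data
SATURATION_LIMIT = 4000
MIN_OBJECT_SIZE = 50


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def measure_nuclear_square(
    intensity_image: np.ndarray, centroid: tuple[float, float]
) -> float:
    """Mean intensity of the 5×5 pixel square centered on the centroid.

    ``centroid`` is (row, col), 0-based; it is rounded to the nearest pixel
    (halves away from zero).  The full square must fit inside the image,
    i.e. the rounded centroid must be at least 2 px from every border.
    """
    img = np.asarray(intensity_image)
    r = _round_half_away(float(centroid[0]))
    c = _round_half_away(float(centroid[1]))
    if r < 2 or c < 2 or r > img.shape[0] - 3 or c > img.shape[1] - 3:
        raise MeasurementError(
            f"centroid ({centroid[0]}, {centroid[1]}) too close to image border"
        )
    return float(img[r - 2 : r + 3, c - 2 : c + 3].mean())


#: 8-connected structuring element; applied twice for the 2-px expansion
_STRUCT = np.ones((3, 3), dtype=bool)


def cytoplasmic_ring(nuclear_mask: np.ndarray) -> np.ndarray:
    """2-px cytoplasmic ring: dilate the nuclear mask by 2, subtract it."""
    mask = np.asarray(nuclear_mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    expanded = ndimage.binary_dilation(mask, structure=_STRUCT, iterations=2)
    return expanded & ~mask


def measure_ring_brightest_half(
    intensity_image: np.ndarray, ring_mask: np.ndarray
) -> float:
    """Mean of the brightest 50% (ceil(n/2)) of ring pixels; NaN if empty."""
    ring = np.asarray(ring_mask).astype(bool)
    pixels = np.asarray(intensity_image, dtype=float)[ring]
    n = pixels.size
    if n == 0:
        return float("nan")
    k = (n + 1) // 2
    top = np.partition(pixels, n - k)[n - k :]
    return float(top.mean())


def compute_cnr(ktr_nuc, ktr_cyto):
    """Cytoplasmic fraction ``cyto / (nuc + cyto)``; NaN when both are zero.

    Accepts scalars or arrays; negative intensities are invalid.
    """
    nuc = np.asarray(ktr_nuc, dtype=float)
    cyto = np.asarray(ktr_cyto, dtype=float)
    if np.any(nuc < 0) or np.any(cyto < 0):
        raise MeasurementError("intensities must be nonnegative")
    total = nuc + cyto
    with np.errstate(invalid="ignore", divide="ignore"):
        cnr = np.where(total > 0, cyto / total, np.nan)
    return float(cnr) if cnr.ndim == 0 else cnr


#: columns checked for saturation and missing values by filter_tracks
_INTENSITY_COLUMNS = ("nuc", "cyto")


def filter_tracks(
    tracks: pd.DataFrame,
    n_timepoints: int,
    saturation_limit: float = SATURATION_LIMIT,
    min_size: int = MIN_OBJECT_SIZE,
) -> pd.DataFrame:
    """Apply the track-quality filters; returns the surviving subset.

    A cell is removed if its track is shorter than ``n_timepoints``, any of
    its objects is smaller than ``min_size`` pixels (strict: exactly
    ``min_size`` is kept), any intensity exceeds ``saturation_limit`` at any
    time point, or any measured value is missing.  Filtering is total and
    idempotent.
    """
    if tracks.empty:
        return tracks.copy()
    value_cols = [c for c in _INTENSITY_COLUMNS if c in tracks.columns]

    def keep(group: pd.DataFrame) -> bool:
        if len(group) < n_timepoints:
            return False
        if "size_px" in group.columns and (group["size_px"] < min_size).any():
            return False
        for col in value_cols:
            if group[col].isna().any() or (group[col] > saturation_limit).any():
                return False
        if "cnr" in group.columns and group["cnr"].isna().any():
            return False
        return True

    kept = [cid for cid, g in tracks.groupby("cell_id", sort=False) if keep(g)]
    return tracks[tracks["cell_id"].isin(kept)].copy()


def footprint_mean_series(
    intensity_stack: np.ndarray, footprint_mask: np.ndarray
) -> np.ndarray:
    """Per-frame mean intensity within a fixed footprint ROI (TIRF modality)."""
    stack = np.asarray(intensity_stack, dtype=float)
    mask = np.asarray(footprint_mask).astype(bool)
    if stack.ndim != 3 or stack.shape[1:] != mask.shape:
        raise MeasurementError(
            f"stack spatial shape {stack.shape[1:]} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise MeasurementError("empty footprint mask")
    return stack[:, mask].mean(axis=1)


def measure_cell(
    intensity_image: np.ndarray,
    nuclear_label_mask: np.ndarray,
    label: int,
    centroid: tuple[float, float],
) -> dict:
    """Full single-cell KTR measurement: nuclear square, ring, CN_R."""
    nuc = measure_nuclear_square(intensity_image, centroid)
    ring = cytoplasmic_ring(nuclear_label_mask == label)
    cyto = measure_ring_brightest_half(intensity_image, ring)
    cnr = float("nan") if math.isnan(cyto) else compute_cnr(nuc, cyto)
    return {"nuc": nuc, "cyto": cyto, "cnr": cnr}
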