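"""Synthetic microscopy fixtures: labeled nuclei with known ground truth.

Cells are rendered as concentric discs — a nuclear disc inside a cytoplasmic
disc — with uniform compartment intensities, so every downstream pixel
measurement has an analytically known expected value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LayoutError


@dataclass
class CellSpec:
    """One synthetic cell: concentric nuclear/cytoplasmic discs."""

    center: tuple[float, float]  # (row, col), pixels
    nucleus_radius: float
    cyto_radius: float
    nuc_intensity: float
    cyto_intensity: float

    def ground_truth_cnr(self) -> float:
        total = self.nuc_intensity + self.cyto_intensity
        return self.cyto_intensity / total if total > 0 else np.nan


def render_synthetic_cell_image(
    layout_spec: dict,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render an intensity image, nuclear label mask and ground-truth table.

    ``layout_spec``: ``{"shape": (H, W), "background": float, "noise_sd": float,
    "cells": [CellSpec or dict, ...]}``.  Cytoplasmic discs must not overlap
    (2-px ring margin included); intensities are clipped to the 12-bit range
    and returned as uint16.

    Returns ``(intensity_image, nuclear_label_mask, centroids)`` where
    ``centroids`` carries per-cell label, centroid, compartment intensities
    and the ground-truth CN_R for assertions.
    """
    shape = tuple(layout_spec.get("shape", (128, 128)))
    background = float(layout_spec.get("background", 0.0))
    noise_sd = float(layout_spec.get("noise_sd", 0.0))
    cells = [
        c if isinstance(c, CellSpec) else CellSpec(**c)
        for c in layout_spec.get("cells", [])
    ]

    # reject overlap including the 2-px cytoplasmic ring margin
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            ci, cj = cells[i], cells[j]
            dist = np.hypot(
                ci.center[0] - cj.center[0], ci.center[1] - cj.center[1]
            )
            if dist < ci.cyto_radius + cj.cyto_radius + 2.0:
                raise LayoutError(f"cells {i} and {j} overlap (distance {dist:.1f})")

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    image = np.full(shape, background, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    records = []
    for k, cell in enumerate(cells, start=1):
        d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
        cyto = d2 <= cell.cyto_radius**2
        nuc = d2 <= cell.nucleus_radius**2
        image[cyto] = cell.cyto_intensity
        image[nuc] = cell.nuc_intensity
        labels[nuc] = k
        records.append(
            {
                "label": k,
                "row": cell.center[0],
                "col": cell.center[1],
                "nuc_intensity": cell.nuc_intensity,
                "cyto_intensity": cell.cyto_intensity,
                "cnr_truth": cell.ground_truth_cnr(),
            }
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=shape)
    image = np.clip(np.rint(image), 0, 4095).astype(np.uint16)
    columns = ["label", "row", "col", "nuc_intensity", "cyto_intensity", "cnr_truth"]
    centroids = pd.DataFrame(records, columns=columns)
    return image, labels, centroids
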