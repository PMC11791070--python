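"""Reference analysis scenarios binding the pipeline end to end.

Each function reconstructs one of the package's headline computations from
scratch — simulate, normalize, estimate — under the calibrated study
conditions, and returns the resulting number together with the problem size.
They are used by the verification suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .info import build_response_matrix, channel_capacity, fit_decoder
from .recipe import _concat_trajectories
from .simulate import SimConfig, simulate_trajectories
from .trajectories import normalize_fold_change, pathway_contribution, peak_fold_change

#: 1 nM / 10 nM / 100 nM dose classes with widely separated response
#: amplitudes (plateau fold-change elevations 1, 2, 3) and negligible noise:
#: a perfectly distinguishable three-input channel
SEPARABLE_DOSE_AMPLITUDES = {1.0: 1.0, 10.0: 2.0, 100.0: 3.0}


def three_dose_capacity_bits(seed: int = 1, n_cells: int = 500) -> tuple[float, int]:
    """Capacity (bits) of a perfectly separable three-dose trajectory channel.

    Returns ``(capacity_bits, n_cells_total)``.  The ceiling for three
    distinguishable inputs is log2(3) ~ 1.585 bits.
    """
    sets = []
    for i, (dose, amp) in enumerate(sorted(SEPARABLE_DOSE_AMPLITUDES.items())):
        cfg = SimConfig(
            stimulus="IGF1",
            dose=dose,
            peak_amplitude=amp,
            heterogeneity_cv=0.0,
            noise_sd=0.01,
            n_cells=n_cells,
            seed=seed * 17 + i,
        )
        sets.append(simulate_trajectories(cfg))
    traj = normalize_fold_change(_concat_trajectories(sets))
    Z, S = build_response_matrix(traj, label_by=("dose",))
    decoder = fit_decoder(Z, S, seed=seed)
    estimate = channel_capacity(decoder, Z, S, seed=seed)
    return estimate.bits, Z.shape[0]


def tirf_design_datapoint_count(n_cells: int = 60, seed: int = 1) -> tuple[int, int]:
    """Cell x time-point count of the 60-min / 70-s live-imaging design.

    One measurement per cell per frame: 60 cells over 52 frames exceed 3000
    individual data points.  Returns ``(n_datapoints, n_cells)``.
    """
    traj = simulate_trajectories(SimConfig(n_cells=n_cells, seed=seed))
    Z, _ = build_response_matrix(traj)
    return int(Z.size), n_cells


def calibrated_peak_fold_change(
    peak_amplitude: float, seed: int = 1, n_cells: int = 1000
) -> tuple[float, int]:
    """Mean-trace peak after first-four-median normalization.

    WT calibrations: peak_amplitude 0.55 (IGF1-like) or 0.25 (EGF-like) above
    baseline 1.0, heterogeneity CV 0.2, noise SD 0.02.
    """
    cfg = SimConfig(
        peak_amplitude=peak_amplitude,
        heterogeneity_cv=0.2,
        noise_sd=0.02,
        n_cells=n_cells,
        seed=seed,
    )
    traj = normalize_fold_change(simulate_trajectories(cfg))
    return peak_fold_change(traj)["mean_trace_peak"], n_cells


def contribution_recovery(
    residual_fraction: float, seed: int = 1, n_cells: int = 500
) -> tuple[float, int]:
    """Isoform-contribution percentage recovered from an inhibitor arm.

    Simulates a reference arm and a perturbed arm whose sustained elevation
    is ``residual_fraction`` of reference (inhibitor at 15 min), normalizes
    both, and evaluates the contribution over the 40-60 min window.  The
    ground truth is ``(1 - residual_fraction) * 100``.
    """
    base = dict(peak_amplitude=0.55, heterogeneity_cv=0.2, noise_sd=0.02, n_cells=n_cells)
    reference = simulate_trajectories(SimConfig(seed=seed * 31 + 1, **base))
    perturbed = simulate_trajectories(
        SimConfig(
            seed=seed * 31 + 2,
            inhibitor_time=15.0,
            residual_fraction=residual_fraction,
            **base,
        )
    )
    pct = pathway_contribution(
        normalize_fold_change(reference),
        normalize_fold_change(perturbed),
        phase_window=(40.0, 60.0),
    )
    return pct, n_cells
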