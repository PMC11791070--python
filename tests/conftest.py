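import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from signalcap import SimConfig, TrajectorySet, simulate_trajectories

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trajectory_set(values, time_s=None, **meta) -> TrajectorySet:
    """Hand-built TrajectorySet from a 2-D array of values."""
    values = np.asarray(values, dtype=float)
    n_cells, n_time = values.shape
    if time_s is None:
        time_s = np.arange(n_time) * 70.0
    frame = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "genotype": meta.get("genotype", "WT"),
            "stimulus": meta.get("stimulus", "IGF1"),
            "dose": meta.get("dose", 100.0),
        }
    )
    return TrajectorySet(np.asarray(time_s, dtype=float), values, frame)


@pytest.fixture
def tiny_traj() -> TrajectorySet:
    return make_trajectory_set(
        [
            [2.0, 2.0, 2.0, 2.0, 4.0, 6.0],
            [1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
        ]
    )


@pytest.fixture
def wt_igf1() -> TrajectorySet:
    """Deterministic-ish WT IGF1-like population (small, for fast tests)."""
    cfg = SimConfig(peak_amplitude=0.55, n_cells=200, seed=7)
    return simulate_trajectories(cfg)


def three_class_trajectories(
    amplitudes=(1.0, 2.0, 3.0),
    n_cells=150,
    noise_sd=0.01,
    heterogeneity_cv=0.0,
    seed=0,
) -> TrajectorySet:
    """Dose-labeled trajectory classes with configurable separation."""
    from signalcap.recipe import _concat_trajectories

    sets = []
    for i, amp in enumerate(amplitudes):
        cfg = SimConfig(
            stimulus="IGF1",
            dose=float(10**i),
            peak_amplitude=amp,
            heterogeneity_cv=heterogeneity_cv,
            noise_sd=noise_sd,
            n_cells=n_cells,
            seed=seed * 101 + i,
        )
        sets.append(simulate_trajectories(cfg))
    return _concat_trajectories(sets)
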