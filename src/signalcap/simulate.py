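"""Seeded generative models for single-cell PI3K/AKT reporter data.

Two reporter modalities are emulated:

* membrane phosphoinositide (PIP3/PI(3,4)P2) fold-change trajectories as
  measured by TIRF microscopy — a transient overshoot peaking a few minutes
  after growth-factor addition, relaxing to a sustained quasi-steady state
  above baseline, sampled every 70 s over 60 min;
* AKT kinase-translocation-reporter (KTR) cytoplasmic fractions (CN_R in
  [0, 1]) sampled every 6 min over 300 min.

The per-cell trajectory law is phenomenological, not mechanistic: after the
stimulus at ``stim_onset_s`` the elevation above the genotype baseline is

    A_i * [(1 - plateau_fraction) * exp(-t/adaptation) + plateau_fraction]
        * (1 - exp(-t/rise)) / g_max

with ``A_i`` lognormal across cells (mean ``peak_amplitude``, CV
``heterogeneity_cv``), ``g_max`` the envelope maximum on the sampled grid
(so the mean per-cell peak equals ``peak_amplitude`` exactly), plus i.i.d.
Gaussian measurement noise.  PI3Kα inhibition at ``inhibitor_time`` scales
the subsequent elevation by ``residual_fraction + (1 - residual_fraction) *
exp(-(t - t_inh)/adaptation)``, i.e. an exponential switch-off toward the
non-PI3Kα residual.

Genotype effects: an additive baseline offset per mutant allele, selective
amplification of EGFR-family responses in H1047R mutants, and inflation of
cell-to-cell heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import SnapshotSample, TrajectorySet

GENOTYPES = ("WT", "HET", "HOM", "LOF")
MUTANT_GENOTYPES = ("HET", "HOM")
#: stimuli signaling through EGFR-family receptors (subject to mutant amplification)
EGFR_FAMILY = ("EGF", "epigen")


@dataclass
class SimConfig:
    """Parameters of the trajectory generator (times in the units noted)."""

    stimulus: str = "IGF1"
    dose: float = 100.0  # nM
    genotype: str = "WT"
    baseline: float = 1.0  # fold-change units
    baseline_offset: float = 0.05  # per mutant allele, fold-change units
    peak_amplitude: float = 0.55  # mean per-cell peak above baseline
    plateau_fraction: float = 0.5  # fraction of peak retained at steady state
    rise_time: float = 2.0  # minutes
    adaptation_time: float = 4.0  # minutes
    egf_amplification: float = 2.2  # amplitude factor, mutant × EGFR-family only
    residual_fraction: float = 0.0  # non-PI3Kα fraction surviving inhibition
    inhibitor_time: float | None = None  # minutes, None = no inhibitor
    heterogeneity_cv: float = 0.2  # lognormal CV of per-cell amplitude
    noise_sd: float = 0.02  # additive Gaussian measurement noise
    variance_inflation: float = 1.5  # multiplies heterogeneity_cv in mutants
    sampling_interval: float = 70.0  # seconds
    duration: float = 60.0  # minutes
    stim_onset_s: float | None = None  # default: after the 4th sample
    missing_prob: float = 0.0  # per-point probability of NA injection
    n_cells: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = {
            "baseline": self.baseline,
            "peak_amplitude": self.peak_amplitude,
            "heterogeneity_cv": self.heterogeneity_cv,
            "noise_sd": self.noise_sd,
            "variance_inflation": self.variance_inflation,
            "egf_amplification": self.egf_amplification,
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ConfigurationError(f"{name} must be finite, got {value!r}")
        if self.genotype not in GENOTYPES:
            raise ConfigurationError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if not 0 < self.plateau_fraction <= 1:
            raise ConfigurationError("plateau_fraction must be in (0, 1]")
        if not 0 <= self.residual_fraction <= 1:
            raise ConfigurationError("residual_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be > 0")
        for name in ("rise_time", "adaptation_time", "duration"):
            if getattr(self, name) <= 0 or not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be a positive finite time")
        if self.heterogeneity_cv < 0 or self.noise_sd < 0:
            raise ConfigurationError("dispersion parameters must be >= 0")
        if not 0 <= self.missing_prob < 1:
            raise ConfigurationError("missing_prob must be in [0, 1)")

    # -- derived quantities -------------------------------------------------

    def time_grid_s(self) -> np.ndarray:
        """Sample times in seconds, 0 .. duration inclusive of the last fit."""
        return np.arange(0.0, self.duration * 60.0 + 0.5, self.sampling_interval)

    def onset_s(self) -> float:
        if self.stim_onset_s is not None:
            return float(self.stim_onset_s)
        return 4.0 * self.sampling_interval

    def genotype_baseline(self) -> float:
        alleles = {"WT": 0, "LOF": 0, "HET": 1, "HOM": 2}[self.genotype]
        return self.baseline + alleles * self.baseline_offset

    def effective_amplitude(self) -> float:
        amp = self.peak_amplitude
        if self.genotype in MUTANT_GENOTYPES and self.stimulus in EGFR_FAMILY:
            amp *= self.egf_amplification
        return amp

    def effective_cv(self) -> float:
        cv = self.heterogeneity_cv
        if self.genotype in MUTANT_GENOTYPES:
            cv *= self.variance_inflation
        return cv


def _envelope(t_min: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Overshoot-then-plateau response shape for minutes since stimulus."""
    t = np.maximum(t_min, 0.0)
    active = t_min >= 0
    shape = (1.0 - np.exp(-t / cfg.rise_time)) * (
        (1.0 - cfg.plateau_fraction) * np.exp(-t / cfg.adaptation_time)
        + cfg.plateau_fraction
    )
    return np.where(active, shape, 0.0)


def _inhibitor_factor(t_min: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.inhibitor_time is None:
        return np.ones_like(t_min)
    dt = t_min - cfg.inhibitor_time
    r = cfg.residual_fraction
    decay = r + (1.0 - r) * np.exp(-np.maximum(dt, 0.0) / cfg.adaptation_time)
    return np.where(dt > 0, decay, 1.0)


def _per_cell_amplitudes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Lognormal amplitudes with mean = effective amplitude, CV as configured."""
    mean = cfg.effective_amplitude()
    cv = cfg.effective_cv()
    if cv == 0 or mean == 0:
        return np.full(cfg.n_cells, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=cfg.n_cells)


def _meta(cfg: SimConfig, prefix: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [f"{prefix}{i:05d}" for i in range(cfg.n_cells)],
            "genotype": cfg.genotype,
            "stimulus": cfg.stimulus,
            "dose": cfg.dose,
        }
    )


def _inject_missing(
    values: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    if prob > 0 and values.size:
        values[rng.random(values.shape) < prob] = np.nan
    return values


def simulate_trajectories(config: SimConfig) -> TrajectorySet:
    """Simulate phosphoinositide fold-change trajectories (TIRF modality).

    Returns ``config.n_cells`` trajectories on the 0..duration grid.  With
    zero heterogeneity and noise every cell peaks exactly at
    ``genotype baseline + peak amplitude`` on the sampled grid; identical
    seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    time_s = config.time_grid_s()
    t_rel_min = (time_s - config.onset_s()) / 60.0
    shape = _envelope(t_rel_min, config)
    g_max = shape.max()
    if g_max > 0:
        shape = shape / g_max
    shape = shape * _inhibitor_factor(t_rel_min, config)

    amps = _per_cell_amplitudes(config, rng)
    values = config.genotype_baseline() + amps[:, None] * shape[None, :]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = _inject_missing(values, config.missing_prob, rng)
    return TrajectorySet(time_s, values, _meta(config, "cell_"))


#: default KTR (AKT activity) configuration — 300 min at 6 min sampling;
#: baseline cytoplasmic fraction and amplitudes are in CN_R units
KTR_DEFAULTS = dict(
    baseline=0.35,
    baseline_offset=0.02,
    peak_amplitude=0.30,
    plateau_fraction=0.6,
    rise_time=12.0,
    adaptation_time=50.0,
    noise_sd=0.02,
    sampling_interval=360.0,
    duration=300.0,
)


def ktr_config(**overrides) -> SimConfig:
    """A :class:`SimConfig` preset on the KTR grid; overrides win."""
    params = {**KTR_DEFAULTS, **overrides}
    return SimConfig(**params)


def simulate_ktr_trajectories(config: SimConfig) -> TrajectorySet:
    """Simulate KTR cytoplasmic-fraction trajectories, clipped to [0, 1].

    Same generative law as :func:`simulate_trajectories` but the signal is a
    cytoplasmic fraction CN_R, hard-bounded to [0, 1] as the ratio itself is.
    """
    traj = simulate_trajectories(config)
    mask = np.isnan(traj.values)
    clipped = np.clip(traj.values, 0.0, 1.0)
    clipped[mask] = np.nan
    return TrajectorySet(traj.time_s, clipped, traj.meta)


# ---------------------------------------------------------------------------
# snapshot (cytometry-style) generator
# ---------------------------------------------------------------------------


def simulate_snapshot(
    condition_spec: dict,
    n_cells: int,
    seed: int,
) -> SnapshotSample:
    """Simulate one snapshot condition of cytometry-style marker intensities.

    ``condition_spec`` maps::

        {"condition": {...labels...},
         "markers": {name: {"loc": float, "scale": float}, ...},
         "cofactor": 5.0,             # optional
         "variance_inflation": 1.0}   # optional, e.g. >1 for mutants

    Marker values are generated so that their arcsinh transform (with the
    given cofactor) is Gaussian with the stated location and scale: the raw
    intensity is ``cofactor * sinh(y)``, a right-skewed nonnegative law for
    positive locations.  Rare negative draws are clipped to zero so raw
    intensities remain valid cytometry values.
    """
    markers = condition_spec.get("markers")
    if not markers:
        raise ConfigurationError("condition_spec must define at least one marker")
    cofactor = float(condition_spec.get("cofactor", 5.0))
    inflation = float(condition_spec.get("variance_inflation", 1.0))
    if cofactor <= 0:
        raise ConfigurationError("cofactor must be > 0")
    if n_cells < 0:
        raise ConfigurationError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    columns = {}
    for name, params in markers.items():
        loc = float(params["loc"])
        scale = float(params["scale"]) * inflation
        if scale < 0:
            raise ConfigurationError(f"marker {name!r}: negative scale")
        y = rng.normal(loc, scale, size=n_cells) if n_cells else np.empty(0)
        columns[name] = np.maximum(cofactor * np.sinh(y), 0.0)
    return SnapshotSample(
        condition=dict(condition_spec.get("condition", {})),
        marker_values=pd.DataFrame(columns),
    )


# ---------------------------------------------------------------------------
# stimulus calibrations used by the worked examples and recipes
# ---------------------------------------------------------------------------

#: mean WT peak fold-change elevation above baseline per stimulus
STIMULUS_AMPLITUDES = {"IGF1": 0.55, "insulin": 0.50, "EGF": 0.25, "epigen": 0.15}
#: fraction of the response surviving PI3Kα inhibition (HeLa)
STIMULUS_RESIDUALS = {"IGF1": 0.40, "insulin": 0.40, "EGF": 0.50, "epigen": 0.50}


def calibrated_config(stimulus: str, **overrides) -> SimConfig:
    """WT TIRF-modality configuration for a named growth factor."""
    if stimulus not in STIMULUS_AMPLITUDES:
        raise ConfigurationError(
            f"no calibration for stimulus {stimulus!r}; "
            f"known: {sorted(STIMULUS_AMPLITUDES)}"
        )
    params = dict(
        stimulus=stimulus,
        peak_amplitude=STIMULUS_AMPLITUDES[stimulus],
        residual_fraction=STIMULUS_RESIDUALS[stimulus],
    )
    params.update(overrides)
    return SimConfig(**params)
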