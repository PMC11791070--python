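# signalcap

Information transfer through single-cell PI3K/AKT signaling dynamics.

Growth factors such as IGF1 and EGF activate class IA PI3K, producing
transient PIP3/PI(3,4)P2 lipid responses at the plasma membrane and
downstream AKT activity that can be read out per cell — as fold-change
trajectories from membrane reporters (TIRF imaging, one frame every 70 s for
60 min) or as the cytoplasmic fraction of a FOXO-based kinase translocation
reporter, CN_R = KTR_cyto / (KTR_nuc + KTR_cyto) ∈ [0, 1].  Treating the
stimulus *S* (growth factor × dose, *m* discrete levels) and the single-cell
response *Z* as a communication channel, `signalcap` quantifies how much a
cell can "know" about its input:

- **Mutual information** I(Z;S) = H(S) − H(S|Z), with H(S|Z) estimated from
  a multinomial logistic decoder that learns P(S|Z) directly — no density
  estimation or binning of the high-dimensional trajectory response — and is
  cross-validated by default.
- **Channel capacity** max over input distributions P(S) of I(Z;S), solved
  by Blahut–Arimoto updates on the *m*-simplex (ceiling log₂ m bits;
  1.585 bits for three doses), with subsampling diagnostics (default 40
  repetitions on 80% of cells, median and IQR).

Around this core the package provides the measurement and analysis
operators such studies need: pixel-level KTR quantification (5×5 nuclear
square, 2-px cytoplasmic ring, brightest-50% rule, saturation/size/track
filters), fold-change normalization and percentile-bootstrap summaries of
trajectory populations, the PI3Kα-contribution estimator for inhibitor
experiments, and earth-mover's-distance (Wasserstein-1) scoring of
arcsinh-transformed cytometry marker distributions with percentile-threshold
responder fractions and a pluggable (PHATE/MDS) embedding.  Seeded synthetic
generators emulate all of these data modalities, so the entire pipeline is
testable without any download.

## Worked example

```python
import signalcap as sc
from signalcap.recipe import _concat_trajectories

# WT IGF1-like population: overshoot then sustained plateau
cfg = sc.calibrated_config("IGF1", n_cells=500, seed=7)
traj = sc.normalize_fold_change(sc.simulate_trajectories(cfg))
peak = sc.peak_fold_change(traj)
print(f"IGF1 mean-trace peak: {peak['mean_trace_peak']:.3f} at {peak['peak_time_min']:.1f} min")

# PI3Ka-selective inhibition at 15 min; contribution over the sustained window
inhibited = sc.simulate_trajectories(
    sc.calibrated_config("IGF1", n_cells=500, seed=8, inhibitor_time=15.0)
)
pct = sc.pathway_contribution(traj, sc.normalize_fold_change(inhibited))
print(f"PI3Ka contribution (40-60 min window): {pct:.1f}%")

# capacity of a realistic (noisy, overlapping) three-dose channel
sets = [
    sc.simulate_trajectories(
        sc.SimConfig(dose=dose, peak_amplitude=amp, n_cells=300, seed=int(dose))
    )
    for dose, amp in [(1.0, 0.15), (10.0, 0.35), (100.0, 0.55)]
]
pooled = sc.normalize_fold_change(_concat_trajectories(sets))
Z, S = sc.build_response_matrix(pooled, label_by=("dose",))
est = sc.bootstrap_diagnostics(Z, S, estimator="capacity", n_boot=40, frac=0.8, seed=1)
print(f"dose-channel capacity: {est.bits:.2f} bits "
      f"(bootstrap median {est.boot_median:.2f}, IQR {est.boot_iqr[0]:.2f}-{est.boot_iqr[1]:.2f})")
```

prints

```
IGF1 mean-trace peak: 1.538 at 9.3 min
PI3Ka contribution (40-60 min window): 58.5%
dose-channel capacity: 1.26 bits (bootstrap median 1.26, IQR 1.25-1.27)
```

The peak of the population mean trace lands near the 1.55 fold-change
calibration (sampling error at 500 cells); the inhibitor arm, simulated with
a non-PI3Kα residual fraction of 0.40, is correctly decoded as ~60% of the
sustained response being PI3Kα-mediated; and a noisy, partially overlapping
three-dose channel transmits 1.26 of the theoretical 1.585 bits — the doses
are distinguishable but not perfectly so.

The same pipeline is scriptable from the shell (`signalcap simulate`,
`signalcap traj normalize|summarize|peaks|contribution`,
`signalcap info mi|capacity`, `signalcap shift emd|embed|threshold`) and as
multi-stage YAML recipes (`signalcap recipe run three_dose_capacity
--outdir out/`).  A recipe template for re-analysing real deposited
trajectory data is bundled as `osf_capacity_template`
(see `docs/methods.md`).

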