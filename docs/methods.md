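# Methods

## The channel model

A stimulation experiment is modeled as a discrete-input channel: the input
*S* is one of *m* conditions (a growth factor at a dose), the output *Z* is a
single cell's response — either the full reporter trajectory (a vector of
fold-change values on the acquisition grid) or a single snapshot coordinate.
Mutual information and capacity are

    I(Z;S) = H(S) − H(S|Z),      C = max_{P(S)} I(Z;S),

in bits (log₂).  H(S) is analytic given P(S).  H(S|Z) is the population mean
of the per-cell predictive entropy of a decoder model for P(S|Z).  This is
the discriminative ("decode-the-input") strategy for information estimation:
it sidesteps density estimation of the high-dimensional Z entirely and scales
to trajectory responses with dozens of coordinates.

### Decoder

A multinomial logistic regression on the raw response coordinates (no basis
expansion), fitted class-balanced so its probabilities are posteriors under
equal class priors.  L2 regularization strength is selected over the fixed
grid C ∈ {0.01, 1, 100} by stratified 3-fold cross-validated log-loss — the
criterion that matches the entropy-based use of the probabilities (accuracy
is blind to calibration, and on separable data it cannot distinguish a
confident decoder from a hedging one).

### Cross-validated conditional entropy

By default H(S|Z) is evaluated on held-out cells via stratified 5-fold
cross-validation: each cell's P(S|z) comes from a decoder that never saw it.
In-sample evaluation (`cv=0`) is retained as an option for parity with
estimators that skip this step; it biases MI upward for high-dimensional
features.  The MI estimate is clamped below at 0.

### Input reweighting and capacity

For a candidate input distribution P, each cell's balanced posterior q(s|z)
is reweighted to p(s|z) ∝ q(s|z)·P(s), and

    H(S|Z; P) = Σ_s P(s) · mean over cells of class s of H(p(·|z)).

I(P) is concave in P for a fixed channel, so capacity is found by
Blahut–Arimoto multiplicative updates P(s) ← P(s)·2^{c_s} / norm, with
c_s the class-conditional mean of log₂ p(s|z) − log₂ P(s).  Iteration stops
when the capacity estimate changes by < 10⁻⁶ bits and the Blahut–Arimoto
bound gap max_s c_s − I is small; non-convergence with a residual gap above
0.01 bits raises an error rather than returning a doubtful number.  Since the
iteration starts at the uniform distribution and the lower bound increases
monotonically, capacity ≥ uniform-input MI by construction.

### Subsampling diagnostics

`bootstrap_diagnostics` refits the decoder and re-estimates MI or capacity on
`n_boot` random subsets of ⌊frac·n⌋ cells drawn without replacement
(defaults: 40 repetitions, 80%), reporting the median and interquartile range
alongside the full-data point estimate.  A class dropping below the decoder's
identifiability floor (10 cells per level) aborts with an explicit error.

## Trajectory operations

Fold-change normalization divides each cell by its own reference median:
either the first k time points (default k = 4; with the default stimulus
onset these are pre-stimulus baseline) or a late window such as 40–60 min,
which anchors the quasi-steady state at 1 and exposes baseline pathway
elevation in mutant cells.  Cells with a nonpositive reference cannot be
expressed as fold change; they are dropped, not clamped, and the count is
logged.

Population summaries use a percentile bootstrap over cells — cells, not time
points, are the independent replicates — with 1000 draws and α = 0.05 by
default.  The percentile interval is defined to contain the sample mean.  On
Gaussian populations of 100 cells its empirical coverage is ≈ 95% (verified
over 500 replicates in the test suite); percentile intervals are known to
under-cover slightly at small n.

The isoform-contribution estimator compares a reference arm against an
inhibitor arm, both normalized on the same convention:
100·(1 − elevation_perturbed / elevation_reference), where elevation is the
window mean fold change minus 1.  Defaults: peak window 0–10 min, sustained
window 40–60 min, mean-trace convention (a per-cell variant is exposed as an
option; the two agree in expectation).

## KTR image quantification

Nuclear intensity is the mean of the 5×5-pixel square centered on the
tracked centroid (rounded half-away-from-zero, 0-based row/col convention;
the square must fit inside the image).  The cytoplasmic ring is the nuclear
mask dilated by 2 px minus the mask; dilation uses the 8-connected (3×3)
structuring element applied twice.  Cytoplasmic intensity is the mean of the
brightest ⌈n/2⌉ ring pixels — robust to background pixels entering the ring
in thin, elongated cells, and never empty for a nonempty ring.  CN_R =
cyto/(nuc+cyto) is scale-invariant, 0 for a fully nuclear reporter, 1 for
complete nuclear exclusion, and missing (NA) when both compartments read 0.
Quality filters remove tracks shorter than the full time course, objects
under 50 px (exactly 50 is kept — the strict inequality as specified),
cells with any intensity above the 12-bit saturation limit of 4000, and
trajectories containing missing values.  Segmentation and tracking are
inputs; they are not reimplemented here.

## Distribution-shift analysis

Cytometry-style marker intensities are arcsinh-transformed with cofactor 5
before any distance is computed (transformation precedes distance).  The
shift score is the 1-D Wasserstein-1 (earth mover's) distance between a
condition's per-marker distribution and the reference condition's — equal to
the L1 distance between empirical quantile functions, symmetric, and
translation-faithful (a pure shift of c scores exactly |c|).  Unsigned
scores are the default; a signed variant (sign of the median shift) is an
option.  The condition × marker score matrix can be embedded in 2-D through
a pluggable backend: PHATE when importable, otherwise classical metric MDS
on the euclidean row distances, with a logged warning when the fallback
substitutes for a requested backend.  Responder fractions count cells
strictly above the q-th percentile (linear interpolation between order
statistics; default q = 95) of the reference distribution.

## Synthetic data generators

The generators exist so every stage is testable against known ground truth;
they are calibrated to the phenomenology of the real modalities, not to any
mechanism.

**Trajectories.**  Per cell i at time t (minutes since stimulus onset):

    r_i(t) = b_g + A_i · g(t)/g* · u(t) + ε,   ε ~ N(0, noise_sd²)
    g(t)   = (1 − e^{−t/τ_rise}) · [(1 − p)·e^{−t/τ_adapt} + p]

with plateau fraction p, g* the maximum of g on the sampled grid (so the
mean per-cell peak equals `peak_amplitude` exactly), A_i lognormal with mean
`peak_amplitude` and CV `heterogeneity_cv`, and genotype baseline b_g =
baseline + 0.05 per mutant allele.  Defaults τ_rise = 2 min and
τ_adapt = 4 min put the peak at ~4–5 min post-stimulus (within the first
10 min) and the quasi-steady state well before 40 min.  The stimulus onset
defaults to after the 4th sample, so the first four time points are
pre-stimulus baseline — the reference of the default normalization.
Inhibition at t_inh multiplies the subsequent elevation by
u(t) = r + (1 − r)·e^{−(t−t_inh)/τ_adapt}: an exponential switch-off toward
the non-PI3Kα residual fraction r, which makes the late plateau exactly
baseline + r × (uninhibited elevation) — the ground truth the contribution
estimator must invert.  Mutant genotypes amplify EGFR-family amplitudes by
`egf_amplification` (default 2.2, placing mutant EGF near WT IGF1) and
inflate the amplitude CV by `variance_inflation` (default 1.5).  WT stimulus
calibrations: peak elevations 0.55 (IGF1), 0.50 (insulin), 0.25 (EGF),
0.15 (epigen); residual fractions 0.40 (IGF1R/INSR ligands) and 0.50
(EGFR-family).  The grid is 70 s over 60 min (52 points).

**KTR trajectories** use the same law on a 6-min / 300-min grid (51 points)
with CN_R-unit amplitudes around a default baseline of 0.35 (a free
parameter — not constrained by published values — exposed in the config) and
hard clipping to [0, 1], since the measured quantity is a fraction.

**Snapshots.**  Marker values are cofactor·sinh(y) with y Gaussian at the
condition's location/scale on the transformed scale, so the arcsinh
transform recovers exactly the specified location shifts; the law is
right-skewed and nonnegative (rare negative draws are clipped to zero).
Mutant conditions multiply the transformed-scale spread by a variance
inflation factor.

**Synthetic images** place non-overlapping concentric nuclear/cytoplasmic
discs with uniform intensities in a 12-bit range, returning the label mask
and per-cell ground-truth CN_R for pixel-level assertions.

### What the generators do not emulate

No receptor/lipid biochemistry (the trajectory law is phenomenological), no
correlated or heteroscedastic measurement noise, no cell cycle, division,
migration or apoptosis events, no spatial structure in the TIRF footprint,
no marker–marker correlations in snapshots, and no batch or acquisition-day
effects.  Tests passing on these generators therefore validate the
*estimators and their contracts* (normalization conventions, information
bounds, metric properties, filter semantics, seeded reproducibility) — they
do not certify performance on real data, where feature correlations and
non-lognormal heterogeneity can change estimator bias.

## Numerical choices and degenerate inputs

Log base 2 throughout; 0·log 0 ≡ 0.  MI clamped below at 0.  Snapshot
feature times snap to the nearest grid point.  Capacity tolerance 10⁻⁶ bits;
decoder max_iter 1000.  Empty cytoplasmic ring → missing value; both KTR
compartments zero → NA, propagated and later filtered.  Empty trajectory
sets are valid for simulation (grid preserved) but rejected by estimators
that need data.  CSV reads use round-trip float parsing so writer→reader
round trips are bit-exact.

## Problem sizes

The bundled benchmark scenarios run at the study's scales where those are
desk-scale: 500 cells per class for capacity and contribution analyses,
1000 cells for peak calibration, 60 cells for the acquisition-design count,
40×80% subsampling diagnostics.  The coverage check uses 500 replicates of
100-cell populations with 400 bootstrap draws.

## Reproducing published real-data numbers

Capacities on the order of 1.2 bits (IGF1) and 0.75 bits (EGF) for WT
three-dose channels were reported from thousands of real single-cell
trajectories; those datasets are deposited externally and are not shipped
here, so those numbers are not reproduced by this package's tests.  The
bundled `osf_capacity_template` recipe documents the exact pipeline to rerun
on a user-supplied long-format export of the deposited trajectories:
window-median (40–60 min) normalization, dose-labeled response matrix,
capacity with 40×80% subsampling diagnostics.

## Known limitations

- The decoder-based MI is a lower-bound-style estimator: a misspecified or
  under-trained decoder underestimates I; cross-validation removes the
  optimistic bias but not this pessimistic one.
- Blahut–Arimoto operates on the *estimated* channel; capacity inherits the
  decoder's bias.
- The percentile bootstrap slightly under-covers for small cell counts.
- 1-D EMD scores ignore marker–marker dependence; a joint shift invisible in
  the marginals scores zero.
- FCS ingestion requires the optional `fcsparser` dependency; CSV is the
  canonical interchange format.
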