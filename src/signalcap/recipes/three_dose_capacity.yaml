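# Three-dose channel-capacity recipe: simulate dose-graded trajectory
# responses on the 60-min / 70-s grid, fold-change normalize, and estimate
# the capacity of the dose -> trajectory channel with subsampling diagnostics.
name: three_dose_capacity
seed: 1
stages:
  - name: sim_dose_1
    kind: simulate
    params: {stimulus: IGF1, dose: 1.0, peak_amplitude: 0.15, n_cells: 200}
    out: traj_dose_1nM.csv
  - name: sim_dose_10
    kind: simulate
    params: {stimulus: IGF1, dose: 10.0, peak_amplitude: 0.35, n_cells: 200}
    out: traj_dose_10nM.csv
  - name: sim_dose_100
    kind: simulate
    params: {stimulus: IGF1, dose: 100.0, peak_amplitude: 0.55, n_cells: 200}
    out: traj_dose_100nM.csv
  - name: combined
    kind: concat
    uses: [sim_dose_1, sim_dose_10, sim_dose_100]
  - name: normalized
    kind: normalize
    uses: [combined]
    params: {mode: first_k_median, k: 4}
  - name: capacity
    kind: capacity
    uses: [normalized]
    params: {n_boot: 10, frac: 0.8}
    out: capacity.json
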