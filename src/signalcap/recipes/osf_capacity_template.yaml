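# Template for recomputing dose-channel capacity from downloaded real
# trajectory data (not shipped with the package).  Convert the deposited
# trajectory tables to the long CSV schema (cell_id, genotype, stimulus,
# dose, time_s, value) with all three doses of one growth factor in one
# file, point `path` at it, and run:
#
#   signalcap recipe run osf_capacity_template.yaml --outdir results/
#
# The capacity stage reports the point estimate plus the median and IQR of
# 40 subsampling repetitions at 80% of the cells.
name: real_data_dose_capacity
seed: 1
stages:
  - name: trajectories
    kind: read
    params: {path: trajectories_long.csv}
  - name: normalized
    kind: normalize
    uses: [trajectories]
    params: {mode: window_median, window: [40, 60]}
  - name: capacity
    kind: capacity
    uses: [normalized]
    params: {n_boot: 40, frac: 0.8, label_by: [dose]}
    out: capacity.json
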