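# Example end-to-end run configuration for `cohortbias run --config ...`.
# Either name a simulation scenario (null | design | selection) or point
# data_dir at a directory holding the five linked CSVs + truth.json.
out_dir: cohortbias_out
seed: 7
scenario: selection
n_persons: 12000
suppress_threshold: 5
min_events_per_param: 10
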