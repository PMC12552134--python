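# Scaled-down CDDM study: all six architectures, 3 nets each, full
# 15-coherence training grid.  Run with `actbias run --config <this file>`.
task: cddm
profile: scaled_down
master_seed: 1
out_dir: study
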