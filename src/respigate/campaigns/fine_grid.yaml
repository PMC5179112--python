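# Fine-step interior sweep: R 300-495 Hz and S 50-195 Hz in 5 Hz steps
# (40 x 30 = 1200 parameter points).
R_values: {start: 300, stop: 495, step: 5}
S_values: {start: 50, stop: 195, step: 5}
variants: [PG]
modes: [primary]
cycles_per_run: 40
seeds: [0, 1, 2]
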