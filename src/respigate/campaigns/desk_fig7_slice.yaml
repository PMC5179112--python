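# Desk-scale slice of the main sweep: three respiratory strengths
# against a coarse sensory axis, PG circuit, primary input mode.
R_values: [120, 400, 760]
S_values: {start: 20, stop: 740, step: 40}
variants: [PG]
modes: [primary]
cycles_per_run: 40
seeds: [0, 1, 2]
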