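# Full R x S input-strength grid: 20-760 Hz inclusive in steps of 20 Hz
# (38 x 38 = 1444 combinations), single PG-inhibition circuit.
R_values: {start: 20, stop: 760, step: 20}
S_values: {start: 20, stop: 760, step: 20}
variants: [PG]
modes: [primary]
cycles_per_run: 40
seeds: [0, 1, 2]
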