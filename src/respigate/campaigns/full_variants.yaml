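# The full campaign: 1444 R x S combinations crossed with the 4 circuit
# variants and 2 input modes = 11552 parameter points.
R_values: {start: 20, stop: 760, step: 20}
S_values: {start: 20, stop: 760, step: 20}
variants: [none, PG, GC, PG+GC]
modes: [primary, secondary]
cycles_per_run: 40
seeds: [0, 1, 2]
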