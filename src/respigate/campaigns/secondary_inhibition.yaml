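# Secondary-glomerulus input model with lateral inhibition onto the
# recorded mitral cell: 1444 R x S combinations x 2 inhibitory circuit
# variants = 2888 parameter points.
R_values: {start: 20, stop: 760, step: 20}
S_values: {start: 20, stop: 760, step: 20}
variants: [PG, GC]
modes: [secondary]
cycles_per_run: 40
seeds: [0, 1, 2]
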