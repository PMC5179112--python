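# Higher granule-cell inhibition levels (30/50/70/90 x the PG strength):
# 1444 R x S combinations x 4 GC levels = 5776 parameter points.
R_values: {start: 20, stop: 760, step: 20}
S_values: {start: 20, stop: 760, step: 20}
variants: [GC]
modes: [primary]
gc_levels: [30, 50, 70, 90]
cycles_per_run: 40
seeds: [0, 1, 2]
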