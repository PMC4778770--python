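# Desk-scale type I sweep: two species levels x two site levels, all models.
# Run with:  commnull type1 examples/type1_desk.yaml --outdir results/type1
species_levels: [5, 10]
site_levels: [10, 35]
replicates: 200
models: [cooc, aits_nn, aits_sdnn, awts_nn, awts_sdnn]
n_randomizations: 500
n_swaps: 5000
alpha: 0.05
seed: 1
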