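# Demo configuration for the harmonized-library workflow.
# [pipeline] holds the workflow constants; [simulation] sizes the synthetic
# three-biofluid experiment used by `harmolib run --simulate`.

[pipeline]
fdr_alpha = 0.01            # global peptide FDR across all library files
ppm_tolerance = 10.0        # fragment mass tolerance, parts per million
max_quant_ions = 5          # quantitative ions per peptide
min_quant_ions = 3          # below this the peptide is detection-only
coelution_tolerance = 30.0  # seconds; co-elution window for interference
cofragmentation_rule = "union"       # or "demultiplexed"
correlation_aggregation = "min"      # or "mean"
peak_sigma = 6.0            # seconds; Gaussian peak width for integration
rng_seed = 1

[pipeline.wide_scheme]      # wide-window acquisition scheme
start_mz = 400.0
end_mz = 1000.0
window_width = 16.0
staggered = true

[simulation]
n_true_peptides = 150
n_false_targets = 80
n_decoys = 230
n_interference_pairs = 8
runs_per_matrix = 4
n_diff_proteins = 5
fold_change = 2.0
seed = 1
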