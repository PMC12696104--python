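# Example analysis configuration for a simulated 1 Hz cohort.
[analysis]
arena_radius_cm = 4.2
sample_freq = 1.0
edge_dist_cm = 1.0
time_bin_size = 1.0
inactivity_threshold = 0.05
bound_level = 2.0
verbose = true
save_outputs = true

[analysis.groups_and_types]
"sim" = "generic"

[plot.group_colors]
"sim" = "tab:blue"

[defaults]
node_size = 1.0
coverage_sample_period = 1.0
n_points = 40
n_bins = 25
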