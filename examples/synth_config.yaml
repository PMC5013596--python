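# Example configuration for `ga-merge synth --config synth_config.yaml --out DIR`
# A pool of 30 wedges: 20 isomorphous + 10 with strong non-isomorphism.

n_subsets: 30
cell: [30.0, 34.0, 36.0, 90.0, 90.0, 90.0]   # a b c alpha beta gamma
space_group_number: 16                        # P222 (Laue class mmm)
d_min: 2.0                                    # high-resolution limit (Å)
group_spec: [[20, 0.0], [10, 0.5]]            # [group size, non-isomorphism delta]
completeness_per_subset: 0.25                 # fraction of unique set per wedge
scale_range: [0.5, 2.0]                       # per-wedge scale factor k
b_range: [0.0, 0.0]                           # per-wedge isotropic B (Å^2)
noise_a: 1.0                                  # sigma = sqrt(a*I + b)
noise_b: 1.0
mean_intensity: 1000.0
anomalous_frac: 0.0                           # planted |F| anomalous perturbation
multiplicity_within_subset: 2
seed: 11
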