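"""End-to-end combined mode: HCA pre-selection, then GA refinement.

Writes a pool to disk, runs the file-based pipeline (what the `ga-merge
combined` command does), and prints the manifest highlights.
"""

import gamerge as gm
from gamerge.ga import GAParams

cfg = gm.SynthConfig(
    n_subsets=15, group_spec=((10, 0.0), (5, 0.7)), completeness_per_subset=0.3, seed=23
)
pool, truth = gm.generate_pool(cfg)
gm.write_pool(pool, truth, "scratch/combined_pool")

run_cfg = gm.RunConfig(
    input_dir="scratch/combined_pool",
    out_dir="scratch/combined_out",
    d_min=2.0,
    cc_cutoff=0.9,  # strict pre-selection threshold
    ga=GAParams(population_size=15, generations=30, seed=1),
    seed=1,
)
manifest = gm.run_combined(run_cfg)

pre = manifest["preselection"]
print(f"pre-selected {len(pre['selected'])}/{len(pool)} sub-data sets by clustering")
print(f"GA best group: {manifest['ga']['best_group_members']}")
print(f"fitness: merge-all {manifest['merge_all']['fitness']:.1f} -> best {manifest['ga']['best_fitness']:.1f}")
print("outputs in scratch/combined_out/: manifest.json, generations.tsv, best_group_merged.HKL")
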