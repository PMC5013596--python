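"""Generate a synthetic serial-crystallography pool with planted structure.

Creates 30 sub-data sets — 20 mutually isomorphous plus 10 sharing a strong
non-isomorphism perturbation — and writes them as XDS_ASCII-dialect files
with a ground_truth.json recording what was planted.
"""

import gamerge as gm

cfg = gm.SynthConfig(
    n_subsets=30,
    group_spec=((20, 0.0), (10, 0.5)),  # (size, non-isomorphism level delta)
    completeness_per_subset=0.25,  # each wedge sees ~25% of unique reflections
    seed=11,
)
pool, truth = gm.generate_pool(cfg)
paths = gm.write_pool(pool, truth, "scratch/example_pool")

print(f"wrote {len(paths)} sub-data sets to scratch/example_pool/")
print(f"unique reflections in the asymmetric unit: {len(truth.hkl_unique)}")
print(f"observations in the first wedge: {len(pool[0])}")
print(f"planted isomorphous group: subsets {truth.groups[0][0]}..{truth.groups[0][-1]}")
# Each file is a partial, noisy, individually scaled view of the same set of
# true intensities; the second group's intensities are additionally perturbed
# index-wise, which is what non-isomorphism looks like to merging statistics.
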