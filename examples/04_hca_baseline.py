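"""Hierarchical cluster analysis — the baseline selection method.

Correlates every pair of sub-data sets over their common reflections, cuts
the dendrogram at a CC threshold and merges the largest cluster.
"""

import gamerge as gm

cfg = gm.SynthConfig(n_subsets=20, group_spec=((12, 0.0), (8, 0.6)), seed=4)
pool, truth = gm.generate_pool(cfg)

dm = gm.pairwise_cc(pool)
clusters = gm.cluster_and_cut(dm, cc_cutoff=0.9)
print(f"clusters at CC cutoff 0.9: {[len(c) for c in clusters]} (planted blocks: 12 + 8)")

scheme = gm.make_shells(36.0, 2.0, 10)


def r_inner(subsets):
    scales = gm.scale_group(subsets)
    merged = gm.merge_group(subsets, scales, rng_seed=1)
    return gm.compute_stats(merged, scheme, subsets[0].space_group_number).inner.r_meas


top = [pool[i] for i in clusters[0]]
print(f"inner-shell R_meas: largest cluster {r_inner(top):.1f}%  vs  merge-all {r_inner(list(pool)):.1f}%")
# The dominant cluster is the planted isomorphous block; merging only it
# avoids the inflation of R_meas caused by the perturbed wedges.
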