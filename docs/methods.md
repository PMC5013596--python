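# Methods

This note documents the models, conventions and numerical choices behind
`gamerge`, and what the synthetic tests do and do not demonstrate.

## Symmetry and index reduction

Merging operates on orbits of Miller indices under the Laue group (the point
group of the diffraction pattern; always centrosymmetric). Rotation matrices
come from gemmi's space-group tables, closed under inversion; indices
transform as row vectors, h′ = hR. The canonical orbit representative is the
**lexicographically greatest** equivalent over the full orbit including
inversion — a deterministic, order-free rule. When Friedel's law is not
assumed, each observation records whether its reducing operation involved
inversion (Friedel sign ±1); centric reflections, reachable both ways, get
+1. Consistent indexing across wedges (resolution of indexing ambiguities)
is assumed done upstream by the integration software and is out of scope.

Input files use a minimal XDS_ASCII dialect: `!`-prefixed header with space
group number, cell constants and the Friedel-law flag; records of
`H K L IOBS SIGMA(IOBS)` (extra columns ignored). Records with σ ≤ 0 are
dropped at read time and counted. Cells may deviate from the pool median by
< 2% per edge and < 2° per angle (serial pools are near-isomorphous by
construction); larger deviations are rejected rather than re-indexed.

## Scaling

Within one merging group, wedge *j* is corrected by
g_j(d) = k_j · exp(−B_j / (2d²)). Parameters minimise
Σ_h Σ_j (I_hj/g_j − ⟨I_h⟩)² by alternating least squares between per-index
means and per-wedge parameters, with the first wedge anchored at k = 1,
B = 0. The scale-only model is the default; B refinement (a log-linear fit
per iteration, restricted to positive intensity/mean pairs) is opt-in.
Iteration stops when the largest relative parameter change falls below
1e−10 (the error roughly halves per iteration, so this costs only a few
extra iterations over a looser tolerance and makes noiseless recovery exact
to ~1e−9) or after 100 iterations. Wedges sharing no reflection with the
rest of their group are flagged and excluded with a warning. No outlier
rejection, error-model inflation or zero-dose extrapolation is performed:
the scaler's job is to rank candidate groups, not to produce final data.

## Merging and statistics

Scaled observations sharing a reduced index are combined as an
inverse-variance-weighted mean with σ_mean = 1/√(Σ 1/σ²). The R-factor
numerators use the conventional unweighted mean:

- R_merge = Σ_h Σ_i |I_hi − ⟨I_h⟩| / Σ_h Σ_i I_hi over indices with ≥ 2
  observations;
- R_meas adds the per-index factor √(n_h/(n_h−1)) (multiplicity-unbiased).

CC<sub>1/2</sub> is the Pearson correlation between the means of two random
halves of each index's observations; the split is a seeded random
alternation per index, and the seed is derived from the run seed plus the
group membership, so a group's statistics are independent of which
chromosome proposed them (this also makes fitness exactly invariant under
group-label permutation). SigAno is the mean of |⟨I+⟩ − ⟨I−⟩| /
√(σ(⟨I+⟩)² + σ(⟨I−⟩)²) over indices with both Friedel mates; for pure noise
its expectation is √(2/π) ≈ 0.798. CC_anom correlates half-set anomalous
differences. Any correlation over fewer than 3 reflections is reported as
undefined, never as 0.

⟨I/σ(I)⟩ is computed in two variants: the merged-reflection ratio
mean_I/σ_mean, which grows like √multiplicity by error propagation, and the
plain per-observation mean of I/σ, which is essentially flat in
multiplicity. Published processed-data tables behave like the flat variant
(integration error models inflate σ with observed scatter), and a
√multiplicity term would make "merge everything" dominate any clean
subgroup regardless of non-isomorphism, defeating selection. The fitness
therefore uses the per-observation variant by default
(`FitnessWeights(i_source="observations")`); both are reported.

Resolution shells default to 10 bins of equal reciprocal volume (equally
spaced in 1/d³) between the pool's d_max and the user resolution limit;
an explicit edge list is accepted. "Inner" is the first (lowest-resolution)
shell, "outer" the last. Completeness divides by a brute-force enumeration
of the unique reflections inside the resolution sphere (cached per
cell/shells/symmetry). Systematic absences are not subtracted: the bias is
at the percent level and identical for every candidate group, so rankings
are unaffected.

## Fitness

Each term is oriented higher-is-better. R_meas enters as 100 − R (default)
or 1/R (capped at 10⁴ as R → 0). Undefined statistics contribute the worst
value of their transform (0 for higher-is-better terms; T(100) for R), so
empty or degenerate groups are dominated rather than erroring — the search
must be free to propose them. Term shells follow the usual practice (R and
I/σ and SigAno from the inner shell, where data are strong; CC1/2 from the
outer shell, where it is discriminating; completeness and multiplicity
overall) and can be overridden per term. The optional anomalous term is
either inner-shell SigAno or 10/d*, where d* is the finest resolution down
to which SigAno > 1.0 and CC_anom > 30% hold contiguously from the inner
shell; the factor 10 simply puts the term on a magnitude comparable to
SigAno. All weights default to 1.0 (anomalous 0) and are exposed as flags.
An individual's fitness is the best group score, ties broken by lowest
group id; "combined" mode averages over non-empty groups.

## The evolutionary loop

The classic generational scheme: evaluate the random initial population;
each generation, select population-size offspring by tournament (k = 3,
ties to the first drawn), apply uniform crossover to consecutive pairs with
probability 0.3 (per-gene swap probability 0.05), uniform integer mutation
to each offspring with probability 0.6 (per-gene resampling probability
0.05, self-draws allowed, so the effective flip rate is p(1 − 1/g)),
re-evaluate modified individuals, replace the population. No elitism in the
population; a hall of fame of size 1 keeps the best-ever individual, whose
fitness is non-decreasing by construction. One master seed drives separate
streams for initialisation, operators and half-set splits; serial runs are
bit-reproducible. Fitness is cached on the canonical chromosome (groups
relabelled by first appearance) and group scores on the membership set.
Groups of any size ≥ 1 are scored — completeness and multiplicity terms
already penalise tiny groups, so no explicit floor is imposed.

## HCA baseline and combined mode

Each wedge is pre-merged to one plain-mean intensity per reduced index;
pairs are compared by Pearson CC over their common indices (pairs with < 5
common indices get the maximum distance 2 and are flagged). Distance is
1 − CC with average linkage by default (both configurable: single/complete
linkage, √(1 − CC²) distance), the dendrogram is cut at height 1 − cutoff,
and the largest cluster is the selection. Combined mode runs HCA at a
strict cutoff as a pre-selection and the GA on the surviving wedges; if
pre-selection leaves fewer than 2 wedges it falls back to the full pool
with a warning.

## Synthetic pools

The generator emulates the statistical shape of a serial pool, not the
physics. True intensities are exponential (acentric Wilson) with mean 1000
(so Poisson-like noise σ = √(a·I + b), defaults a = b = 1, gives
per-observation I/σ of a few tens at low resolution — typical of good
synchrotron wedges). Non-isomorphism is an index-wise log-normal multiplier
exp(δ·N(0,1)) shared by all wedges of a group: it produces the elevated R
and depressed between-group CC that real non-isomorphism shows, without
simulating structures. Each wedge samples a random fraction of the unique
set (default 25%, mid-range between sparse and half-complete real pools),
observes each index twice, and applies its own k and B. An anomalous signal
can be planted on acentric indices as ΔI/I = 2·Δ|F|/|F|; a Δ_frac of 0.05
on intensities near the mean corresponds to roughly a five-sigma Friedel
difference under the default noise. Noiseless configurations report a tiny
nominal σ (10⁻⁶ of the mean intensity) because the format requires σ > 0.
The default study pool is 30 wedges of a small orthorhombic P222 cell
(30×34×36 Å, d_min = 2 Å, ~2700 unique reflections): large enough for
stable shell statistics, small enough that a full GA run takes tens of
seconds on one core.

What the generator does **not** model: resolution-dependent intensity
falloff (so ⟨I/σ⟩ does not decay into the outer shell as real data do),
partiality, radiation damage, dose, absorption, or correlated error between
wedges beyond the planted group structure. Passing tests therefore show
that the statistics engine is correct and that the selection machinery
finds planted structure of realistic magnitude — not that any particular
weight set is optimal on real beamline data.

## Test problem sizes

The standard planted pool (30 wedges, 20 + 10 at δ = 0.5) is searched with
population 20 for 100 generations — convergence on this size is typically
reached within ~40 generations, so 100 leaves a comfortable margin while a
production run on real data would use 300. Exhaustive-oracle checks use 8
wedges and g = 2 (256 assignments). Stochastic acceptance uses 5-seed
sweeps with a ≥ 4/5 pass rule; operator statistics are checked to 3σ of
their closed-form expectations.

## Known limitations

- The scaler is intentionally minimal; on real data XSCALE-grade error
  models and outlier rejection would change absolute statistic values
  (group *rankings* are much less sensitive).
- Completeness ignores systematic absences (constant, percent-level bias).
- The anomalous-resolution score depends on shell granularity, since d* is
  quantised to shell edges.
- With g groups the chromosome space is g^n; for pools of hundreds of
  wedges more generations and/or larger populations than the defaults used
  in the tests are needed.
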