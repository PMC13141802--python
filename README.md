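# eventseg

Analysis pipeline for naturalistic **event segmentation** experiments:
participants watch a movie and press a button whenever they feel one
meaningful event has ended and another has begun, while EEG is recorded.
The package covers the full statistical path from button-press streams and
situational-change codings to source-space oscillatory contrasts and group
comparisons — with a synthetic-data module standing in for non-shareable
EEG and clinical recordings, so every stage is testable offline.

Intended users: cognitive-neurophysiology researchers who want a tested,
scriptable implementation of this analysis chain (or of individual pieces
such as the cluster-based permutation test, the jackknife group comparison,
or the from-scratch DBSCAN) on their own data.

## What it computes

**Behavior.** The movie timeline is cut into 2-s bins; a per-bin coding
marks nine types of situational change (character, character–character,
character–object, temporal, large/small spatial, cause, goal, scene).
Segmentation probability is modeled with a random-intercept logistic
regression

&nbsp;&nbsp;&nbsp;&nbsp;logit P(response<sub>sb</sub> = 1) = β₀ + u<sub>s</sub> + (β₁ + g<sub>s</sub>·β₂)·changes<sub>b</sub>,&nbsp;&nbsp;u<sub>s</sub> ~ N(0, σ²)

fit by maximum likelihood with Gauss–Hermite quadrature; odds ratios are
exp(β) with Wald 95% intervals.  A nine-flag variant models each change
type separately.  Mean event length (movie duration / response count) is
compared across groups with a pooled t test, and summary-statistic
routines recompute printed group contrasts (pooled t from mean/SD/n,
Pearson χ² from count tables).

**Intervals.** Responses closer than 4 s are pruned (greedy left-to-right);
bins holding a response are Boundary Intervals (BI), the rest No-Boundary
Intervals (NBI).  Per clip, NBI are sampled to the BI count, paired in
time order, given virtual markers copying the partner's within-bin offset,
and realigned to a [−1 s, +1 s] window around the marker.

**Source power.** A DICS beamformer: band-limited cross-spectral density
(Hanning taper, 0.5 Hz resolution of 2-s segments; theta 4–7, alpha 8–12,
beta 15–30 Hz), unit-gain spatial filters W = (LᵀC⁻¹L)⁻¹LᵀC⁻¹ from the
pooled-condition CSD regularized at λ = 5%, and per-voxel power as the
dominant eigenvalue of the projected 3×3 source CSD.  One common filter
per subject serves both conditions.

**Statistics.** A from-scratch cluster-based permutation test (CBPT):
paired t per voxel, suprathreshold clustering over the grid's
6-connectivity, cluster statistic T<sub>sum</sub>, and a sign-flip
max-statistic null (default 1000 permutations) for family-wise-corrected
cluster p values.  Group comparison runs the CBPT in a leave-one-out
jackknife (n iterations for n subjects), collects per-iteration cluster
size and relT<sub>sum</sub> = T<sub>sum</sub>/size, and compares groups
with Wilcoxon–Mann–Whitney tests and effect size r = |Z|/√N.  The
strongest contrasts are localized by DBSCAN (eps = 0.75 cm = 1.5 × the
0.5 cm grid spacing, minPts = 5) on the top-1% difference voxels,
cerebellum excluded, with atlas-table labeling.

## Worked example

```python
import numpy as np
import eventseg as es

# simulate a cohort: 30 subjects/group, 30-min movie in 2-s bins
cfg = es.SimConfig(seed=7, n_subjects_per_group=30, n_bins=900)
changes = es.simulate_change_table(cfg)
streams = es.simulate_responses(changes, cfg)

# intervals for one subject
s = streams[0]
pruned = es.prune_responses(s.response_times)
pairs = es.build_interval_pairs(pruned, es.default_clips(), seed=0)
print(f"{s.subject_id}: {len(s.response_times)} presses, {len(pruned)} after "
      f"pruning, {(pairs['kind'] == 'BI').sum()} BI/NBI pairs")

# behavioral GLMM
binned = np.array([es.classify_bins(x.response_times, cfg.duration, cfg.bin_width)
                   for x in streams])
groups = np.array([x.group for x in streams])
design, _ = es.build_designs(changes, binned, groups, [x.subject_id for x in streams])
print(es.fit_mixed_logit(design, "count").summary().round(3))

# source statistics: planted 20-voxel effect, group B at half extent
spec = es.SourceSimSpec(grid_shape=(10, 10, 10), planted_voxels=tuple(range(440, 460)),
                        effect_delta=1.0, group_scale=0.5)
ga, gb = es.simulate_power_dataset(spec, 15, seed=1)
adj = es.build_adjacency(es.grid_coordinates((10, 10, 10), 0.5))
res = es.permutation_test(ga.bi, ga.nbi, adj, n_perm=1000, seed=2)
c, p = res.clusters[0], res.p_values[0]
print(f"largest cluster: {c.size} voxels, Tsum = {c.t_sum:.1f}, p = {p:.4f}")

ma = es.loo_cbpt_metrics(ga.bi, ga.nbi, adj, n_perm=200, seed=3)
mb = es.loo_cbpt_metrics(gb.bi, gb.nbi, adj, n_perm=200, seed=4)
comp = es.compare_group_metrics(ma, mb)["size"]
print(f"jackknife size comparison: Z = {comp.z:.2f}, p = {comp.p:.2g}, r = {comp.r:.2f}")
```

Output:

```
nt00: 51 presses, 50 after pruning, 49 BI/NBI pairs
                 estimate     se  ci_lo  ci_hi  odds_ratio
intercept          -3.316  0.099 -3.510 -3.121       0.036
n_changes           0.294  0.027  0.241  0.348       1.342
group              -0.005  0.166 -0.330  0.320       0.995
n_changes:group    -0.090  0.040 -0.168 -0.012       0.914
largest cluster: 11 voxels, Tsum = 40.8, p = 0.0010
jackknife size comparison: Z = 4.79, p = 1.7e-06, r = 0.87
```

The fitted count slope (0.294, OR 1.34) and group interaction (−0.090)
recover the generating coefficients (0.30, −0.09): each extra situational
change in a bin raises the odds of a boundary response by ~34% in group 0
and less steeply in group 1.  The planted 20-voxel power increase comes
out as a significant positive cluster at the permutation floor
(p = 1/1001 ≈ 0.001), and the jackknifed cluster-size distributions of
the two groups — planted at 20 vs 10 voxels — separate clearly in the
rank-sum comparison.

A `eventseg` console script exposes the stages (`simulate`, `intervals`,
`dics`, `cbpt`, `loo`, `localize`, `behavior`) for file-based use; run
`eventseg --help`.

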