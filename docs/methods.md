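# Methods

This note records the models implemented in `eventseg`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
validation does and does not establish about real data.

## Behavioral model

Segmentation behavior is modeled at the level of 2-s movie bins.  With
subject *s*, bin *b*, group code *g* ∈ {0, 1} and per-bin change count
*c<sub>b</sub>*:

    logit P(y_sb = 1) = β0 + u_s + (β1 + g_s β2) c_b ,   u_s ~ N(0, σ²)

The nine-flag variant replaces the count with one indicator per change
type plus type-by-group interactions.  The fit is maximum likelihood: the
random intercept is integrated out per subject with Gauss–Hermite
quadrature and the marginal likelihood is optimized with L-BFGS-B using
analytic gradients; standard errors come from the numerical Hessian at
the optimum, intervals are Wald 95%, and odds ratios are exp(β).

*Quadrature.* The quadrature is non-adaptive, so the node grid must
resolve each subject's intercept posterior, which narrows as the number
of bins per subject grows.  At the package's target sizes (hundreds of
bins per subject) 61 nodes reproduce adaptive-quadrature reference fits
(`lme4::glmer`, nAGQ = 15) to ~1e-6 in all coefficients and SEs; this is
the default, and the test suite keeps the cross-check.

*Why likelihood rather than MCMC.* The inferential targets are point
estimates, 95% intervals and odds ratios; a likelihood fit preserves all
three without a sampler dependency.  Wald intervals are the frequentist
analogue of the credible intervals the original analysis style reports —
an analogue, not a replication of posterior geometry.

Printed-summary routines: `t_from_summary` is the pooled-variance
two-sample t (df = n₁+n₂−2) from means, SDs and group sizes;
`chisq_from_table` is Pearson's χ² without continuity correction.  Group
sizes for questionnaire contrasts are inferred from the reported dfs
given the stated missing-questionnaire counts (df 58 → 30/30, 49 → 29/22,
47 → 29/20) and encoded as constants where used.

## Interval construction

Responses under 4 s apart are pruned greedily left-to-right (keep a time
iff ≥ 4 s after the last kept one); the source description does not say
whether pruning is greedy or cascaded, so the greedy reading is
implemented and flagged here.  Bins are 0-based and half-open
[t, t+2); an edge response belongs to the later bin (unstated convention,
fixed for determinism).  Per clip, NBI bins are sampled without
replacement (dedicated seeded generator) to the BI count, both lists are
time-sorted, and k-th members are paired; the NBI virtual marker copies
the partner's within-bin offset, and both segments are realigned to
[marker−1, marker+1].

Two conservative rules cover cases the procedure leaves open:

* An NBI bin is eligible only if **no response falls within 1 s of any
  point of the bin**, so the realigned window is response-free whatever
  offset is copied into it.
* A BI whose realigned window would cross a clip edge is dropped with a
  warning, as is any NBI candidate bin whose window could.

The 4-s rule guarantees realigned BI windows never overlap (2-s windows,
≥ 4-s spacing).

## DICS beamformer

Cross-spectral density: per 2-s segment, Hanning-tapered FFT (natural
0.5 Hz resolution at 300 Hz sampling), coefficients at all in-band bins;
the CSD is the average outer product over segments and bins.  The
"0.5 Hz smoothing" is read as this in-band bin averaging — the simplest
construction consistent with a 2-s segment length; no multitaper.

Filters: C_reg = Re(C) + λ·(tr Re(C)/n)·I with λ = 0.05;
W(v) = (LᵀC_reg⁻¹L)⁻¹LᵀC_reg⁻¹ with L the voxel's n_sensors × 3
free-orientation leadfield ("rank 3" is realized as the three leadfield
columns; no further truncation).  W L = I₃ holds to 1e-8 on
well-conditioned inputs and is asserted.  One filter set per subject is
computed from the *appended* BI+NBI segments and applied to both
condition CSDs, so condition differences cannot come from filter
differences (hashable filter array for auditing).

Power: per voxel S = W Re(C) Wᵀ (3×3, PSD since Re of a Hermitian PSD
matrix is PSD); the summary is the largest eigenvalue
(dominant-orientation convention), with the trace available via
`summary="trace"`.  Which convention the original toolbox used is not
stated; the eigenvalue is the default because it is invariant to
orientation splitting of a single dipole.  Imaginary CSD parts are kept
for inspection but unused in filtering/power.

## Cluster-based permutation test

Paired t per voxel (d = BI − NBI, t = mean/ (sd/√n)); voxels with zero
difference variance get t = 0 if the mean is also zero.  The
cluster-forming threshold is the two-sided t critical value at
α_form = 0.05 — the common toolbox default, configurable, since no value
is stated.  Clusters are connected components among suprathreshold
voxels, per sign, over orthogonal 6-connectivity of the lattice (an
optional radius rule exists).  Clustering is spatial only: the contrast
is band-averaged power, so the nominal time/frequency dimensions
collapse at this stage.

Null: each permutation flips every subject's condition labels
independently (sampled 2ⁿ scheme).  Sign flips leave Σd² per voxel
invariant, so permuted t maps need only the flipped means — this makes
the loop a single matrix product plus component labeling.  The
max statistic is the maximum |T_sum| over clusters of **both** signs
(two-sided family-wise control; signed clusters are still reported
separately), and p = (1 + #{max ≥ |T_sum|})/(n_perm + 1), bounded below
by 1/(n_perm+1).

## Jackknife group comparison

For a group of n subjects the CBPT is rerun n times, leaving one subject
out per iteration.  Each iteration contributes the significant-voxel
count and relT_sum = T_sum/size of the significant clusters of the
*dominant sign* (the sign with the larger total |T_sum| among significant
clusters); multiple significant clusters of that sign are pooled, since
multiplicity must be handled even though the typical outcome is a single
cluster.  Iterations with no significant cluster contribute (0, 0) —
the zero-fill rule for mixed cases is this package's decision and is
visible in the output.  relT_sum keeps its sign; magnitude comparisons
are available behind `magnitude=True`.

The group comparison is a Wilcoxon–Mann–Whitney rank-sum per metric:
midrank ties, tie-corrected normal-approximation Z (no continuity
correction), exact enumeration of the p value for n₁+n₂ ≤ 12 without
ties, effect size r = |Z|/√(n₁+n₂), z > 0 when the first group tends
larger.  Jackknife iterations share n−1 subjects and are dependent; the
rank-sum test is applied regardless, mirroring the original scheme, and
its p values should be read as descriptive.

Per-iteration permutation seeds can be fixed or iteration-derived
(`seed_policy`); iteration-derived is the default so iterations are
independent draws of the permutation null.

## Localization

The top ceil(pct/100 × n_eligible) voxels by condition difference —
direction explicit ("positive", "negative", or magnitude), cerebellum
mask applied before ranking, cutoff ties broken by voxel id — are
clustered with a from-scratch DBSCAN: eps = 0.75 cm (1.5 × the 0.5 cm
grid spacing, connecting face and edge but not cube-diagonal neighbors),
minPts = 5, neighborhood counts including the point itself (classic
convention, unstated in the source).  Core membership is order-invariant;
border points reachable from several clusters join the cluster expanded
first in the ascending-id scan — determinism was preferred over fidelity
to an unspecified toolbox behavior.  Cluster voxels are tallied against
an atlas table (voxel_id → region label); unknown voxels are reported
as "unlabeled", never dropped.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the pipeline assumes,
with defaults set to the study conditions: 30 subjects/group, 900 bins of
2 s (three 10-min clips), behavioral coefficients β0 = −3.26, β1 = 0.30,
β2 = −0.09, intercept SD 0.5 (a typical between-subject spread; the
original intercept spread is not reported), 300 Hz sampling, 2-s
segments.  Per-type change probabilities default to 0.1 each — chosen so
per-bin counts concentrate on 0–3 and counts above 5 are rare (matching
the observed 0–5 range without truncating, which would bias the
generative model); they are config values, not claims about the actual
stimulus.

Deliberate simplifications, documented rather than hidden:

* Change flags are i.i.d. across types and bins; real codings have
  temporal structure.  Independence suffices for testing the regression
  stage.
* Response placement within a bin is uniform; within-bin timing is not
  modeled.
* Power datasets are i.i.d. Gaussian log-power with an additive planted
  shift — no spatial noise correlation, no 1/f background.
  `group_scale` scales the planted **extent** for the second group
  (first round(scale·k) voxels of the sorted planted set); the per-voxel
  shift is left unchanged so extent and magnitude can be manipulated
  independently.
* Sensor segments are one active voxel's leadfield times band-limited
  oscillations (independent random phases per segment and orientation,
  giving a band CSD of rank ≤ 3) plus white noise; leadfields are random
  (optionally spatially smoothed) rather than physical — no volume
  conduction model, no real atlas.

Consequently, passing tests show the *statistical machinery* is correct
(error control, power, recovery, oracle equivalence) under these
conditions; they do not certify performance under realistic EEG noise,
leadfield correlation structure, or coding autocorrelation.

## Validation problem sizes

The end-to-end checks run at deliberately desk-scale sizes: CBPT error
control on 500 null datasets (n = 15 paired subjects, 10×10×10 grid,
200 permutations), planted-cluster recovery over 50 replicates
(20-voxel cluster, 1 noise-SD shift), the sampled-vs-exhaustive null at
n = 5 (32 sign patterns, 2000 draws), GLMM recovery over 20 replicates
at the full behavioral size (30/group × 900 bins), and jackknife group
separation over 20 replicates (extent 20 vs 10 voxels).  The published
neurophysiological cluster values themselves depend on unavailable
recordings and are not reproduction targets; the recomputable quantities
(questionnaire t statistics, education χ², effect-size arithmetic,
sample accounting) are verified exactly from printed inputs.

## Known limitations

* The GLMM fit covers a single Gaussian random intercept only — no
  random slopes, no crossed effects.
* The rank-sum p values on jackknife metrics inherit the dependence
  caveat above.
* DBSCAN border-point assignment (not membership of core points) is
  scan-order dependent by construction; all oracle comparisons account
  for this.
* CSD estimation offers only the Hanning taper; no multitaper or Welch
  variants.
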