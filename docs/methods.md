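# Methods

This package re-implements, as a tested pipeline, a perfusion-pattern analysis
for SUDEP risk stratification in drug-resistant focal epilepsy (DRFE): paired
interictal/ictal brain-perfusion SPECT scans are quantified over a 74-structure
atlas, each scan's perfusion profile is partitioned by univariate k-means into
hypo- and hyperperfused clusters, cluster membership is aggregated across
patients, and each structure's interictal→ictal perfusion change is screened
as a predictor of the SUDEP-7 clinical risk score.

## Perfusion quantification

**ROI activity.** The substrate is a per-scan table of mean tracer activity
(counts/voxel) per atlas structure. When co-registered volumes are supplied
(activity, integer atlas labels, grey-matter mask — all on one grid, checked
not resampled), the mean is taken over voxels with the structure's label *and*
inside the GM mask, so ventricular and extracerebral CSF voxels never
contribute. Structures left without voxels after masking are absent, not zero,
and downstream stages work on the intersection of available structures.

**Partial-volume correction** is region-based geometric-transfer-matrix (GTM):
with PSF ⊛ denoting convolution with the scanner's Gaussian point-spread
function, the observed ROI means obey `observed = W · true`, where
`W[i, j] = mean over ROI_i of (PSF ⊛ 1_{ROI_j})`. The correction solves this
linear system; `cond(W) > 1e8` aborts with advice (larger ROIs or smaller
PSF), and FWHM 0 is the exact identity. Only ROI means feed the downstream
analysis, so the voxel-wise redistribution half of hybrid PVC schemes would
change nothing here and is deliberately omitted. No PSF width is standard
across cameras; the default is 8 mm FWHM, exposed in configuration.

**Perfusion index (PI).** `PI(s) = mean(s) / reference`, with the reference
defaulting to the voxel-count-weighted mean of all grey matter *excluding* s
(leave-one-out, "rest" mode); a "global" mode (all grey matter) is a config
switch for comparability with pipelines that normalise to the whole-brain
mean. PI is unitless and scale-invariant: rescaling all activities leaves it
unchanged. PI > 1 is relative hyperperfusion.

**Change.** `change(s) = (PI_ictal(s) − PI_interictal(s)) / PI_interictal(s)`,
a relative fraction with 0 = invariant perfusion. Note the asymmetry: a +30%
increase and the reverse transition do not have equal magnitudes; the pipeline
always quantifies the interictal→ictal direction.

## Atlas and laterality

The bundled catalogue has 74 structures (36 left/right pairs + medulla and
pons on the midline), each classed cortical/subcortical, with the partner
relation validated as an involution. Because the seizure-onset side differs
between patients, cross-patient analyses re-key paired structures to
ipsilateral/contralateral given each patient's onset side. This is done on
the ROI table (a pure permutation of rows), which after ROI averaging is
mathematically equivalent to flipping the images, and avoids re-registration.
The catalogue does not claim the reference parcellation's exact geometry —
only its structure inventory, pairing and classes, which are what the
analysis consumes.

## Clustering and K selection

Each scan's 74 values (PI or change) are clustered by **univariate k-means**:
Lloyd iterations, Euclidean distance, centroids initialised on data points,
best of `n_restarts = 20` by inertia, reported in centroid-sorted order. The
lowest- and highest-centroid clusters are the scan's hypo- and hyperperfused
ROIs (for change vectors: decrease and increase sets). Engineering choices
that matter:

* restart inits mix one deterministic quantile spread, plain random
  data-point draws, and D²-weighted draws;
* each converged run is polished by coordinate descent on the sorted-order
  segment boundaries (exact best split of each adjacent segment pair, plus a
  merge-and-resplit "jump" move). Lloyd stationarity is weaker than
  single-point optimality in 1-D, and plain restarts alone miss the global
  optimum on a few percent of small instances;
* nearest-centroid ties break toward the lower sorted cluster index, and
  empty clusters are re-seeded on the farthest point, keeping runs
  deterministic per seed.

An **exact dynamic program** over the sorted values (optimal 1-D clusters are
contiguous; O(k·n²) with prefix sums) ships alongside as the independent
optimality oracle and as an optional engine (`engine="dp"`). With the polish
step, best-of-20 Lloyd attains the DP optimum on all but ~0.1% of random
instances (n ≤ 74, k ≤ 6); the remaining misses are genuine multi-boundary
local minima.

**K selection** is v-fold cross-validation on distortion: for each candidate
K, values are split into `folds = 10` random folds; a fit on the other folds
scores each held-out value by squared distance to the nearest centroid. K
grows while each step improves the mean held-out distortion by at least
`improvement_threshold = 5%` of the previous value; the last
sufficiently-improving K is chosen (candidates 2–10 by default). A candidate
infeasible on a training split (more clusters than distinct values), or a
zero previous distortion, ends the growth. Two properties follow:

* data concentrated on m well-separated point masses select K = m exactly
  (the held-out distortion hits zero there), which is how planted-K recovery
  is tested for K ∈ {2..6};
* on *continuous* structureless data the rule runs to the top candidate:
  splitting a Gaussian cluster reduces even held-out distortion by ~40–60%
  regardless of scale, so no distortion-threshold rule can flag "no
  structure". This is a documented limitation of distortion-elbow selection,
  not of this implementation; with realistic observation noise the per-scan
  selected K therefore overshoots, and the pipeline reports the full per-scan
  K distribution rather than asserting a single K.

## Cross-patient aggregation

The match table counts, per structure × state × role (hypo/hyper for PI
scans, decrease/increase for change), how many patients carry the structure
in that extreme set, with percentages to one decimal. Both rounding and
truncation styles are available (`percent_style`); truncation reproduces the
convention of the published per-structure match figures (8/9 → 88.8).
Cluster summaries report mean ± sample SD (n−1) of member values, N and
N_subcortical per extreme cluster; single-member clusters report SD 0 with a
flag. `describe` supplies mean, sample SD, SE = SD/√n, median and range.

## SUDEP-7 scoring

The seven inventory items (GTC > 3/yr; GTC > 0/yr; any seizure > 0/yr; any
seizure > 50/month; duration ≥ 30 yr; ≥ 3 AEDs; intellectual disability) are
summed with weights `w = (2, 1, 1, 2, 2, 2, 2)` under two exclusion rules:
item 2 scores 0 when item 1 is present, item 3 scores 0 when item 4 is
present. The published inventory is weighted with a 0–10 ceiling but does not
print the weights; this default is the simple assignment whose maximum under
the exclusion rules is exactly 10 (2+2+2+2+2) and which produces the odd
scores seen in the reference cohort. **The weights are configuration, not a
clinical claim.** Scores > 5 are the high-risk stratum.

## Feature screening (binned F)

Each structure's change values across patients are binned into
`n_intervals = 10` equal-width intervals over their observed range; the
one-way F statistic of the SUDEP-7 score across the occupied bins (between-
over within-bin mean square, df = (bins−1, n−bins), p from the F
distribution) ranks the structures. Two small-sample safeguards are built in,
both operating on the predictor only (so they cannot bias the test under
permutation of the outcome):

* adjacent occupied intervals merge into one bin — only an *empty* interval
  marks a real gap in a 9-point sample;
* bins with fewer than two patients merge into their nearest neighbour.

Without these, most bins are singletons at n = 9 and the F statistic is
infinite on pure overfit (zero within-bin degrees of freedom) for a large
share of structures, planted or not. Degenerate structures (constant change,
or a single bin after merging) are flagged and ranked last. Selection takes
the top 3 by F or p < 0.05, both configurable.

Known calibration limit: with a discrete, heavily tied outcome (the reference
scores are 3,4,4,5,7,7,7,7,7) the normal-theory p is mildly anticonservative —
permutation replicates put the p < 0.05 rate near 0.055 rather than 0.050.
An exact permutation p would calibrate but is not what the screening
procedure specifies.

The companion correlation analysis relates each patient's ictal
hypoperfused-cluster size to the SUDEP-7 score by Spearman rank correlation
(mid-ranks for ties), in both total-N and subcortical-N variants, since
published phrasing of that quantity is ambiguous.

## Synthetic cohort (study conditions)

The generator emulates the reference cohort: 9 patients, 74 structures,
paired interictal/ictal ROI tables, clinical items yielding SUDEP-7 scores
(3,5,7,7,7,4,7,7,4) and onset sides (L,L,R,R,R,R,L,L,R). Per patient, each
structure sits on one of five PI levels — hypo 0.53, low-normal 0.85, normal
1.00, high-normal 1.08, hyper 1.31 — so K selection has a planted K = 5. The
hypo set is medulla, red nucleus L/R, substantia nigra L/R and ipsilateral
entorhinal; the hyper set is rectus L/R, putamen L/R, cingulate L/R and
ipsilateral globus pallidus. Level values shift between patients (hypo
SD 0.06 clipped to [0.42, 0.64]; hyper SD 0.08 clipped to [1.16, 1.46];
mid-levels SD 0.015, ±2 SD) so per-patient cluster means span the published
ranges; the clip bounds are exactly those ranges. Observation noise is a
Gaussian on the PI scale, SD 0.02 (the low end of the published
within-cluster SDs), truncated at ±0.05.

Ictally, hypoperfused structures fall ~−20% and hyperperfused rise ~+30%;
the ipsilateral middle temporal gyrus rises +15% — *except* in high-risk
patients (score > 5), whose ipsilateral putamen, entorhinal and middle
temporal factors are 1.0 (no change). That no-change pattern is the planted
biomarker the screening stage must find.

Counts are constructed so that leave-one-out PI quantification returns the
planted values *exactly* for every structure off the normal level: with equal
ROI sizes the leave-one-out identity constrains the PI vector (Σ p/(73+p)
must equal 1), so the normal-level structures absorb the constraint through a
common rescaling of order 1–2% — they are the reference tissue, and their
exact PI is immaterial. Everything is deterministic per seed, bit-identical
across runs.

What the generator does **not** emulate: anatomically shaped ROIs,
registration error, correlated inter-state noise, scanner-specific count
statistics, or any true clinical association between perfusion and SUDEP-7
beyond the planted no-change pattern. Passing tests therefore demonstrate
that the pipeline recovers what was planted under these idealised conditions,
not that the biological findings replicate.

**Block phantoms** for the imaging path tile disjoint cubes (one per
structure, configurable size/gap; gap 0 makes neighbours adjacent so the PSF
mixes them) with activity `PI × poisson_scale`, blurred by the Gaussian PSF
and optionally Poisson-sampled. The PVC recovery check blurs a two-block
phantom at 8 mm FWHM and requires corrected means within 1% of planted
(identity at FWHM 0).

## Reference-cohort tables

The published per-patient clinical and cluster summaries of the nine-patient
DRFE cohort are transcribed in `reference_cohort.py`; the pipeline's
descriptive statistics are recomputed from them and checked against the
printed values (SUDEP-7 median 7, SE 0.55; injection-time SD 4.5 s, range
2–17 s; interictal hypo cluster means spanning 0.42–0.64; ictal hyper
1.16–1.46 with mean 1.322). Known internal inconsistencies of the published
summaries (a printed mean seizure duration and two printed PI ranges that do
not match their own table columns) are documented in that module; all
asserted quantities come from the tables themselves.

## Problem sizes

Defaults are desk-scale by design: 9 patients × 2 states × 74 structures;
K selection over candidates 2–10 with 10 folds and 20 restarts; 200 random
instances for the Lloyd-vs-DP oracle check; 200 permutation replicates for
screening calibration; 10 cohort seeds for planted-biomarker recovery;
40³-voxel phantoms. A full pipeline run and the whole verification suite
each complete in well under a minute per cohort on one CPU.
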