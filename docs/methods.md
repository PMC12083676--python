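# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic validation does and does not
establish about real data.

## Data model

All spatial data live on a `GridSpace`: a voxel grid (shape + 4×4 affine)
with a boolean analysis mask. The mask induces a fixed row-major linear
ordering of in-mask units; every per-unit array in the pipeline uses that
ordering, so there is exactly one flattening convention. Vertex-wise
(surface) data reuse the same container — a 1×n "grid" with identity
affine — and the surface-to-volume registration is abstracted as a supplied
vertex→voxel lookup (`resample_to_volume`), with voxel values the mean of
contributing vertices. Grid resolution is fully configurable; nothing in
the analysis depends on it.

Missing phenotype values are explicit (CSV tokens "", "NA", "NaN" → NaN);
`cfi_total` is computed as `cfi_pt + cfi_sp` when absent.

## Normative model and w-scores

Per-unit OLS of thickness on (1, age, sex), fitted on the Aβ− control
group; education is deliberately excluded here and enters later as an
inference covariate. Residual SD uses denominator n − p (p = 3); sex is
coded 0 = male, 1 = female. The w-score is (observed − predicted)/σ̂(v).
Two identities pin the implementation down: in-sample control w-maps have
per-unit mean exactly 0 and SD exactly √((n−p)/(n−1)); and the fit equals
an independent per-unit regression oracle to 1e-8.

Numerical conventions: an exactly-interpolated unit (residual SD below
1e-10 of the data scale) is snapped to σ̂ = 0; computing a w-score there is
an error unless observed = predicted, in which case w = 0.

**Seeds.** The default seed is the binary set {v : w(v) ≤ −2}; −2 means "2
SD thinner than expected", and the threshold is configurable (pipeline
robustness is exercised at −1.5 and −2 in the tests). A magnitude-weighted
mode, weight(v) = max(0, −w(v) − |threshold|), is provided because the
choice between binary and weighted seeding is genuinely open; output
metadata records which was used. An empty seed either errors or falls back
to the k = 50 most-negative voxels (logged), per configuration.

## Connectivity maps

For each connectome subject: Pearson r between the seed's (weight-)mean
time course and every voxel's series, clipped to |r| ≤ 1 − 1e-7 so a
single-voxel seed stays finite under atanh, then Fisher z. Aggregation
across connectome subjects is the per-voxel mean of z by default, with a
one-sample t alternative — both are exposed because the downstream
inference is agnostic to the choice, and the output records which was used.
Connectome subjects whose seed course is degenerate are skipped; more than
10% failing aborts the run. The connectome streams one subject at a time
with exact running sums, so memory is flat and results are identical to an
all-in-memory computation; `connectivity_maps` additionally batches all
cohort seeds into one pass (matrix products), verified against the
per-seed path to machine precision.

## Permutation inference

Per-unit t of the predictor (group dummy or SUVr) in an OLS with age, sex,
education and intercept; listwise deletion of incomplete subjects, counts
logged. FWE control references each unit's |t| to the permutation
distribution of the maximum |t| (two-sided default; signed one-sided modes
available).

Permutation schemes: Freedman–Lane (default — permute reduced-model
residuals, add back the nuisance fit, refit) and Manly (permute the
predictor). Internally Manly applies the *inverse* of the drawn
permutation to the predictor so that, for the same drawn permutation, the
two schemes induce the same (predictor, data) pairing and therefore agree
exactly whenever the nuisance matrix is intercept-only; the two schemes'
null distributions are unaffected by this convention.

p-value conventions: sampled mode uses (1 + b)/(1 + m), never zero;
when n! is at or below a configurable cap (default 10,000) exhaustive
enumeration over all index permutations (identity included) replaces
sampling and p = b/m is exact. Comparisons use a relative tie tolerance of
1e-8 because re-computing the identity permutation leaves O(ε) float
residue that must still count as "as extreme as observed". Exchangeability
blocks are explicitly unsupported (error), and no cluster/TFCE statistics
are offered: correction is voxelwise max-t only.

Inside permutation loops the GLM is evaluated via the
Frisch–Waugh–Lovell partial-correlation identity (residualize predictor
and data against the nuisance basis once, then one matrix product per
batch of permutations); the tests verify this path equals one-at-a-time
refits to ~1e-9.

## Map similarity

Spatial Pearson r between two maps on an explicit mask argument (the
correlated object is the *unthresholded* t-map — thresholded maps make r
degenerate). The permutation null shuffles the clinical measure across
subjects while covariates stay attached to their imaging, rebuilds the
t-map, and recomputes r; p is one-sided (greater), (1 + b)/(1 + m), with
1000 permutations by default.

## Leave-one-out validation

For each subject, the continuous-SUVr t-map is refitted without that
subject and correlated with the subject's own connectivity map. The
`downdate` engine subtracts each subject's rank-one contribution from
X'X, X'Y and the per-voxel sums of squares; the `naive` from-scratch refit
is the oracle, and the two agree to 1e-8 on every tested instance. A
duplicated-subject mutation test establishes that subject i is genuinely
excluded from their own reference map.

Associations: binary outcomes (Aβ status, suicidality/death-wish history)
use Welch's t; continuous outcomes use Pearson r with its t-distributed p.
For Aβ status both the group t and the regression-style r on a 0/1 coding
are emitted, since either convention is defensible. Raw p-values are the
primary output across the 14 standard outcomes; a Bonferroni column is
added as good practice. Constant outcomes are an error at the function
level; the orchestrator can record them as missing rows instead, since a
rare binary history can be constant in a small cohort.

## Synthetic cohort

What it emulates, and the generating defaults (all configurable, all
driven by one seed with bit-identical reproducibility):

* **Connectome**: each voxel's series is √w·latent(network) + √(1−w)·noise,
  both stationary unit-variance AR(1) (ρ = 0.3), standardized per voxel.
  Same-network voxels correlate at w in expectation (default w = 0.5, a
  realistic within-network coherence); cross-network voxels at 0. Networks
  are contiguous equal blocks of the in-mask ordering by default.
* **Cohort**: age 71.5 ± 4.7 y, 59.6% female, education 16.6 ± 2.8 y;
  SUVr from a two-component mixture (Aβ− 0.99 ± 0.07, Aβ+ 1.33 ± 0.18,
  70% positive); a simulated visual read equals the mixture component with
  a 5% flip rate and is only consulted in the 1.10–1.15 band.
* **Thickness**: intercept 2.90 mm, age slope −0.01 mm/y, sex effect
  −0.02 mm, voxel noise SD 0.10 mm — giving a mean thickness near 2.18 mm
  at the cohort's mean age.
* **Planted effect**: thinning = gain · max(0, SUVr − 1.15) · affinity(v),
  where affinity is the voxel's connectivity to a designated target network
  computed from the simulated connectome itself and min-max scaled to
  [0, 1]. Planting atrophy as a smooth function of connectivity (rather
  than a fixed ROI) gives the network-level method a well-defined true
  positive set: the top-decile affinity voxels. The hinge mirrors the
  clinical threshold; a signed linear link is available. Default gain
  0.6 mm per SUVr unit puts a typical Aβ+ subject (SUVr ≈ 1.33) at about
  one noise-SD of thinning at the network core — chosen to make effects
  detectable at n ≈ 200, not as a claim about real effect sizes.
* **Cognition**: PACC = −c·load + ε, CFI subscores = +c/2·load + ε each,
  with load the subject's mean planted thinning, c = 50 score-units per mm
  and ε SD 2.6 — reproducing a group gap of the order of the published
  cohort's PACC difference at its SD. Digit Symbol, FCSRT and MMSE carry
  half couplings; delayed logical memory, GDS, FTPS and the suicidality
  histories are deliberately uncoupled so "no association" also has a
  ground truth.

What the generator does **not** emulate: cortical geometry and spatial
autocorrelation of noise, scanner/site effects, partial volume,
non-Gaussian thickness distributions, hemodynamics beyond AR(1), and any
longitudinal dynamics. Passing tests therefore establish the *algorithmic*
correctness and calibration of the pipeline under its own assumptions, not
the effect sizes or anatomical claims one would obtain from real cohorts.

## Problem sizes in the test suite

Unit and property tests run on grids of 8–512 voxels. The study-scale
validation uses n = 200 subjects, 50 connectome subjects and a 2000-voxel
grid with 500-permutation max-t inference; FWE calibration uses 200 null
replicates (n = 40, 500 voxels, 500 permutations); similarity-null
uniformity uses 100 meta-replicates of 100 tests at 200 permutations.
These sizes were chosen as the smallest at which the statistical properties
under test are stable.

## Known limitations

* Binary + intercept-only exhaustive enumeration grows as n!; the cap
  (10,000) limits exact mode to n ≤ 7 — beyond that, sampled permutations.
* The max-t correction assumes exchangeable subjects; families, sites or
  repeated measures would require exchangeability blocks, which are
  rejected rather than approximated.
* The LOO downdating assumes the design stays full-rank after each
  removal; degenerate removals yield missing scores with a warning.
* `t_stat` aggregation of connectivity maps is undefined for single-voxel
  seeds whose own voxel hits the correlation clip; such maps are flagged
  `degenerate` rather than silently truncated.
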