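# Methods

This note documents the models, defaults and design choices behind
`atroseq`: a pipeline that infers the origin and order of progressive
grey-matter loss from *cross-sectional* morphometry by combining voxel-wise
group statistics, Granger causality on severity-ranked pseudo-time series,
and event-based modelling.

## Synthetic cohorts (`atroseq.synthetic_cohort`)

**Model.** Each region *r* is a disjoint axis-aligned block (or sphere) on a
voxel lattice.  A subject at disease severity *s* (sum-of-boxes units,
0–24) has expected in-region density

    B_r − A_r · logistic((s − s0_r) / w_r)
      + β_age (age − age_ref) + β_sex [sex = M] + site_offset,

i.e. a sigmoidal loss trajectory with baseline `B_r`, amplitude `A_r`,
onset `s0_r` (severity of half-maximal loss) and transition width `w_r`,
plus linear covariate effects.  Out-of-region voxels sit at a constant
background of 0.5, safely above the 0.1 absolute masking threshold.
Independent Gaussian voxel noise (SD σ) and optional isotropic Gaussian
smoothing come last.  Patients draw severities uniformly from a configured
range; controls sit at severity 0 and are generated through the identical
code path, so the two groups are exchangeable at matched severity.

**Defaults and why.** 150 patients / 80 controls; 24³ lattice at 1.5 mm;
eight 5×5×5 regions named after a frontoinsular-origin cascade (anterior
insula → orbitofrontal → putamen/accumbens → pregenual ACC → DLPFC →
inferior temporal → supramarginal → lingual); `B = 0.8`, `A = 0.35`,
onsets 5.0–15.5 evenly spaced, `w = 5.0`, `σ = 0.03`; severity range 2–22
(uniform, so every regional transition is observed); β_age = −0.003/yr,
β_sex = +0.01, two scanner sites with a +0.01 offset.  The wide,
overlapping transitions matter: with narrow sigmoids the seed region's
trajectory saturates early and carries no lagged information about
late-transitioning regions, and the Granger stage (correctly) finds
nothing downstream.  Real atrophy trajectories are gradual on the scale of
the whole severity range, which is what the wide default emulates.  These
values were fixed once, as the generator's definition of "realistic", and
all recovery results are reported under them.

**What passing tests show — and don't.** Recovery of the ground-truth
cascade demonstrates the estimators' correctness under the generator's
assumptions (regional homogeneity, iid noise, sigmoidal monotone loss,
uniform severity coverage).  It does not establish performance under real
anatomy, spatially correlated noise, segmentation error, diagnostic
heterogeneity, or non-uniform severity distributions.

## Cohort statistics (`atroseq.cohort_stats`)

Pooled-variance Student *t* (not Welch) and Pearson χ² without continuity
correction, selected because they reproduce the published statistics of the
reference cohort table from its printed summaries.  Both accept raw
columns or `GroupSummary(n, mean, sd)` triples.  Three printed cells do not
recompute from their own printed summaries (moderate-stage age *t*,
moderate-stage education *t* — whose summaries duplicate the mild row —
and severe-stage sex χ², each off by 0.01–0.10); these are reported as
computed, not forced to the printed value.

## Voxel-wise group GLM (`atroseq.vbm_stats`)

OLS per in-mask voxel on `[intercept, patient, sex, age, education, TIV,
site dummies]`; the atrophy statistic is the negated patient-coefficient
*t* (positive where patients have less grey matter); residual df
= n − rank(X).  Analysis mask: mean density ≥ 0.1.  Choices:

* **FWE = Bonferroni**, not random-field theory: deterministic,
  assumption-free and conservative at desk scale.  This diverges from SPM
  and is recorded in output metadata.
* **Cluster connectivity 26** by default (6/18 configurable); the SPM
  convention is not universal, so it is surfaced as a parameter.
* Rank-deficient designs raise an error naming the columns that add no
  rank given the columns listed before them.
* Peaks are reported in 0-based lattice indices and in mm via the NIfTI
  affine; tied peak statistics resolve to the lexicographically smallest
  index; clusters sort by size, then peak statistic, then peak index.

The seed ("epicentre") is the FWE-surviving cluster containing the global
peak, intersected with a user-supplied atlas mask; an empty intersection is
an explicit error rather than a silent fallback.

## Causal structural covariance network (`atroseq.cascn`)

Patients are ordered by ascending severity (stable sort, ties by subject
id) to form a pseudo-time series; the seed series is the mean density over
the seed mask.  Per voxel the order-1 signed-path model

    y_t = α + a·y_{t−1} + b·x_{t−1} + γᵀz_t + ε_t ,  t = 2..T

is fit by least squares, with contemporaneous covariates z_t = (sex, age,
education, TIV, site dummies, Δs_t) and Δs_1 ≡ 0.  The per-step severity
increment (rather than a cumulative clock) is used as the time-interval
covariate.  The reported z is the Wald ratio b/SE(b) with p from the
Student t reference; an across-voxel standardisation mode exists behind a
flag (`standardize=True` z-scores the series first), default off.  Model
order is fixed at 1 — the convention of seed-based signed-path
implementations — and configurable.

Only positive-*b* voxels are eligible (the directional hypothesis: seed
loss precedes target loss); BH-FDR runs over exactly that eligible set;
seed voxels are excluded from the reported map because self-influence is
trivial.  The whole voxel grid is fit in one batched pass via per-voxel
Gram matrices assembled from shared matrix products; voxels with singular
or ill-conditioned (cond > 1e12) Gram matrices are dropped and counted
(`GCAMap.n_failed`), and constant voxels return b = z = 0, p = 1 by
convention.

A note on interpretation: in the generator there is no mechanistic
coupling between regions — all regions respond to the same latent severity
with different onsets.  The positive lagged-seed coefficient detects
*temporal precedence within the pseudo-time ordering*, which is exactly
what the method claims, not biophysical transmission.

## Event-based model (`atroseq.ebm`)

**Mixtures.** Per event, normal and abnormal densities are Gaussian-kernel
KDEs with Silverman bandwidths on responsibility-weighted samples (scipy
`gaussian_kde` conventions: neff-based factor, unbiased weighted variance).
Initialisation: normal from controls, abnormal from the patient tail below
the control median.  The fit alternates posterior responsibilities and
weighted refits, stopping when the normal-component weight w changes by
< 1e-4 or after 100 iterations (the cap binds in practice: w drifts
geometrically with ratio ≈ 0.96).  Controls are anchored to the normal
component — their labels are known, and anchoring prevents label drift on
weak events.  The atrophy direction (abnormal median < normal median) is
enforced by swapping components if violated.  During the alternation the
densities are evaluated from a precomputed squared-distance matrix, which
is numerically identical to, and ~2× faster than, constructing scipy KDE
objects per iteration; the returned components are scipy KDEs built from
the final weights.

**Likelihood and search.** log L(S) uses the uniform stage prior over
k = 0..N with both cohorts contributing; densities are floored at 1e-250
before the log.  Greedy ascent (default 10 chains × 10,000 uniform-random
transpositions, accept only strict improvement) initialises Metropolis
MCMC (default 500,000 transpositions, accept with min(1, exp(ΔlogL));
equal-likelihood proposals always accepted).  The reported sequence is the
maximum-likelihood sequence *visited*, without burn-in subtraction; the
trace is kept for diagnostics.  Both searches memoise the likelihood of
every transposition neighbour of the current state (cache invalidated on
acceptance): a rejected proposal leaves the state unchanged, so repeat
proposals are free and the trajectory is bit-identical to the uncached
computation.  The hot loops are numba-compiled when available, with an
exactly mirrored NumPy fallback cross-tested against them.  One RNG seed
drives chain initialisations, proposals, acceptance draws and fold
assignment, so a full run is reproducible from a single integer.

Two formulation choices are surfaced as flags on `EventBasedModel`:
biomarkers enter as raw densities by default, with `standardize=True`
z-scoring each event column first; and both cohorts contribute to the
sequence likelihood by default (the standard formulation — controls
anchor stage 0), with `include_controls=False` restricting the likelihood
to patients while mixtures are still fit on everyone.

**Cross-validation and the final sequence.** 10 repeats of stratified
5-fold CV (sklearn `StratifiedKFold`), refitting mixtures and sequence on
each 80% training split and recording the held-out log-likelihood; the 50
ML sequences define the positional variance matrix P[e, pos].  The final
sequence sorts events by expected position Σ pos·P[e, pos] (ties by event
index); a modal-position rule is available behind `rule="modal"`.

**Null behaviour.** When patients are indistinguishable from controls, the
mixture keeps almost all mass normal (w → ~0.8–0.95 rather than exactly 1:
the tail-initialised abnormal component retains the few lowest patients).
A flat positional variance diagram is the correct null signature, but it
must be assessed **across independent replicate datasets**: CV folds of a
single dataset share that dataset's sampling noise and therefore agree on
a spurious but data-fixed ordering.  Across 100 independent null cohorts
the position distribution is uniform (max entry 0.26 < 2/N); within one
null cohort the 50-fold diagram can concentrate arbitrarily.  The tests
encode the across-replicates version.

**Staging.** P(k | x, S) ∝ ∏_{i≤k} p_abn ∏_{i>k} p_norm, normalised over
k — the standard stage posterior; `EventBasedModel.predict` returns its
argmax.

## Pipeline and formats (`atroseq.io`, `atroseq.pipeline`, `atroseq.cli`)

Stage order: VBM (FDR q = 0.005, extent 300) → seed (Bonferroni α = 1e-5,
extent 500) → CaSCN (FDR q = 0.001, extent 100) → region extraction → EBM
(10 × 5 CV; greedy 10 × 10,000; MCMC 500,000).  All thresholds live in
`RunConfig` (JSON/YAML) — nothing is hard-coded — and the thresholds
actually applied are logged and written to a provenance sidecar together
with the config hash, seed and library versions.  Maps are float32 NIfTI-1
on disk, float64 internally; tables are TSV; results JSON is written with
sorted keys and no timestamps, so identical config + seed reproduces
byte-identical result files.  A failing stage aborts with its name and
preserves earlier artefacts.

For the bundled synthetic grid, `synthetic_run_config` scales the extent
thresholds to the 125-voxel regions (40/40/20) and shortens the MCMC chain
to 50,000 iterations — an 8-event permutation space (40,320 states) needs
nothing more — while keeping every other analysis setting at its full-size
default.  Validation problem sizes used by the test suite and the
acceptance script: 3-event × 200-subject cohorts for oracle-equivalence
(100 replicates), the default 230-subject cohort for cascade recovery (10
generator seeds), length-80 series × 1,000 replicates for the Granger null
calibration.

## Known limitations

* Bonferroni FWE is conservative relative to random-field theory; on real
  smoothed maps it will under-select.
* The GCA stage assumes a single seed and order-1 lags; multivariate or
  conditional extensions are out of scope.
* KDE mixtures need ≥ 5 subjects per diagnosis per event and fail loudly
  on constant biomarkers.
* Pseudo-time ordering treats the severity score as a noiseless ranking;
  severity measurement error is not modelled.
* The "final sequence" aggregation rule (expected position over CV models)
  is one reasonable convention among several; the modal rule is provided
  for sensitivity analysis.
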