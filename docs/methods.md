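# Methods

`dynfnc` implements a resting-state functional network connectivity (FNC)
analysis of the kind used to study treatment-induced network reorganization
in the Alzheimer's disease spectrum: static FNC, tapered sliding-window
dynamic FNC with k-means connectivity states, pre/post group statistics on
cognitive-domain composites, and individualized prediction of treatment
response from baseline connectivity.  Because subject-level fMRI and
neuropsychological data of such cohorts are not publicly deposited, the
package ships a synthetic cohort generator with planted ground truth; every
pipeline stage is validated by recovery of what was planted, plus one exact
recomputation from published group-level moments.

## Pipeline model

**Time courses.** The pipeline's currency is per-subject-session component
time courses `(14 components × 230 TRs, TR = 2 s by default)`.  Cleaning
per component: removal of the constant+linear trend, Hampel despiking
(centered window of 7 samples, threshold 3.5 robust SDs, robust SD =
1.4826·MAD, outliers replaced by the local median), and a zero-phase
5th-order Butterworth low-pass at 0.15 Hz.  The despike threshold and
passband are package defaults; the cleaning steps themselves are the
standard FNC preprocessing sequence.

**Static FNC.** Pearson correlation of every component pair over the whole
scan, capped at |r| ≤ 1−10⁻⁷ and Fisher z-transformed (atanh).  The cap
keeps duplicated signals finite.

**Dynamic FNC.** A tapered window (rectangle of L = 30 TRs convolved with
a Gaussian of σ = 3 TRs, truncated at ±4σ, cropped to its central L
samples, renormalized to sum 1) slides in steps of 1 TR, giving
T − L + 1 = 201 windows per session.  The taper enters as observation
weights in a weighted Pearson correlation (weighted means and covariances),
which preserves the correlation scale; windowed values are Fisher-z
transformed by default (`window_fisher_z` switches this off) so windowed
and static values live on a comparable scale.  Temporal variability of a
pair is the sample SD (denominator n−1) of its windowed z values.

**Connectivity states.** Exemplar windows are those at strict local maxima
of the across-pair variance of windowed FNC (endpoints never qualify; a
session with no strict maximum contributes its global-maximum window).
Exemplars of all subject-sessions — pre and post pooled, so both sessions
share one state vocabulary — are clustered with k-means under the
city-block metric (centroid update = coordinate-wise median, the L1
optimum; k-means++ seeding; 150 random restarts, best objective kept;
Euclidean available by configuration).  The number of states is scanned
over k = 2..10 and chosen by the elbow of
`ratio(k) = mean distance of exemplars to their centroid / mean pairwise
inter-centroid distance`.  All windows are then assigned to the nearest
centroid (ties to the lowest state index) without refitting — the
established exemplar-train/full-assign two-stage scheme.

*Elbow operationalization.*  The elbow is the interior k maximizing the
discrete second difference of **log** ratio(k).  The raw-scale second
difference is dominated by the large relative drop from strongly underfit
k (the ratio can halve between k = 2 and 3), which masks the bend at the
true state count; log-scale curvature is scale-invariant, so the bend is
judged by relative, not absolute, change.  The within/between ratio itself
is the standard criterion; only the bend-detection rule is a package
choice, and the recovery it achieves is what the state-count acceptance
test measures.

**State metrics.** Per subject-session state sequence: fractional time
(occupancy), mean dwell time (mean run length in windows; NaN for
unvisited states, which are excluded — not zero-filled — from group
statistics, since zero-filling biases means), number of transitions, and
the row-stochastic transition-probability matrix (NaN rows for states with
no outgoing step).  Identities `Σ fractional = 1`, `Σ dwell·runs = length`
and row sums = 1 are property-tested against an independent run-length
encoding oracle.

**Cognitive composites.** Raw subtest scores are pooled over pre and post
(2n values), z-scored against the pooled mean and sample SD (denominator
2n−1), sign-flipped where a higher raw score means worse performance
(timed tests), and averaged within domain.  Pooled centering makes the
baseline and post composite group means exact negatives — the ± symmetry
visible in published cohort tables, which is also what identifies this
convention: recomputing composites from published per-subtest group
moments (n = 28) reproduces the printed baseline means of the three
untimed domains (memory −0.27, visuospatial −0.06, language −0.15) to two
decimals.  The two domains containing timed/Stroop measures do not
recompute under either Stroop orientation, so their published scoring
convention is unknown and they are not recomputation targets.  Group
comparisons use paired t tests on d = pre − post (improvement on a
higher-is-better score gives negative t), Pearson correlations relate
change scores, and no multiplicity correction is applied by default
(mirroring the exploratory analyses emulated; a Benjamini–Hochberg switch
exists but is off).

**Prediction.** Leave-one-out cross-validated epsilon-SVR, linear kernel,
C = 1, epsilon = 0.1, no nested tuning (a deliberately simple single-model
protocol).  Per fold: features are ranked by |Pearson r| with the change
score on the n−1 training subjects (kept if p < 0.05 uncorrected, ties to
the lower feature index), and models with the top 1..m features are fit
with training-fold standardization (the held-out subject never enters
ranking, scaling, or fitting — asserted by a poisoned-subject test).
Accuracy is R(m) = Pearson(observed, pooled predictions), maximized over
m; `max_features` defaults to the smallest fold's passing count, capped at
n−2.  Consensus features are the intersection over folds of the top-(best
m) selections.  Because best-m is chosen on the pooled predictions, R(best)
is optimistic; `permutation_pvalue` re-runs the entire procedure (per-fold
re-ranking included) on permuted targets, p = (1 + #{R_perm ≥ R_obs}) /
(n_perm + 1).  Feature families (sFNC, per-state dFNC means, variability)
are modelled separately.

**Group ICA (optional volumetric entry point).** Model order by the
classical Wax–Kailath MDL on the covariance eigenvalue spectrum with
voxels as samples (the fMRI-specific i.i.d. correction of some toolboxes
is out of scope).  Two-stage reduction: subject-level temporal PCA (51
components by default), temporal concatenation, group PCA to the IC count
(34 by default).  Unmixing by natural-gradient Infomax with a logistic
nonlinearity (full batch; learning rate 0.1, annealed ×0.97 when the
gradient norm grows by >10%; tolerance 10⁻⁶ on the relative update norm;
2048 iterations maximum; non-convergence warns and flags, never raises).
ICASSO-style reliability: ICA repeated with distinct seeds (20 by
default), pooled estimates clustered by average-linkage agglomeration of
1 − |r|, cluster centrotypes kept, stability = within-cluster minus
between-cluster mean |r| clipped to [0, 1].  Subject time courses and maps
come from spatial then temporal regression against the group maps
(spatial–temporal back-reconstruction), which is exact on noiseless data
with orthonormal maps.  Component signs follow the convention that each
map's largest-|value| voxel is positive.  Network labelling matches
components to user-supplied templates by spatial |r| (threshold 0.25, one
component per label, best match wins); no canonical template set is
bundled.  The pipeline's primary entry point is component time courses, so
desk-scale work never requires volumetric data.

## Synthetic cohort: what it emulates, and what it does not

Each subject-session's component vectors are drawn TR-by-TR from one of
`n_states = 5` planted covariance (correlation) matrices selected by a
sticky Markov chain (uniform initial state; stay probability 0.99; uniform
jumps otherwise), plus isotropic observation noise (SD 0.2).  States
switch at TR resolution, so windows straddling a switch mix states — the
regime where windowed clustering is genuinely stressed.

*State geometry.*  State s has correlations `R_ij = 0.6·v_i·v_j` for a
state-specific sign vector v (rank-one structure, positive definite, all
|r| = 0.6).  Sign vectors are chosen (deterministically) so any two states
disagree on roughly half the free components, maximizing the number of
component pairs whose correlation flips sign between states — the
strongest separation attainable at this correlation strength.  The first
four components (rFPN, lFPN, aDMN, pDMN) never flip, so the six pairs
among them are state-invariant: their baseline connectivity carries purely
subject-level information, which is what the prediction couplings need.
With 30-TR tapered windows, per-pair windowed-z sampling noise has SD
≈ 0.2, so within-state city-block dispersion over 91 pairs is ≈ 15 against
inter-centroid separations of ≈ 70 — well-separated, though the taper
length puts a floor on dispersion that no geometry can remove.

*Stickiness.*  Stay probability 0.99 gives a mean dwell of 100 TRs
(200 s): long against the 30-TR window, so most windows are state-pure,
and short against the 230-TR session, so sessions still switch (~2–3
segments).  A chain with dwell shorter than the window makes every window
a state mixture and the state-count question ill-posed at any separation.

*Subject heterogeneity.*  Each subject carries trait-like connectivity
offsets (symmetric, SD 0.15 per pair on the correlation scale, shared by
both sessions and all states; matrices re-projected to the nearest valid
correlation by eigenvalue clipping at 10⁻⁶).  Without this, all 91
baseline sFNC features are driven by one latent occupancy vector and are
so collinear that no feature-selection procedure could isolate planted
couplings.

*Treatment effects.*  Post-session state matrices carry +0.3 on rFPN–lFPN
and −0.3 on pVN–mVN (correlation scale, applied per state, nearest-valid
projection afterwards; an effect driving |r| ≥ 1 is a configuration
error naming the pair).  Effect directions mirror the treatment-induced
increase between the frontoparietal networks and decrease within the
visual networks that motivate the pipeline; the 0.3 magnitude gives a
planted effect detectable by the paired test in ≥ 9 of 10 cohorts at
n = 30.

*Cognition.*  The memory change score is
`Δ = Σ beta·(baseline sFNC feature) + N(0, 0.16)` with unit couplings on
rFPN–lFPN and aDMN–pDMN; pre scores are independent standard normals and
post = pre + Δ.  The noise SD was set once so that the planted signal to
noise variance ratio is ≈ 2 at the default feature scale (planted-feature
SD ≈ 0.13 each).

*Determinism.*  One cohort seed fans out to per-subject substreams
(`numpy.random.SeedSequence.spawn`), so enlarging the cohort leaves
existing subjects bit-identical.  The state geometry uses a fixed internal
seed: it is study design, not a random draw.

*Not emulated:* hemodynamic convolution, scanner drift, motion artifacts,
spatial realism of maps, session-specific state vocabularies, and any
non-Gaussian marginal structure of real BOLD time courses.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not performance on real fMRI.

## Numerical choices and edge cases

- r-cap 1−10⁻⁷ before atanh; windowed correlations with a zero-variance
  window are set to 0 rather than raising (static FNC raises, naming the
  component).
- Exemplar variance ties and nearest-centroid ties break to the lowest
  index; the elbow tie breaks to the lower k.
- Empty k-means clusters are re-seeded at the worst-fit point.
- A fold whose ranking is empty contributes no prediction; the run aborts
  only if every fold is empty.  Permutations that abort count as no
  evidence of signal.
- Byte-identical outputs for a fixed configuration: CSVs are written with
  `%.10g`, JSON with sorted keys, and the run manifest contains no
  timestamps.  The manifest's parameter hash covers every parameter except
  the output directory.

## Desk-scale problem sizes

Clustering benchmarks (and the acceptance recomputation) use 20 subjects ×
2 sessions = 40 subject-sessions of 230 TRs — the smallest cohort at which
the elbow selection is stable over seeds — with the full 150-replicate,
k = 2..10 protocol, majority-voted over 10 cohort seeds.  Prediction
recovery uses n = 30 subjects (the emulated trial's imaging cohort size);
permutation-null calibration uses n = 16 with 10 features, ranking alpha
0.2 and 99 permutations per replicate.  Window-level state-recovery
accuracy uses 8-subject cohorts with 20 clustering restarts at the planted
k.  The decomposition benchmark plants q = 8 components over 2000 voxels
and 150 TRs at noise SD 0.1.

## Known limitations

- City-block k-means with coordinate-median updates converges to a local
  optimum per restart; correctness relies on many restarts, not on any
  global guarantee.
- The MDL order estimate treats voxels as i.i.d. samples; spatially
  smoothed real data violate this and typically inflate the estimated
  order.
- The permutation p-value wraps the full selection procedure but not the
  choice of feature family; running several families and reporting the
  best remains a multiplicity the package does not correct.
- Infomax with a logistic nonlinearity separates super-Gaussian sources
  only; Gaussian or sub-Gaussian sources return with convergence metadata
  but no recovery guarantee (the extended-Infomax switch is not
  implemented).
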