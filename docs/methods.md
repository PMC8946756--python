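# Methods

`lowernet` implements a single-subject detection pipeline for the four
lower-order resting-state fMRI networks — sensorimotor (SM), auditory (AUD),
lateral visual (LVIS) and medial visual (MVIS) — and a classification layer
that separates vegetative state / unresponsive wakefulness syndrome (VS/UWS)
from the minimally conscious state (MCS) using network scores, map
intensities, structural ratings and clinical covariates.  Because no patient
data ship with the package, a first-class synthetic-cohort generator supplies
inputs with the statistical structure the analysis assumes; every stage is
tested against that generator's ground truth.

## Synthetic cohort model

Each subject receives a 4D BOLD run (default 32 x 32 x 24 voxels of 3 mm,
200 volumes at TR = 2.8 s, about 9.5 minutes) on a synthetic brain: an
ellipsoidal brain mask with a white-matter core and a small CSF ventricle.
Ten spherical nodes (radius 6 mm = 2 voxels) are laid out so that
within-network node spacing exceeds the smoothing support; SM has four nodes
(bilateral pre/post-central and supplementary motor area analogues), the
other networks two bilateral nodes each.

Signal model, per network *g* with unit-variance band-limited
(0.01–0.08 Hz) latent *s_g(t)*:

    x_v(t) = c_v * s_g(t) + sqrt(1 - c_v^2) * sigma * eps_v(t)

for voxels *v* in a node of *g*, with iid standard-normal noise eps and
noise scale sigma (`noise_sd`, default 1, at which the voxel–latent
correlation equals the coupling *c_v* exactly).  Coupling is graded by
diagnosis — defaults 0.2 (VS/UWS), 0.5 (MCS), 0.8 (SD), 0.85 (controls) —
the reference study conditions used by the test suite.  Lesions strike each
node with an etiology-dependent probability (traumatic 0.25, vascular 0.35,
anoxic 0.30) scaled by clinical severity (VS/UWS 1.4, MCS 1.0, SD 0.5); a
lesioned node multiplies its coupling by U(0, 0.3), zeroes the corresponding
grey matter in the structural volume, and lowers its 0–4 structural MRI
rating into the 0–2 range.  The severity scaling matters: without it,
structural ratings would carry no diagnostic signal and the MRI-rating
classification model would be uninformative, contrary to the data structure
the pipeline is meant to emulate.

On top of the network signal the generator adds:

* **Structured noise sources** (default 30 per subject): focal Gaussian
  blobs (sigma 1.5–3 voxels) at random brain locations with broadband time
  courses and amplitudes 0.8–2.0 x `noise_sd`.  These emulate the vascular
  and physiological components that dominate real resting-state
  decompositions.  They are essential, not cosmetic: without them a
  fixed-order ICA of a 200-volume run recovers even a coupling-0.2 network
  almost surely, and detection would not grade with diagnosis.  With ~30
  structured sources competing for 30 components, weak networks fall below
  the decomposition floor — the mechanism that makes component vetting
  meaningful.  The source count and amplitude were fixed once so that the
  cohort reproduces the qualitative regime reported for chronic DoC:
  network-count modes near 0 (VS/UWS), 2–3 (MCS) and 4 (SD), with ICA
  recovering fewer networks than seed-based analysis.
* **Compartment signals and drift**: slow WM and CSF signals inside their
  masks and a linear trend over the brain (amplitude 0.5 x `noise_sd`),
  giving the confound regressors something real to remove.
* **Motion**: a small random-walk drift plus spike frames
  (probability 0.02/frame, 3 mm translation jumps) with matching global
  artifact frames in the data, to exercise scrubbing.

Clinical scores are drawn from residual coupling: CRS-R total =
clip(2 + 20·mean-coupling + N(0, 1.5), 0, 23), so totals track diagnosis
stochastically; the visual subscale spans its full 0–5 range in proportion
to visual-network coupling, while motor (mass on 2) and auditory (mass on
1–2) are polarized, reproducing the subscale asymmetry that limits
motor/auditory correlations in real cohorts.  Ground-truth network presence
is defined as at least one node (two for SM) retaining effective coupling
>= 0.35.

Everything is reproducible bit-for-bit from one integer seed; clinical
draws and BOLD synthesis use separate child streams, so cohorts can be
generated records-only for cheap statistical tests.

### What the generator does not emulate

No spatial autocorrelation of thermal noise, no EPI distortion or slice
timing, no registration error (volumes are generated aligned, so
normalization is out of scope), no multi-site effects, no negative/
anticorrelated networks.  Passing tests therefore demonstrate the
*procedure* — thresholds, selection rules, inference and cross-validation
behave as specified under a controlled signal model — not performance on
real patient data.

## Preprocessing

Fixed order: framewise displacement (Power formulation, 50 mm head radius)
with outliers at FD strictly greater than 2 mm; OLS confound regression
(6 motion parameters, mean WM, mean CSF, Legendre polynomial trends up to
order 4, one one-hot regressor per outlier frame — spike regression rather
than deletion, preserving series length for filtering); 0.01–0.1 Hz
band-pass as zero-phase rFFT masking with a one-bin raised-cosine
transition (deterministic, testable gains); 6 mm FWHM Gaussian smoothing
(sigma = FWHM / 2.355 per axis).  Polynomial order, thresholds and band
edges are configuration values; band edges are validated against the
Nyquist frequency before any computation.

## Seed-based analysis

Per node, the mean time course of the 6 mm seed sphere enters a whole-brain
Pearson correlation; maps are Fisher z-transformed (z clipped at
atanh(1 − 1e−7)) and thresholded at z > 0.55, one-sided, so only positive
connectivity survives.  Whether the published threshold is Fisher z or a
normalized statistic is ambiguous; unscaled Fisher z is used and documented
in the configuration.  Two placements per seed are computed — the model
coordinate, and a subject-specific coordinate at the best-preserved grey
matter within 3 voxels (ties resolved to the literature coordinate, then to
the lowest linear index) — and the better map is chosen by two auditable
scores: specificity (suprathreshold mass inside the network template over
total mass) and noise (suprathreshold fraction outside a 2-voxel template
dilation).  Left and right seed maps stay separate until the group stage,
which fuses them by voxelwise maximum.

## ICA and component vetting

Spatial ICA with a fixed 30 components (whitening + fixed-point unmixing via
FastICA with deflation; the symmetric variant does not converge when the
minor components are Gaussian).  Maps are z-scored over the brain mask and
sign-fixed to positive skewness so the z >= 3 component threshold is
comparable across subjects.  Group templates come from temporally
concatenated control runs: per network, the component best correlated with
the network's node-ROI mask, binarized at z >= 3.  Candidate patient
components are ranked by template correlation (the similarity index) and
vetted on three thresholds, all in configuration: specificity ratio
(in-template over out-of-template suprathreshold mass) >= 1, low-frequency
(< 0.1 Hz) spectral fraction >= 0.5, and lag-1 autocorrelation of the time
course >= 0.3.  The first-ranked component passing all three is the
network's component; none may pass.

## Rating, presence and intensity

The 0–3 per-node rating of real data is an expert judgment; the automated
proxy scores a map from coverage *c* (fraction of rating-ROI voxels
suprathreshold) and specificity *s* (in-template mass over total mass):
0 with no suprathreshold ROI voxel, 3 when c >= 0.4 and s >= 0.5, 2 when
c >= 0.1 and s >= 0.25, else 1.  For ICA maps the rating ROI is the node's
own sphere.  For SBA maps it is the union of the network's *other* nodes:
after 6 mm smoothing the seed's own neighbourhood is suprathreshold at any
coupling (the seed average shares smoothed noise with its neighbours), so
own-node coverage cannot separate a destroyed network from a preserved one,
whereas reaching the contralateral node can.  Externally supplied human
ratings (which may carry half steps from rater averaging) override the
proxy wherever present.

Presence: rating >= 2 on at least one node (ICA or SBA) for AUD/LVIS/MVIS,
on at least two distinct nodes for SM.  Intensity: mean map value over the
node sphere per method, ICA and SBA means added, aggregated into left and
right hemisphere sums per network.  Structural ratings are averaged over
raters per node and summed per network.

## Group statistics

Mann–Whitney U uses exact enumeration (conditional on tie-averaged ranks)
for n1 + n2 <= 12 and a tie-corrected normal approximation with continuity
correction otherwise.  Spearman rho is Pearson on average ranks, with exact
permutation p for n <= 8.  The voxelwise analysis correlates subject maps
(SBA, left/right max-fused) with a clinical subscale using Spearman rho per
voxel; inference is by score-label permutation with add-one smoothed
p-values, and family-wise error is controlled by the permutation
distribution of the maximum |rho| over in-mask voxels (999 permutations by
default, seeded).  Subjects whose map rating is 0 or 0.5 are excluded
beforehand — zero-filled maps would generate spurious correlations.
Inter-rater agreement is quadratic-weighted kappa; the statistic behind the
published agreement values is unnamed there, and kappa is the ordinal-scale
convention.

## Classification

Feature models per scope (single network or all four): (1) rs-fMRI rating,
2 scores per node; (2) rs-fMRI map intensity, 2 scores per node; (3) MRI
rating, 1 score per node; (4) = 1 + 3; (5) = 2 + 3; each also with a
clinical block (etiology dummy-coded against a traumatic reference, disease
duration, age), plus a clinical-only baseline.  Columns are standardized
before L1-penalized logistic regression (liblinear with a large intercept
scaling, leaving the intercept effectively unpenalized); the penalty weight
is selected by inner stratified 10-fold cross-validation maximizing
out-of-fold log-likelihood over a fixed grid (leave-pair-out when a class
is too small to stratify).  If nothing is retained the model degrades to an
intercept-only fit of the training prevalence, flagged.

Validation re-runs the whole pipeline — standardization, penalty selection,
fit — on each training split (leave-one-out by default, stratified 10-fold
as an alternative).  MCS is the positive class; classification uses the 0.5
probability cutoff; balanced accuracy is (sensitivity + specificity) / 2;
sensitivity/specificity CIs come from 2000 stratified bootstrap replicates.
The AUC is the rank statistic over pooled held-out scores, with one
correction: folds whose model retained no variables contribute a tied score
of 0.5, because their predicted probability encodes the training fold's
class balance rather than the held-out patient — pooled naively, those
probabilities rank every held-out positive below every held-out negative
and bias the null AUC to zero.  Model comparisons use McNemar's test on
discordant pairs (exact binomial up to 25 discordant pairs, chi-square with
continuity correction beyond).  AUC quality bands assign boundaries upward
(0.80 reads "very good").  Per-etiology runs repeat the full evaluation
within each stratum; strata with one class are skipped with a flag, strata
with under five patients per class are flagged underpowered; a stratum
model that predicts one class constantly has an undefined AUC, reported as
NaN and rendered 0 in table exports.

## Problem sizes and numerical choices

The reference synthetic study used by the tests and the acceptance script
is 60 patients (25 VS/UWS, 25 MCS, 10 SD) plus 6 controls on the default
grid — large enough for stable medians and cross-validated AUCs while a
full pipeline run stays around five minutes on one CPU.  The demo
configuration (`configs/demo.yaml`) is half that size.  FWE calibration
uses 200 null simulations of 20 subjects x 500 voxels with 99 permutations.
Fisher z values are clipped at atanh(1 − 1e−7); zero-variance voxels map to
z = 0 with a logged count; collinear confound columns are dropped by a
pivoted-QR rank check; all stochastic steps (cohort, ICA, permutations,
folds, bootstrap) derive their seeds from one top-level integer recorded in
the run manifest.

## Known limitations

The rating proxy is a two-feature stand-in for expert judgment; its bands
are calibration knobs, not estimates of rater behaviour.  The generator's
group-coupling defaults are study conditions, not estimates of real effect
sizes — the literature gives no quantitative VS-vs-MCS coupling difference.
Group templates require at least two controls and a matching component per
network; inside the orchestrated pipeline a failed template build falls
back to the node-ROI masks with a manifest warning.  Anticorrelations are
discarded by the one-sided z threshold.  No figure rendering is provided.
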