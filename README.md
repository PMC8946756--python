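# lowernet

Detection of the four lower-order resting-state fMRI networks —
sensorimotor (SM), auditory (AUD), lateral visual (LVIS) and medial visual
(MVIS) — in single subjects, and classification of vegetative state /
unresponsive wakefulness syndrome (VS/UWS) versus minimally conscious state
(MCS) in chronic disorders of consciousness (DoC).

The package is aimed at researchers working on functional imaging of DoC
who need a reproducible, fully automated version of the standard clinical
analysis chain: scrubbing/confound preprocessing, seed-based connectivity
with Fisher-z thresholding, fixed-order spatial ICA with template-based
component selection, per-node network rating and map-intensity indices, a
network presence rule, voxelwise nonparametric inference, and LASSO
logistic classification with internal cross-validation.  A synthetic-cohort
generator stands in for patient data, so every stage runs and is tested
end-to-end with no download.

## The pipeline in brief

Per subject (BOLD run of 200 volumes, TR 2.8 s):

1. **Preprocessing** — outlier frames at framewise displacement FD > 2 mm;
   regression of 6 motion parameters, mean WM/CSF signals, polynomial
   trends and one spike regressor per outlier frame; 0.01–0.1 Hz band-pass;
   6 mm FWHM Gaussian smoothing.
2. **Seed-based analysis (SBA)** — for each of 10 spherical nodes (6 mm),
   whole-brain correlation of the seed's mean time course, Fisher
   z = atanh(r) thresholded at z > 0.55; per node, two seed placements
   (literature coordinate vs most-preserved grey matter) are compared and
   the more specific / less noisy map kept; left and right maps stay
   separate, fused voxelwise by maximum only at the group stage.
3. **ICA** — spatial ICA with 30 components; per network, components are
   ranked by correlation with a control-group template (binarized at
   z ≥ 3) and vetted on spatial specificity, low-frequency power and
   time-course smoothness.
4. **Scoring** — per node and method, a 0–3 rating (automated proxy from
   coverage and template specificity; human ratings can override) and the
   mean map intensity over the node.  A network is present with a rating
   ≥ 2 on one node (two for SM).  Structural MRI node ratings (0–4) are
   rater-averaged and summed per network.
5. **Group statistics** — Mann–Whitney U (exact for small samples),
   Spearman rho, and voxelwise Spearman correlation with CRS-R subscales
   under max-statistic permutation FWE control.
6. **Classification** — five imaging feature models (rating, intensity,
   MRI, and combinations; single-network or all four networks), each ±
   clinical covariates, with L1-penalized logistic regression, inner
   10-fold penalty selection, leave-one-out validation, balanced accuracy,
   AUC with quality bands, stratified-bootstrap sensitivity/specificity
   CIs, and McNemar model comparisons.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Run the demo configuration (24 patients + 3 controls, a few minutes):

```sh
$ lowernet run --config configs/demo.yaml --out demo_out
networks detected: 55 (57% of patient-network pairs)
model intensity: bal.accuracy=0.65 AUC=0.58 (bad)
```

The first line is the detection summary: of 24 patients x 4 networks = 96
patient-network pairs, 55 were detected by the presence rule.
`demo_out/network_summary.tsv` stratifies these counts by etiology and
diagnosis; in this demo cohort the VS/UWS rows detect far fewer networks
(e.g. traumatic VS/UWS 38%) than MCS (75%) and SD (100%) rows, the graded
pattern the generator plants.  The second line is the leave-one-out result
of the map-intensity model: at this small n the balanced accuracy is 0.65
and the AUC band "bad" — single small cohorts are noisy, which is the
point of the larger reference run below.  `demo_out/detections.tsv` holds
the per-patient flags, `demo_out/classification.tsv` the model table
(ACCU / Bal ACCU / AUC / L / R selected-variable counts), and
`demo_out/manifest.json` the seeds, timings and result hashes that make the
run reproducible: running the same command twice yields identical hashes.

Python API sketch:

```python
from lowernet import (
    CohortSpec, default_synthetic_model, generate_cohort,
    preprocess_run, sba_subject,
)

model = default_synthetic_model()
spec = CohortSpec(n_vs=5, n_mcs=5, n_sd=2, n_controls=2, rng_seed=0)
records, runs, structurals = generate_cohort(spec, model)
pre, report = preprocess_run(runs[0])
node_maps = sba_subject(pre, model, structurals[0])  # node name -> thresholded z map
```

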