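# dysconnect

Whole-brain resting-state functional-connectivity discrimination for
case-control cohorts, built around the question: *can the pattern of
pairwise connectivity separate patients (here, functional dyspepsia) from
matched healthy controls, and does that pattern track disease severity?*

The package is aimed at researchers who have per-subject ROI time series (or
precomputed connectivity vectors) plus a clinical table, and want a tested,
reproducible implementation of the multivariate-pattern-analysis pipeline:

1. **Connectome features.** Each subject's T×R ROI time-series matrix is
   linearly detrended, band-passed to 0.01–0.08 Hz, optionally cleaned of
   nuisance signals, and reduced to a feature vector
   z<sub>k</sub> = atanh(r<sub>ij</sub>) over the R(R−1)/2 ROI pairs
   (523776 features for the 1024-node whole-brain parcellation).
2. **Fold-wise two-filter selection.** Inside each leave-one-out fold, an
   edge survives only if (a) its two-sample t-test p-value beats a
   permutation empirical null — retained iff
   (1 + #{|t<sub>perm</sub>| ≥ |t<sub>obs</sub>|}) / (N<sub>perm</sub> + 1) ≤ P,
   with one joint label shuffle across all edges per iteration — and (b) it
   correlates with the patients' NDI quality-of-life score at level α.
3. **Overlap-threshold stabilization.** An edge selected in M of the N folds
   has recurrence rate M/N; the *stable feature set* keeps edges with
   M/N ≥ τ (τ ∈ {100, 95, 90, 85}%).
4. **Classification.** A linear support-vector machine, trained per fold on
   training-only features, yields sensitivity, specificity, accuracy,
   ROC/AUC, and a label-shuffle permutation p-value for the accuracy;
   replication cohorts are scored by a single model on the stable set.
5. **Severity.** Leave-one-out support-vector regression predicts each
   patient's quality-of-life score from the stable edges; dividing by the
   patient-group mean gives the **connectivity severity index**
   (CSI<sub>i</sub> = ŷ<sub>i</sub> / mean(ŷ), mean CSI ≡ 1, lower = more
   severe), whose plain and partial correlations with the clinical scores
   are reported.
6. **Network report.** Stable edges are annotated with node occurrence
   weights, centroid-to-centroid Euclidean lengths, the sign of their
   QoL partial correlation (controlling age), and per-system tallies.

Because no scans are deposited for this design, a seeded synthetic-cohort
generator (subject tables with the published score means/SDs and correlation
structure, planted abnormal edges, optional band-limited time series) makes
every stage testable end to end.

## Worked example

```python
import dysconnect as d

cohort = d.generate_cohort(n_patients=12, n_controls=12, seed=3)
effects = d.PlantedEffectMap.default(n_rois=30, n_planted=5, seed=3)
features = d.generate_edge_data(cohort, n_rois=30, effects=effects, seed=3)

model = d.ConnectivityDiscrimination.from_dataframes(cohort, features)
result = model.fit(p_level=0.05, n_permutations=200, tau=(1.0, 0.9), seed=3)
print(result.summary())
print(result.severity(tau=0.9).summary())
```

prints

```
Connectivity discrimination (leave-one-out SVM)
====================================================
subjects            12 patients / 12 controls
selection           P = 0.05, 200 permutations, corr alpha = 0.05
feature mode        per_fold (linear kernel, C=1.0)
sensitivity         0.8333 (10/12)
specificity         0.9167 (11/12)
accuracy            0.8750 (21/24)
AUC                 0.9097
----------------------------------------------------
stable feature sets (recurrence >= tau):
  tau = 1.00      2 edges
  tau = 0.90      2 edges

Connectivity severity index (tau = 0.9)
====================================================
patients            12
mean CSI            1.000000000000
----------------------------------------------------
score                    r           p
ndi_symptom         -0.723     0.00788
sds                 -0.205       0.522
sas                 -0.138       0.669
duration_months      0.246       0.441
```

Reading the output: the leave-one-out SVM separated the synthetic groups with
87.5% accuracy (21 of 24 subjects); two edges recurred in ≥ 90% of folds
(the cohort planted five, but at n = 12+12 the correlation filter has limited
power); the CSI averages exactly 1 by construction and correlates negatively
with the symptom score (r = −0.72) while duration — generated independently
of connectivity — shows no association, mirroring the expected severity
structure.

The same run is available from the shell:

```bash
dysconnect simulate --n-patients 12 --n-controls 12 --n-rois 30 --seed 3 --outdir run/
dysconnect classify --features run/features.csv --subjects run/cohort.csv \
    --p-level 0.05 --n-perm 200 --seed 3 --out run/report.json
dysconnect run --outdir full_run/          # whole pipeline, default config
```

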