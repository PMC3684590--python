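# Methods

This note documents the statistical machinery, the synthetic-data model, the
numerical choices, and the open design decisions made while building the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The discrimination pipeline

**Features.** Functional connectivity is the Pearson correlation between two
ROIs' conditioned time series, Fisher-transformed (z = atanh r) so edge
values are approximately Gaussian with sampling SD ≈ 1/√(T−3). The strict
upper triangle of the R×R matrix is linearized row-major, giving
E = R(R−1)/2 features; `FeatureIndexMap` is the bijection between linear
index and ROI pair. Conditioning applies a per-column linear detrend, then a
band-pass to 0.01–0.08 Hz. The default filter is an ideal rectangular mask
on the real-FFT bins — the band specification is rectangular, and on
180-sample series an ideal mask passes an in-band tone within a few percent
while suppressing out-of-band tones by orders of magnitude; a zero-phase
4th-order Butterworth is available behind `method="butterworth"` for users
who prefer a realizable filter. Nuisance regression accepts an arbitrary
T×K regressor matrix (white-matter/CSF/ventricle means, motion summaries —
exactly which summaries is a data-provenance question, so it is left to the
caller), adds an intercept, and returns least-squares residuals; a
rank-deficient design degrades to a pseudo-inverse fit with a warning.
Correlations with |r| ≥ 1−1e−12 (duplicated signals) are clipped before
atanh with a warning; a zero-variance ROI is an error naming the ROI.

**Two-filter selection.** Within each leave-one-out fold the training
subjects yield, per edge, a pooled two-sample t-test p-value. The empirical
null is built by permuting group labels jointly across all edges
(`n_permutations` = 1000 by default, at least 100), recomputing the
full-width t-statistics per shuffle. An edge is retained when

  (1 + #{ |t_perm| ≥ |t_obs| }) / (n_permutations + 1) ≤ P.

Because every permutation shares the same degrees of freedom, ranking |t| is
identical to ranking the permutation p-values, which is how the rule is
usually phrased; under the global null the retention probability is
⌊P·(n+1)⌋/(n+1) ≈ P, which the calibration tests check directly. The level
of the quality-of-life correlation filter is nowhere pinned down by the
source analysis, so it is a separate parameter `corr_alpha`, default 0.05.
The per-fold permutation stream is seeded from (seed, fold index), so any
fold can be reproduced in isolation. Degenerate (zero-variance) edges are
silently non-significant inside folds rather than errors.

**Stabilization.** An edge selected in M of N folds has recurrence M/N;
`stabilize` keeps edges with M/N ≥ τ. τ = 1 is exactly the intersection of
the fold subsets, and the retained set grows weakly as τ falls — a
brute-force counting oracle in the tests confirms both.

**Classification.** Linear-kernel SVC with C = 1, features standardized with
training-fold statistics only. The source analysis names the SVM family and
toolbox but not the kernel or C; linear is the defensible default when
E ≫ n, and both are configurable. Three feature modes: `per_fold` (each
fold's own filter output), `stable` (the stable set recomputed from inner
leave-one-out folds of the training subjects — no information from the
held-out subject), and `stable_leaky` (one global stable set reused across
folds; deliberately leaky, provided only for comparison because the
original description is ambiguous on this point). Folds with empty feature
sets fall back to the training majority class and are logged. Significance
of the accuracy uses label shuffles with the whole selection+classification
pipeline re-run per shuffle and perm_p = (1 + #{null ≥ real})/(1 + S),
which cannot be zero.

**Severity.** Patients' quality-of-life scores are predicted by
leave-one-out epsilon-SVR (linear kernel, standardized features and target)
on the stable edges — the predicted-score-to-severity-index construction
follows the connectome-predictive-modeling tradition; the exact regression
scheme was not specified at the source, so SVR mirrors the classification
toolbox and is configurable. CSI_i = ŷ_i / mean(ŷ), so mean(CSI) = 1
identically; out-of-fold rather than in-sample predictions are used (the
less optimistic choice). Partial correlation is classical double
residualization (OLS with intercept) followed by Pearson correlation of the
residuals, with p-value degrees of freedom n − 2 − k; an independent
implementation (pingouin) is the cross-check in the tests, never the
implementation.

**Network report.** Node weights count stable-edge incidences (handshake
identity enforced by test); lengths are centroid Euclidean distances in mm,
taken in whatever single coordinate convention the atlas declares — no
space conversion is attempted. The negative/positive split follows the sign
of the edge's QoL partial correlation controlling age; an exact zero (never
observed on continuous data) counts as positive. An edge touching two
systems counts once in each system's tally by default ("within or across");
exclusive first-ROI assignment is available.

## The synthetic-cohort generator

The generator defines the study conditions for every test; its defaults are
not tuned per test.

**Clinical scores.** Truncated Gaussians with the published group means/SDs
(patients: QoL 76.65 ± 10.17, symptom 47.2 ± 15.87, SDS 44.38 ± 9.98,
SAS 42.63 ± 7.17, duration 37.8 ± 28.2 months; controls: QoL 87.41 ± 5.44,
symptom 1.23 ± 1.90, SDS 33.93 ± 5.77, SAS 32.3 ± 5.87). Correlation
structure comes from two correlated latent factors — "gastro" (loading
+0.85 on symptom, −0.85 on QoL) and "mood" (+0.85 on SDS and SAS, plus a
0.15 cross-loading on gastro), factor correlation 0.3 — with duration and
age independent. A single shared factor cannot simultaneously make
QoL↔symptom and SDS↔SAS strong while symptom↔SDS/SAS stay moderate and
duration independent; two factors reproduce that qualitative pattern, which
is what the tests assert. Truncation is by clipping (QoL to [0,100], others
to ≥0); at the published parameters the clipped mass is small except for
control symptom scores, where a floor at zero is realistic anyway.

**Planted edges.** The default map plants 10 edges on disjoint ROI pairs
with a patient-minus-control mean shift of 2·noise_sd in Fisher-z units and
a within-patient edge-QoL correlation of |r| = 0.7, 65% of slopes negative
(the direction mix reported for the real abnormal network). The magnitude
0.7 satisfies the |r| ≥ 0.5 floor used in the recovery criteria and was
fixed a priori so the correlation filter at α = 0.05 has adequate power in
~19-patient training folds; no effect sizes are published for the real
data, so these are tuning choices of the generator, not estimates.
Non-planted edges are independent zero-mean Gaussian noise — convenient for
binomial calibration arithmetic, but unlike real connectomes, which are
spatially correlated (see *Limitations*).

**Time series.** Each ROI receives an independent unit-variance band-limited
(0.01–0.08 Hz) Gaussian signal; the two ROIs of a planted edge share a
common band-limited source weighted so their correlation approximates
tanh(planted z) for that subject. A random-slope linear drift and a 0.15 Hz
out-of-band sinusoid are added so the conditioning stage has real work to
do. Defaults mirror the acquisition: 180 volumes at TR = 2 s (6-minute
session; the first 10 volumes of a real session would be discarded, giving
170 — `session_volumes`/`discard_initial` do this bookkeeping). Hemodynamics,
spatial structure and motion artifacts are not modeled; edge-level
generation is the primary test path, the time-series path exists to
exercise conditioning.

## Problem sizes

Desk-scale defaults are R = 90 (4005 edges) rather than the full 1024-node
parcellation (523776 edges; supported, exercised only through the index
map), cohorts of 20+20, and 200 permutations. Calibration of the
label-shuffle significance test, which re-runs the entire nested pipeline
per shuffle, uses R = 30, 12+12, 100 inner permutations and 99 shuffles ×
20 seeds — the code path is identical, only the sizes shrink. These sizes
are the package's choices for routine verification; all stages accept
paper-scale inputs.

## What passing tests do and do not show

Passing recovery tests show the pipeline finds planted, independent,
Gaussian edge effects of the stated size with high precision/recall and
classifies the resulting cohorts accurately. They do not show that real
dyspepsia connectomes contain such effects, nor that the published accuracy
figures would replicate: real edges are correlated, effects are not
localized to disjoint pairs, and clinical scores are not Gaussian. The
calibration tests show both permutation schemes hold their nominal error
rates under the generator's null, which is the property that transfers to
real data most directly.

## Known limitations

- The stable-mode LOOCV is O(N²) selection passes; at paper scale (80
  subjects, 523776 edges, 1000 permutations) it is a long single-CPU run —
  the per-fold mode plus separate stabilization is the practical default.
- `relative_error` divides by the actual score; scores of zero produce NaN
  entries that are excluded from means (duration and control symptom scores
  can legitimately be zero).
- The ideal-mask filter assumes the series is analyzed as-is (no padding);
  spectral leakage of strongly off-bin tones near the band edge is not
  corrected.
- Exclusive system assignment uses the first ROI's system as the tie-break;
  there is no principled owner for a cross-system edge.
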