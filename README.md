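# pupilclust

Unsupervised clustering of participants by pupil-size dynamics under
escalating cognitive load, with autonomic, oculomotor and behavioral
contrasts between the recovered groups.

## The problem

In a self-paced color-matching task of 3 blocks × 6 escalating difficulty
levels × 17 trials (306 trials), with deliberately wrong ("deceptive")
feedback in block 2, levels 3–6, individuals differ systematically in how
their pupil responds to rising load and to being told they are failing.
`pupilclust` implements the full analysis for this design:

1. **Trajectory construction** — per-trial mean pupil sizes form one
   vector `x ∈ ℝ³⁰⁶` per participant, z-scored over the whole session
   (`z = (x − x̄)/s`) and smoothed with a 17-trial moving average (one
   difficulty level).
2. **Clustering** — k = 2 Euclidean k-means (Lloyd's algorithm, k-means++
   seeding, best of 25 restarts by inertia), with labels aligned so that
   cluster 0 is the group whose centroid starts block 1 level 1 higher.
   Isolation-forest screening flags anomalous trajectories without
   silently dropping them.
3. **Autonomic metrics** — ECG is high-pass filtered (5th-order
   Butterworth, 0.5 Hz) with a 50 Hz notch; R-peaks are detected from
   gradient steepness with a 250 ms refractory period; HRV is summarized
   as MeanNN, SDNN, RMSSD and Welch-PSD band powers LF (0.04–0.15 Hz), HF
   (0.15–0.40 Hz) and LF/HF per level and block. Skin-conductance
   responses and respiration cycles get threshold/zero-crossing
   treatments.
4. **Group statistics** — every metric × segment comparison is routed
   through a Shapiro–Wilk gate: Student's t with Cohen's d (+ CI) and
   point-biserial r when both groups are normal, otherwise Mann–Whitney U
   with rank-biserial correlation (RBC = 2·CLES − 1) and the
   common-language effect size; χ² for 2×2 categorical tables.

Because the matching raw recordings are not needed for development, a
**synthetic multimodal cohort generator** provides the test substrate: two
latent archetypes (early-pupil-peak/high-HRV/fast-but-error-prone vs.
low-start-rising/deception-reactive/low-HRV/slow-but-accurate) with known
labels, so cluster recovery, metric extraction and the direction of every
contrast can be verified end to end.

## Worked example

```python
from pupilclust import build_schedule, generate_cohort, kmeans_fit, align_labels, adjusted_rand
from pupilclust.pupil import trajectory_matrix

schedule = build_schedule()                       # 3 x 6 x 17 lattice
cohort = generate_cohort(schedule=schedule, seed=0, channels=("pupil",))
matrix, pids = trajectory_matrix(cohort.trial_table)
result = align_labels(kmeans_fit(matrix, k=2, seed=0), matrix, schedule)

print([int((result.labels == k).sum()) for k in (0, 1)])
truth = cohort.truth.set_index("participant").loc[pids, "archetype"].to_numpy()
print(round(adjusted_rand(result.labels, truth), 3))
```

prints

```
[33, 37]
1.0
```

i.e. the 70-participant default cohort splits into 33 early-peak and 37
deception-reactive participants, and the recovered partition matches the
generative archetype labels exactly (adjusted Rand index 1.0).

The `examples/` directory has one short script per capability (schedule +
cohort, clustering, ECG→HRV, group comparison, full pipeline), and
`pupilclust demo` runs the whole study-scale analysis from the shell,
writing labels, per-level and per-block comparison tables, peak-reaction
tables and a validation report.

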