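# Methods

## Task model

The analysis assumes a fixed trial lattice: `n_blocks × n_levels ×
n_trials_per_level` (default 3 × 6 × 17 = 306 trials), difficulty rising
across levels within each block, and a set of deceptive-feedback cells
(default block 2, levels 3–6) where the feedback shown to the participant
is deliberately wrong. Trial indices are 0-based half-open internally;
blocks and levels are 1-based in every report. Inter-block rest breaks are
metadata only and never enter trial indexing, because every analysis is
per-trial or per-level. Self-esteem prompts after each level are treated
as level-level annotations and do not consume trial indices.

## Pupil trajectories

Each participant is a vector of per-trial mean pupil sizes. The fixed
preprocessing order is **trial means → z-score → smooth → screen**:

* **Z-scoring** is per participant over the entire session, with the
  population (n) denominator. This choice makes normalization idempotent;
  it is configurable via `ddof` and is irrelevant to clustering (a common
  scalar rescaling of all entries of a participant's vector).
* **Smoothing** is a uniform moving average whose window equals the
  trials-per-level count (17), so the kernel integrates exactly one
  difficulty level. Edges use shrinking windows (mean over available
  neighbors), which keeps constants exact at the boundary and preserves
  output length. Smoothed vectors are the clustering default; a toggle
  clusters the unsmoothed z-vectors instead.
* **Missing trials** are linearly interpolated when below 5 % of the
  session, otherwise the participant is excluded with a logged reason.
  The threshold is a policy choice: imputation of more than a level's
  worth of data would manufacture trajectory shape.
* **Screening** uses an Isolation Forest over the full vectors and flags
  the `ceil(contamination · n)` highest anomaly scores (default
  contamination 0.05). Flagging never drops anyone; exclusion is an
  explicit pipeline switch, so every exclusion is auditable.

## Clustering

K-means with Euclidean distance on the trajectory vectors, k = 2 by
default. The Lloyd loop is implemented directly so two contracts can be
enforced: within-run inertia monotonicity is asserted at every iteration,
and an emptied cluster is re-seeded at the point farthest from its
assigned centroid. Seeding is k-means++ (via scikit-learn's
`kmeans_plusplus`); the best of `n_init = 25` restarts by inertia is kept;
convergence at centroid shift < 1e-6 or 300 iterations. On instances
small enough to enumerate (n ≤ 8), the restart scheme reproduces the
global optimum found by exhaustive partition search (oracle suite, 200
random cases).

Labels are aligned to a reporting convention: cluster 0 is the cluster
whose centroid has the larger mean over the block-1 level-1 window — the
"strong initial response" group. Exact ties (measure zero in practice)
order by within-cluster inertia contribution with a logged warning.
Silhouette-vs-k is reported on request but never auto-selects k.

## Synthetic cohort

The generator is the package's test substrate and encodes the study
conditions as defaults: 33 + 37 participants in two archetypes.

* **Pupil**: archetype 0 starts each block +1.4 SD-units high and
  declines by 1.8 over the block; archetype 1 starts at −1.1, rises by
  1.4, and adds a deception bump of 1.5 on the first deceptive level,
  decaying ×0.6 per subsequent deceptive level (so the block-2 maximum
  falls in level 3). Per-trial Gaussian noise (SD 0.25) and ±8 %
  participant-level parameter jitter create within-archetype spread;
  with these defaults the between-centroid distance exceeds 4× the mean
  within-archetype spread, which is the separability contract the
  recovery tests rely on.
* **Cardiac**: RR(t) = MeanNN + a_LF·sin(2π·0.1·t) + a_HF·sin(2π·0.25·t)
  + white jitter. The 0.1/0.25 Hz carriers are the standard LF/HF band
  centers; jitter SD is RMSSD_target/√2 (white jitter of SD s gives
  RMSSD = s√2). Archetype 0: MeanNN 860 ms, RMSSD target 45 ms, HF-heavy
  modulation; archetype 1: 760 ms, 25 ms, weaker modulation. Measured
  RMSSD slightly exceeds the jitter target because the HF carrier also
  contributes successive-difference power; the ordering contract
  (archetype 0 > 1 on MeanNN/RMSSD/SDNN/HF) is what downstream tests use.
  ECG is rendered as narrow Gaussian QRS bumps (σ = 12 ms) at cumulative
  R times with ground-truth indices returned — enough morphology to
  exercise the filter and detector, deliberately not a PQRST model.
* **Timing**: trials are self-paced; per-trial duration = 2 s stimulus +
  simulated RT + 0.6 s feedback, giving ≈ 6.5 min blocks. These durations
  anchor all continuous traces, since level windows must be mapped to
  wall-clock spans for HRV segmentation.
* **Behavior/eyes**: RT is gamma (shape 8) with mean rising 8 % per
  level; errors Bernoulli per level (archetype 0 error-prone, archetype 1
  accurate); eye events are homogeneous Poisson per level at archetype
  rates with lognormal durations/amplitudes; self-esteem is a clipped,
  rounded 1–5 rating declining with level plus an archetype bias.
* **EDA/respiration** are minimal (tonic drift + exponential-recovery
  SCRs at Poisson times; sinusoid with jittered period) because these
  channels carry null contrasts in the analysis they support.

What the generator does **not** emulate: pupil light reflex and
within-trial dynamics, real QRS morphology and ectopy, RSA coupling
between respiration and RR, drift or loss in eye tracking, questionnaire
psychometrics. Passing tests therefore demonstrate correctness of the
pipeline's computations and its ability to recover structure of the kind
assumed, not performance on raw laboratory recordings.

## Autonomic processing

ECG filtering is zero-phase (forward–backward) to avoid R-peak latency
shifts: 5th-order Butterworth high-pass at 0.5 Hz plus a 50 Hz notch
(Q = 30). The R-peak detector thresholds the gradient magnitude at
median + 4·MAD over 10 s chunks — deliberately sensitive — then prunes
noise-driven candidates with an amplitude gate at half the 95th-percentile
candidate amplitude, and enforces a 250 ms refractory period keeping the
larger peak. On rendered ECG at 20 dB SNR this yields precision and
recall ≥ 0.99.

NN artifact handling flags intervals deviating more than 20 % from an
11-beat running median (a transparent, configurable rule); a segment with
more than half flagged raises rather than producing silently biased
metrics. SDNN uses the sample (n−1) denominator. Frequency metrics
interpolate the tachogram to 4 Hz (cubic spline), detrend linearly, and
integrate a Welch PSD over LF 0.04–0.15 Hz and HF 0.15–0.40 Hz
(trapezoidal, ms²); spectral metrics require ≥ 60 s of data and are
reported missing below that. Band powers are reported in ms² only — no
absolute HF target is asserted anywhere because normalization conventions
vary across toolkits.

SCR analysis high-passes at 0.05 Hz and counts peaks with rise amplitude
≥ 0.05 µS (configurable). Respiration cycles come from zero-crossings of
the detrended trace: inspiration = trough→peak, expiration = peak→trough,
phase ratio = mean inspiration / mean expiration.

## Group statistics

Comparisons are gated by Shapiro–Wilk at α = 0.05 on both groups:
Student's t (pooled variance — Welch behind a flag) with Cohen's d,
normal-approximation d CI (noncentral-t behind a flag) and point-biserial
r with a Fisher-z CI; otherwise two-sided Mann–Whitney U with RBC and
CLES. A group with zero variance forces the nonparametric branch. The
orientation is fixed and printed on every row: group 1 relative to group
0, CLES = P(random group-1 value > random group-0 value, ties half),
RBC = 2·CLES − 1. The pairwise enumeration is the normative definition;
the rank-sum identity used in code is verified against it exactly,
including ties. Monte-Carlo calibration of the gated procedure over
10,000 null replicates at the study's group sizes stays within
[0.045, 0.055] at nominal α = 0.05.

Per-level reports run one comparison per metric × (block, level); block
reports compare participant-level block values defined as the mean of
that participant's level values (peripheral EDA/respiration metrics,
computed once per block, enter the block report directly). Headline
p-values are uncorrected — the convention for these level-wise tables —
with Benjamini–Hochberg columns appended for transparency, never
substituted. Peak-reaction tables report each cluster's extreme (block,
level) per metric, flagging extremes that fall in deceptive cells; ties
resolve to the earliest segment with a tie flag.

## Pipeline and problem sizes

`run_pipeline` is deterministic under its recorded seeds and writes a
manifest (config hash, seeds, versions, stage row counts) with every run.
Validation of synthetic runs checks ARI ≥ 0.9 against truth labels, the
expected contrast directions (cluster 0 higher MeanNN/SDNN/RMSSD/HF;
cluster 1 higher saccade/fixation/blink counts and total time) and MeanNN
parameter recovery (< 2 % relative error).

Test and acceptance workloads use the study-scale cohort (70 participants,
306 trials, ~19 min of 250 Hz traces per participant) for the headline
checks, and smaller cohorts (12 participants) for multimodal integration
tests; both sizes were chosen as the smallest that exercise every code
path at full fidelity.

## Known limitations

* The clustering restart scheme is exact on enumerable instances but, as
  with any k-means, carries no global-optimality guarantee at scale.
* HRV level windows assume the trial table's wall-clock spans are exact;
  real recordings would need synchronization-offset handling.
* The artifact rule is a stand-in policy (running median ± 20 %), not a
  validated clinical detector; it is configurable.
* EDA decomposition is a single high-pass, not a tonic/phasic model.
* With self-paced trials, per-level spans hover near the 60 s spectral
  minimum; slow participants yield more reliable per-level LF/HF than
  fast ones. Block-level spectral metrics are the robust quantity.
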