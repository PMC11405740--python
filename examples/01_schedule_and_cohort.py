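"""Build the task lattice and a small labeled synthetic cohort.

The task is 3 blocks x 6 difficulty levels x 17 trials (306 trials), with
deliberately wrong feedback in block 2, levels 3-6.  The generator attaches
every other channel (eye events, ECG, EDA, respiration, questionnaires) to
this lattice via self-paced trial timing.
"""

from pupilclust import build_schedule, deceptive_trial_mask, generate_cohort

schedule = build_schedule()
print(f"trials total: {schedule.total_trials}  per block: {schedule.trials_per_block}")
print(f"deceptive trials: {deceptive_trial_mask(schedule).sum()} "
      f"(cells {sorted(schedule.deceptive_cells)})")

cohort = generate_cohort(schedule=schedule, n_per_archetype=(3, 3), seed=1)
print(f"\ncohort: {len(cohort.participants)} participants, "
      f"{len(cohort.trial_table)} trial rows")
print(cohort.trial_table[["participant", "trial", "block", "level",
                          "pupil", "rt_ms", "correct", "self_esteem"]].head())
# Each participant contributes one 306-trial pupil vector; 'truth' holds the
# hidden archetype labels that only validation code is allowed to read.
print("\narchetype truth:\n", cohort.truth[["participant", "archetype"]])
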