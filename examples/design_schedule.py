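"""Build a counterbalanced playback schedule for four females.

Each subject gets two father-vs-non-imprinted sessions of four
alternating 2-minute trials; within a trial, three songs of one male
cycle every 10 s (12 presentations). Starting stimulus types alternate
across subjects so order effects cancel.
"""

from songtool import counterbalance, schedules_to_frame, validate_schedule

subjects = ["JS0311", "JS0314", "JS0327", "JS0330"]
schedules = counterbalance(subjects)

for s in schedules:
    report = validate_schedule(s)
    types = "".join(t.stimulus_type[0].upper()
                    for sess in s.sessions for t in sess.trials)
    print(f"{s.subject_id}: starts with {s.start_with:<13} "
          f"trial types {types}  valid={report.ok}")

df = schedules_to_frame(schedules)
df.to_csv("schedule.csv", index=False)
print(f"\n{len(df)} presentations written to schedule.csv; first rows:")
print(df.head(6).to_string(index=False))
print("\nEach letter above is one trial (F = father, N = non-imprinted): "
      "strict alternation within sessions, opposite start in session 2, "
      "and half the subjects start with the father's song.")
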