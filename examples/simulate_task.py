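"""Generate a task schedule and reaction times for a two-group cohort.

Builds the default 8-block audiovisual redundant-target schedule (34 A, 34 V,
34 AV per block, fixation 1000-3000 ms), simulates reaction times under the
race architecture, and prints per-group condition means.
"""

from avmsi import TaskConfig, generate_schedule, simulate_rt_study

schedule = generate_schedule(TaskConfig(seed=0))
print(f"events: {schedule.n_events} "
      f"({schedule.frame['block'].nunique()} blocks)")
print("per-block condition counts:")
print(schedule.condition_counts().head(3))

rts = simulate_rt_study(n_per_group=12, seed=0)
means = rts.groupby(["group", "condition"], observed=True)["rt_ms"].mean()
print("\nmean RT (ms) by group and condition:")
print(means.round(1))
print("\nAV < V < A within each group is the redundancy-gain signature;")
print("the SCNP group is slower overall by the simulated ~30 ms offset.")
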