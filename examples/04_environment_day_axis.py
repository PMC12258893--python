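"""Developmental arrests and the generations-vs-days distinction.

A 6-day L1 starvation arrest at the first trigger-free generation does not
change how many generations the silencing memory lasts, but it adds 6 days
to the day-axis coordinate of every generation at or after G1 — so the same
memory persists longer in absolute time. Applying both schedules to the
same scored counts isolates the pure timing effect.
"""

import rnai_memory as rm

control = rm.GenerationSchedule(base_days={"20C": 3.5})
arrested = rm.GenerationSchedule(base_days={"20C": 3.5}, arrests=((1, 6.0),))

design = rm.SimulationDesign(
    strain_halflives={"N2": 3.0, "JU1395": 1.5}, seed=4
)
table = rm.simulate_experiment(design)
groups = rm.group_replicates(table)

print(f"{'replicate':>24s} {'gen axis':>9s} {'days (fed)':>11s} {'days (L1 arrest)':>17s}")
for key, records in list(groups.items())[:6]:
    t_fed = rm.build_trajectory(records, control, "20C")
    t_arr = rm.build_trajectory(records, arrested, "20C")
    g = rm.half_life(t_fed, axis="generations").value
    d_fed = rm.half_life(t_fed, axis="days").value
    d_arr = rm.half_life(t_arr, axis="days").value
    g_arr = rm.half_life(t_arr, axis="generations").value
    assert g == g_arr  # the arrest never moves the generation-axis estimate
    label = f"{key.strain} {key.block}-r{key.replicate}"
    print(f"{label:>24s} {g:9.2f} {d_fed:11.2f} {d_arr:17.2f}")

print(
    "\nThe generation-axis half-life is identical under both schedules, while"
    "\nthe day-axis value grows by exactly 6.0 whenever the 50% crossing falls"
    "\nafter the arrested generation: the developmental pause extends silencing"
    "\nmemory in absolute time without changing its generational dynamics."
)
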