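"""Estimate per-replicate half-lives of silencing memory.

For every (block, strain, environment, replicate) series the two scoring
points closest below and above 50% GFP-positive are selected and the linear
crossing is returned — in generations and in days. Replicates already above
50% at G1 are anchored against the fully silenced G0 point; replicates that
never sustainedly reach 50% are censored.
"""

import rnai_memory as rm

design = rm.SimulationDesign(
    strain_halflives={"JU1171": 0.7, "JU1395": 1.5, "N2": 3.0, "MY10": 5.5},
    seed=1,
)
table = rm.simulate_experiment(design)
groups = rm.group_replicates(table)
hl = rm.halflife_table(
    groups, rm.schedules_of(design), axes=("generations", "days")
)

gen = hl[hl["axis"] == "generations"]
print("per-strain half-life of silencing memory (generations):")
print(
    gen[gen["status"] != "censored"]
    .groupby("strain")["value"]
    .agg(["median", "min", "max", "count"])
    .round(2)
)
print("\nstatus counts:", gen["status"].value_counts().to_dict())
print(
    "\nMedians track the simulated half-lives (0.7, 1.5, 3.0, 5.5). JU1171's"
    "\nestimates are 'left_anchored': silencing is already lost at G1, so the"
    "\ncrossing is interpolated against the fully silenced G0 point."
)
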