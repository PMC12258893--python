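"""Simulate a multigenerational RNAi silencing-memory scoring experiment.

Four strains with latent half-lives from 0.7 (memory lost before the first
trigger-free generation) to 5.5 generations are scored for germline GFP in
4 blocks x 3 replicates, ~100 individuals per time point, at generations
G1..G8 after the dsRNA trigger is removed (G0 is emitted fully silenced).
"""

import rnai_memory as rm

design = rm.SimulationDesign(
    strain_halflives={"JU1171": 0.7, "JU1395": 1.5, "N2": 3.0, "MY10": 5.5},
    seed=1,
)
table = rm.simulate_experiment(design)
rm.write_scoring_table(table, "scoring.csv")

print(f"simulated {len(table)} scoring records -> scoring.csv")
print("first replicate of N2 in block A (generation: OFF/DIM/ON):")
for rec in table:
    if (rec.block, rec.strain, rec.replicate) == ("A", "N2", 1):
        pct = rm.pct_gfp_positive(rec.n_off, rec.n_dim, rec.n_on)
        print(f"  G{rec.generation}: {rec.n_off:3d}/{rec.n_dim:3d}/{rec.n_on:3d}"
              f"  -> {pct:5.1f}% GFP-positive")
print(
    "\nThe percent-positive column rises sigmoidally through the generations;"
    "\nits 50% crossing near generation 3 is this replicate's silencing-memory"
    "\nhalf-life (N2 was simulated with a latent half-life of 3.0 generations)."
)
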