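# rnai-memory

Quantitative analysis of multigenerational RNAi silencing-memory assays in
*C. elegans* — from raw per-generation GFP scoring counts to half-lives of
silencing memory and mixed-model comparisons of strains and environments.

In these assays a germline GFP reporter is silenced by feeding dsRNA for two
generations; after the trigger is removed, ~100 animals per replicate are
scored each generation as OFF, DIM or ON (OFF and DIM count as GFP-negative:
DIM animals still inherit silencing). The fraction of GFP-positive animals
rises sigmoidally as the memory decays. This package is for researchers who
run or re-analyze such experiments and need the full statistical chain:

1. **Half-life estimation** — for every replicate series, the two scoring
   points closest below and above 50% GFP-positive bracket the crossing and
   the linear interpolant gives the half-life `V`, in generations or (via a
   generation schedule with L1-arrest / dauer insertions) in days.
   Oscillating series fall back to a widened bracket; series above 50% at G1
   are anchored at the fully silenced G0; series never reaching 50% are
   censored.
2. **Mixed-model comparison** — half-lives are compared with a Gamma
   log-link GLMM with nested random intercepts,

   ```
   V ~ Strain + (1|Block) + (1|Block:Replicate),        family = Gamma(log)
   V ~ Strain * Environment + (1|Block) + (1|Block:Replicate)
   ```

   fitted by Laplace approximation, with Wald/likelihood-ratio term tests,
   equal-weight marginal means, single-step (Tukey) adjusted pairwise
   log half-life ratios, and simulation-based (rank-uniformity) residual
   diagnostics.
3. **Synthetic experiments** — a generator with the same statistical
   structure (logistic desilencing, binomial scoring of ~100 animals,
   lognormal block/replicate variation) for power studies and testing.

See `docs/methods.md` for the estimators, defaults and known limitations.

## Worked example

```python
import rnai_memory as rm

design = rm.SimulationDesign(
    strain_halflives={"JU1171": 0.7, "JU1395": 1.5, "N2": 3.0, "MY10": 5.5},
    seed=1,
)
table = rm.simulate_experiment(design)                      # 432 scoring records
hl = rm.halflife_table(rm.group_replicates(table), rm.schedules_of(design))
fit = rm.fit_glmm(hl[hl["status"] != "censored"], rm.GlmmSpec())
print(rm.wald_test_term(fit, "strain"))
for c in rm.tukey_contrasts(rm.marginal_means(fit, "strain"))[:2]:
    print(c.level_a, c.level_b, round(c.estimate, 3), f"{c.p_adj:.3g}")
```

Output:

```
TermTest(term='strain', stat=2603.854782349503, df=3, p=0.0, kind='wald')
JU1171 JU1395 -0.612 6.63e-47
JU1171 MY10 -2.022 0
```

The per-strain median half-lives from this table are 0.77, 1.33, 3.30 and
5.71 generations — tracking the simulated values 0.7/1.5/3.0/5.5. The Wald
chi-square of 2604 on 3 df says strain identity decisively determines how
long silencing persists; the JU1171-vs-MY10 contrast of −2.02 on the log
scale means JU1171's memory half-life is about 1/7.5 of MY10's, significant
after Tukey adjustment.

The `examples/` scripts walk each capability (simulation, half-life
estimation, strain comparison, day-axis arithmetic under developmental
arrests, residual diagnostics) with commented output.

## Command line

The same pipeline is scriptable from a YAML run configuration:

```bash
rnai-memory simulate --config run.yaml --out scoring.csv
rnai-memory halflife --scoring scoring.csv --config run.yaml --axis both --out halflife.csv
rnai-memory fit --halflife halflife.csv --out fit.json --contrasts contrasts.csv
rnai-memory run --config run.yaml --outdir results/    # all stages + manifest
rnai-memory report --outdir results/ --plots
```

`run` writes every table (scoring, half-life, trajectory summaries,
contrasts, fit report, diagnostics) plus a manifest with checksums; reruns
with the same config and seed are byte-identical.

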